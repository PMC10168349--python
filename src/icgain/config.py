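"""YAML configuration: sections [membrane], [synapse], [stimulus],
[integration] with unit-suffixed keys.  Unknown sections or keys are
rejected so typos never fall back to defaults silently."""

from __future__ import annotations

import yaml

from .mtf import SweepSpec
from .neuron import MembraneParams
from .stimulus import SynapseParams

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config",
           "build_membrane", "build_synapse", "build_sweep_spec",
           "dump_default_config"]

DEFAULT_CONFIG = {
    "membrane": {
        "cm_uf_per_cm2": 1.0,
        "gna_ms_per_cm2": 35.0,
        "ena_mv": 55.0,
        "gk_ms_per_cm2": 9.0,
        "ek_mv": -90.0,
        "gl_ms_per_cm2": 0.7,
        "el_mv": -65.0,
        "phi": 5.0,
        "diameter_um": 15.0,
    },
    "synapse": {
        "gampa_max_ms_per_cm2": 0.5,
        "nmda_ratio": 0.25,
        "tau_rise_ampa_ms": 0.2,
        "tau_decay_ampa_ms": 2.0,
        "tau_rise_nmda_ms": 5.0,
        "tau_decay_nmda_ms": 100.0,
        "esyn_mv": 0.0,
        "nmda_enabled": True,
        "saturating": True,
    },
    "stimulus": {
        "frequency_hz": 16.0,
        "fmin_hz": 16.0,
        "fmax_hz": 512.0,
        "steps_per_octave": 4,
        "duration_ms": 1000.0,
        "gl_list_ms_per_cm2": [0.7],
        "recalibrate": True,
    },
    "integration": {
        "dt_ms": 0.01,
        "seed": 0,
        "noise_sd_ua_per_cm2": 0.0,
    },
}

_MEMBRANE_KEYS = {
    "cm_uf_per_cm2": "Cm", "gna_ms_per_cm2": "gNa", "ena_mv": "ENa",
    "gk_ms_per_cm2": "gK", "ek_mv": "EK", "gl_ms_per_cm2": "gL",
    "el_mv": "EL", "phi": "phi", "diameter_um": "diameter",
}
_SYNAPSE_KEYS = {
    "gampa_max_ms_per_cm2": "gAMPA_max", "nmda_ratio": "nmda_ratio",
    "tau_rise_ampa_ms": "tau_rise_ampa", "tau_decay_ampa_ms": "tau_decay_ampa",
    "tau_rise_nmda_ms": "tau_rise_nmda", "tau_decay_nmda_ms": "tau_decay_nmda",
    "esyn_mv": "Esyn", "nmda_enabled": "nmda_enabled",
    "saturating": "saturating",
}


def merge_config(overrides: dict | None) -> dict:
    """Defaults overlaid with ``overrides``; unknown sections/keys raise."""
    cfg = {sec: dict(vals) for sec, vals in DEFAULT_CONFIG.items()}
    for section, vals in (overrides or {}).items():
        if section not in cfg:
            raise KeyError(f"unknown config section: [{section}]")
        if not isinstance(vals, dict):
            raise TypeError(f"section [{section}] must hold key: value pairs")
        for key, value in vals.items():
            if key not in cfg[section]:
                raise KeyError(f"unknown key '{key}' in section [{section}]")
            cfg[section][key] = value
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return merge_config(data)


def build_membrane(cfg: dict) -> MembraneParams:
    sec = cfg["membrane"]
    return MembraneParams(**{field: sec[key]
                             for key, field in _MEMBRANE_KEYS.items()})


def build_synapse(cfg: dict) -> SynapseParams:
    sec = cfg["synapse"]
    return SynapseParams(**{field: sec[key]
                            for key, field in _SYNAPSE_KEYS.items()})


def build_sweep_spec(cfg: dict) -> SweepSpec:
    stim, integ = cfg["stimulus"], cfg["integration"]
    return SweepSpec(
        fmin=stim["fmin_hz"], fmax=stim["fmax_hz"],
        steps_per_octave=stim["steps_per_octave"],
        gl_values=tuple(stim["gl_list_ms_per_cm2"]),
        duration=stim["duration_ms"], dt=integ["dt_ms"],
        recalibrate=stim["recalibrate"],
        noise_sd=integ["noise_sd_ua_per_cm2"], seed=integ["seed"],
    )


def dump_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
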