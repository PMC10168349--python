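"""Seeded synthetic-data generators for every analysis stage.

Three generators emulate the data the analysis consumes: phase-locked
spike trains with controlled rate and vector strength (inhomogeneous
Poisson process with von Mises-shaped intensity), noisy synaptic-event
traces drawn from the event-fit template, and Bernoulli/multinomial
cell-marker tables with stated co-expression proportions.  All are
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0, i0e, i1e

from .expression import COLUMNS, marker_table
from .metrics import SpikeTrain
from .waveform import epsc_model

__all__ = [
    "gen_phase_locked_spikes",
    "gen_epsc_trace",
    "gen_marker_table",
    "vs_for_kappa",
    "kappa_for_vs",
]

# published overall co-expression proportions of tdTomato+ VIP neurons
DEFAULT_CLASS_PROBS = {"p_only2d": 0.843, "p_only2c": 0.010, "p_both": 0.071}


def vs_for_kappa(kappa: float) -> float:
    """Vector strength of a von Mises phase distribution: I1(κ)/I0(κ)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    # exponentially scaled Bessel ratio avoids overflow at large kappa
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_vs(vs: float) -> float:
    """Concentration κ whose von Mises phase distribution has the given VS."""
    if not 0 <= vs < 1:
        raise ValueError("target vector strength must lie in [0, 1)")
    if vs == 0:
        return 0.0
    return float(brentq(lambda k: vs_for_kappa(k) - vs, 1e-9, 1e4))


def gen_phase_locked_spikes(rate: float, frequency: float, kappa: float,
                            duration: float, seed,
                            phase: float = 0.0) -> SpikeTrain:
    """Phase-locked spike train via thinning of a homogeneous process.

    Intensity λ(t) = rate · e^{κ·cos(2πf·t/1000 − phase)} / I0(κ)
    (spikes/s; t in ms), so the mean rate is ``rate`` and the phase
    distribution is von Mises with concentration κ: κ = 0 gives a
    homogeneous Poisson process, large κ near-perfect locking.
    """
    if rate < 0 or kappa < 0 or not frequency > 0 or not duration > 0:
        raise ValueError("rate/kappa must be >= 0; frequency/duration > 0")
    rng = np.random.default_rng(seed)
    if rate == 0:
        return SpikeTrain(times=np.empty(0), window=(0.0, duration),
                          frequency=frequency)
    lam_max = rate * np.exp(kappa) / i0(kappa)  # spikes/s
    n_cand = rng.poisson(lam_max * duration / 1000.0)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    u = rng.uniform(0.0, 1.0, n_cand)
    arg = 2.0 * np.pi * frequency * cand / 1000.0 - phase
    accept = u < np.exp(kappa * (np.cos(arg) - 1.0))
    return SpikeTrain(times=cand[accept], window=(0.0, duration),
                      frequency=frequency)


def gen_epsc_trace(y0: float, amp: float, x0: float, tau_rise: float,
                   tau_decay: float, noise_sd: float, dt: float,
                   duration: float, seed):
    """(t, y): event-template trace plus iid Gaussian noise.

    The noiseless case is the exact forward model of the event fit, so
    fitting recovers the parameters to solver precision.
    """
    if not tau_rise < tau_decay:
        raise ValueError("need tau_rise < tau_decay")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, duration + dt / 2, dt)
    y = epsc_model(t, y0, amp, x0, tau_rise, tau_decay)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return t, y


def gen_marker_table(n_cells: int, p_only2d: float = None,
                     p_only2c: float = None, p_both: float = None,
                     seed=0, mean_extra_puncta: float = 2.0) -> pd.DataFrame:
    """Random per-cell marker table with given class proportions.

    Each tdTomato+ cell draws its co-expression class from the multinomial
    (p_only2d, p_only2c, p_both, 1 − sum); positive channels receive
    1 + Poisson(``mean_extra_puncta``) puncta, negative channels 0.
    Defaults are the published overall proportions.
    """
    if p_only2d is None:
        p_only2d = DEFAULT_CLASS_PROBS["p_only2d"]
    if p_only2c is None:
        p_only2c = DEFAULT_CLASS_PROBS["p_only2c"]
    if p_both is None:
        p_both = DEFAULT_CLASS_PROBS["p_both"]
    probs = np.array([p_only2d, p_only2c, p_both])
    if (probs < 0).any() or probs.sum() > 1 + 1e-12:
        raise ValueError("class probabilities must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    full = np.append(probs, max(1.0 - probs.sum(), 0.0))
    classes = rng.choice(4, size=n_cells, p=full / full.sum())
    pos2d = (classes == 0) | (classes == 2)
    pos2c = (classes == 1) | (classes == 2)
    puncta2d = np.where(pos2d, 1 + rng.poisson(mean_extra_puncta, n_cells), 0)
    puncta2c = np.where(pos2c, 1 + rng.poisson(mean_extra_puncta, n_cells), 0)
    rows = pd.DataFrame({
        "cell_id": [f"synth_c{i}" for i in range(n_cells)],
        "mouse_id": "synth",
        "slice_id": "synth",
        "subdivision": "unassigned",
        "tdTomato_positive": True,
        "glun2c_puncta": puncta2c,
        "glun2d_puncta": puncta2d,
    }, columns=list(COLUMNS))
    return marker_table(rows)
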