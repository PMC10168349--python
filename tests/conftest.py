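import numpy as np
import pytest
from hypothesis import settings

from icgain import (MembraneParams, SynapseParams, SweepSpec, calibrate_gampa,
                    run_sweep)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# leak values of the sweep experiment, plus the 0.7 mS/cm² reference cell
SWEEP_GLS = (0.282, 0.5, 0.75, 1.99, 5.3)
REFERENCE_GL = 0.7


@pytest.fixture(scope="session")
def membrane():
    return MembraneParams()


@pytest.fixture(scope="session")
def synapse():
    return SynapseParams()


@pytest.fixture(scope="session")
def g_reference(membrane, synapse):
    """Calibrated AMPA strength for the 0.7 mS/cm² reference cell."""
    return calibrate_gampa(membrane.with_leak(REFERENCE_GL), synapse)


@pytest.fixture(scope="session")
def full_sweep(membrane, synapse):
    """The full MTF sweep over all leak values (plus the reference cell),
    both conditions, 16–512 Hz at 4 steps/octave, 1 s trains."""
    spec = SweepSpec(gl_values=SWEEP_GLS + (REFERENCE_GL,))
    return run_sweep(spec, membrane, synapse)


def condition_counts(table, gl):
    """(frequencies, ampa-only counts, ampa+nmda counts) for one leak."""
    sub = table[np.isclose(table["gl_ms_per_cm2"], gl)]
    a = sub[sub["condition"] == "ampa"].sort_values("frequency_hz")
    an = sub[sub["condition"] == "ampa+nmda"].sort_values("frequency_hz")
    return (a["frequency_hz"].to_numpy(),
            a["spikes_per_train"].to_numpy(),
            an["spikes_per_train"].to_numpy())
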