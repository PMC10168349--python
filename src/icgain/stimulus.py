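"""Periodic synaptic input trains and AMPA/NMDA conductance waveforms.

Each presynaptic pulse contributes a peak-normalized double exponential

    g(t) = g_max · N · (1 − e^{−(t−t₀)/τ_rise}) · e^{−(t−t₀)/τ_decay},  t ≥ t₀

where N normalizes a single pulse to peak exactly at ``g_max``; pulses sum
linearly.  Two receptor classes are modelled: a fast AMPA conductance and a
slow NMDA conductance mimicking GluN2C/D-containing receptors — no Mg²⁺
block, so the NMDA conductance is voltage independent and active at rest.
The NMDA peak defaults to 25% of the AMPA peak.

Two summation modes are provided.  :func:`conductance_waveform` sums pulse
contributions linearly — the right model for well-separated events and the
one used for waveform-analysis fixtures.  :func:`saturating_waveform`
scales each pulse by the remaining headroom 1 − s (s = g/g_max), so the
conductance is bounded by g_max however fast the train: this mimics
receptor-pool saturation and is the default drive for simulations
(``SynapseParams.saturating``).  With an unbounded linear sum, the slow
NMDA component accumulates without limit at high input rates and any
parameter choice drives the cell into depolarization block; the bounded
gating reproduces the observed physiology (additive gain in high-resistance
cells, onset responses in low-resistance cells).

The double exponential is a difference of two pure exponentials
(τ_decay and τ_rise·τ_decay/(τ_rise+τ_decay)), so waveforms on a uniform
grid are evaluated exactly with a one-pole recursive filter regardless of
how many pulses overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .neuron import MembraneParams, integrate

__all__ = [
    "SynapseParams",
    "InputTrain",
    "make_train",
    "frequency_grid",
    "peak_normalization",
    "conductance_waveform",
    "saturating_waveform",
    "half_grid",
    "drive_waveforms",
    "calibrate_gampa",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics and strengths of the AMPA and NMDA conductances.

    Defaults: AMPA τ_rise/τ_decay = 0.2/2 ms (fast, typical of auditory
    neurons), NMDA 5/100 ms (GluN2D-like, at the slow end of recorded IC
    NMDA decays), NMDA peak = 25% of the AMPA peak, Esyn = 0 mV.
    """

    gAMPA_max: float = 0.5        # mS/cm², peak of a single AMPA pulse
    nmda_ratio: float = 0.25      # NMDA peak as a fraction of the AMPA peak
    tau_rise_ampa: float = 0.2    # ms
    tau_decay_ampa: float = 2.0   # ms
    tau_rise_nmda: float = 5.0    # ms
    tau_decay_nmda: float = 100.0 # ms
    Esyn: float = 0.0             # mV
    nmda_enabled: bool = True
    saturating: bool = True       # bounded (receptor-pool) gating for drives

    def __post_init__(self) -> None:
        for rise, decay in ((self.tau_rise_ampa, self.tau_decay_ampa),
                            (self.tau_rise_nmda, self.tau_decay_nmda)):
            if not (0 < rise < decay):
                raise ValueError("need 0 < tau_rise < tau_decay")
        if self.nmda_ratio < 0:
            raise ValueError("nmda_ratio must be non-negative")

    @property
    def gNMDA_max(self) -> float:
        if not self.nmda_enabled:
            return 0.0
        return self.nmda_ratio * self.gAMPA_max

    def ampa_only(self) -> "SynapseParams":
        return replace(self, nmda_enabled=False)

    def with_strength(self, gAMPA_max: float) -> "SynapseParams":
        return replace(self, gAMPA_max=gAMPA_max)


@dataclass(frozen=True)
class InputTrain:
    """Pulse onset times (ms) of a periodic input train."""

    onsets: np.ndarray
    frequency: float   # Hz (nominal)
    duration: float    # ms

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and (np.any(np.diff(onsets) <= 0)
                            or onsets[0] < 0 or onsets[-1] > self.duration):
            raise ValueError("onsets must be strictly increasing within "
                             "[0, duration]")


def make_train(frequency: float, duration: float, offset: float = 0.0,
               dt: float | None = None) -> InputTrain:
    """Evenly spaced pulse onsets: floor(duration·f/1000) pulses at period
    1000/f ms starting at ``offset``."""
    if not (frequency > 0 and duration > 0):
        raise ValueError("frequency and duration must be positive")
    period = 1000.0 / frequency
    if dt is not None and period < dt:
        raise ValueError(f"input period {period:g} ms is shorter than the "
                         f"integration step {dt:g} ms")
    n_pulses = int(np.floor(duration * frequency / 1000.0))
    onsets = offset + period * np.arange(n_pulses)
    onsets = onsets[onsets <= duration]
    return InputTrain(onsets=onsets, frequency=frequency, duration=duration)


def frequency_grid(fmin: float, fmax: float,
                   steps_per_octave: int = 4) -> np.ndarray:
    """Geometric frequency grid f_k = fmin·2^{k/steps}, both ends included."""
    if not (0 < fmin < fmax) or steps_per_octave < 1:
        raise ValueError("need fmax > fmin > 0 and steps_per_octave >= 1")
    n_octaves = np.log2(fmax / fmin)
    k = np.arange(int(round(n_octaves * steps_per_octave)) + 1)
    freqs = fmin * 2.0 ** (k / steps_per_octave)
    if not np.isclose(freqs[-1], fmax):
        freqs = np.append(freqs, fmax)
    return freqs


def peak_normalization(tau_rise: float, tau_decay: float):
    """(t*, N): analytic peak time of the unit double exponential and the
    factor N = 1/peak that normalizes a single pulse to amplitude 1."""
    t_star = tau_rise * np.log1p(tau_decay / tau_rise)
    peak = (1.0 - np.exp(-t_star / tau_rise)) * np.exp(-t_star / tau_decay)
    return t_star, 1.0 / peak


def _exp_scan(t: np.ndarray, dt: float, onsets: np.ndarray,
              tau: float) -> np.ndarray:
    """Σ_k e^{−(t−t0_k)/τ}·[t ≥ t0_k] evaluated exactly on the uniform grid.

    Deposits the exact fractional decay factor at the first grid point at or
    after each onset, then propagates with the grid decay ratio; on a
    uniform grid this equals the analytic sum at every point.
    """
    imp = np.zeros(t.size)
    idx = np.searchsorted(t, onsets - 1e-12)
    keep = idx < t.size
    np.add.at(imp, idx[keep], np.exp(-(t[idx[keep]] - onsets[keep]) / tau))
    return lfilter([1.0], [1.0, -np.exp(-dt / tau)], imp)


def _check_uniform(t: np.ndarray) -> float:
    dts = np.diff(t)
    dt = dts[0]
    if not np.allclose(dts, dt):
        raise ValueError("time grid must be uniform")
    return dt


def _weighted_exp_scan(t, dt, onsets, weights, tau):
    imp = np.zeros(t.size)
    idx = np.searchsorted(t, onsets - 1e-12)
    keep = idx < t.size
    np.add.at(imp, idx[keep],
              weights[keep] * np.exp(-(t[idx[keep]] - onsets[keep]) / tau))
    return lfilter([1.0], [1.0, -np.exp(-dt / tau)], imp)


def _pulse_sum(t: np.ndarray, onsets: np.ndarray, g_max: float,
               tau_rise: float, tau_decay: float,
               saturating: bool = False) -> np.ndarray:
    if g_max == 0.0 or onsets.size == 0:
        return np.zeros(t.size)
    dt = _check_uniform(t)
    _, norm = peak_normalization(tau_rise, tau_decay)
    tau2 = tau_rise * tau_decay / (tau_rise + tau_decay)
    if saturating:
        # each pulse is scaled by the headroom 1 − s at its onset, where
        # s = g/g_max just before the pulse; exact recursion over onsets
        w = np.empty(onsets.size)
        slow = fast = 0.0
        prev = 0.0
        for k, t0 in enumerate(onsets):
            if k:
                d = t0 - prev
                slow *= np.exp(-d / tau_decay)
                fast *= np.exp(-d / tau2)
            s = norm * (slow - fast)
            w[k] = max(1.0 - s, 0.0)
            slow += w[k]
            fast += w[k]
            prev = t0
    else:
        w = np.ones(onsets.size)
    slow = _weighted_exp_scan(t, dt, onsets, w, tau_decay)
    fast = _weighted_exp_scan(t, dt, onsets, w, tau2)
    g = g_max * norm * (slow - fast)
    if saturating:
        # pulses landing mid-rise can still overshoot; hard cap at g_max
        np.minimum(g, g_max, out=g)
    return g


def conductance_waveform(train: InputTrain, params: SynapseParams,
                         t: np.ndarray):
    """(gAMPA(t), gNMDA(t)) in mS/cm² on the uniform grid ``t``.

    Pulse contributions sum linearly; a single pulse peaks exactly at the
    receptor's g_max.
    """
    t = np.asarray(t, dtype=float)
    gA = _pulse_sum(t, train.onsets, params.gAMPA_max,
                    params.tau_rise_ampa, params.tau_decay_ampa)
    gN = _pulse_sum(t, train.onsets, params.gNMDA_max,
                    params.tau_rise_nmda, params.tau_decay_nmda)
    return gA, gN


def saturating_waveform(train: InputTrain, params: SynapseParams,
                        t: np.ndarray):
    """Like :func:`conductance_waveform` but with bounded (saturating)
    gating: each pulse is scaled by the remaining headroom 1 − g/g_max at
    its onset, so the conductance never exceeds g_max.  Identical to the
    linear sum for a single pulse or well-separated pulses."""
    t = np.asarray(t, dtype=float)
    gA = _pulse_sum(t, train.onsets, params.gAMPA_max,
                    params.tau_rise_ampa, params.tau_decay_ampa,
                    saturating=True)
    gN = _pulse_sum(t, train.onsets, params.gNMDA_max,
                    params.tau_rise_nmda, params.tau_decay_nmda,
                    saturating=True)
    return gA, gN


def half_grid(duration: float, dt: float) -> np.ndarray:
    """Half-step time grid (2·n_steps + 1 points) used by the integrator."""
    n_steps = int(round(duration / dt))
    return np.arange(2 * n_steps + 1) * (dt / 2.0)


def drive_waveforms(train: InputTrain, params: SynapseParams,
                    duration: float, dt: float):
    """Conductance pair sampled on the integrator's half-step grid,
    saturating or linear per ``params.saturating``."""
    t = half_grid(duration, dt)
    if params.saturating:
        return saturating_waveform(train, params, t)
    return conductance_waveform(train, params, t)


# ---------------------------------------------------------------------------
# Synaptic-strength calibration
# ---------------------------------------------------------------------------

def _spikes_for_strength(g: float, membrane: MembraneParams,
                         synapse: SynapseParams, train: InputTrain,
                         duration: float, dt: float) -> int:
    syn = synapse.with_strength(g)
    drive = drive_waveforms(train, syn, duration, dt)
    res = integrate(membrane, synapse_drive=drive, duration=duration, dt=dt,
                    Esyn=syn.Esyn)
    return res.spike_times.size


def _bisect_threshold(predicate, g_lo: float, g_hi: float,
                      rel_tol: float = 1e-3) -> float:
    """Smallest g in (g_lo, g_hi] with predicate(g) True (monotone in g)."""
    while g_hi / g_lo > 1.0 + rel_tol:
        mid = np.sqrt(g_lo * g_hi)
        if predicate(mid):
            g_hi = mid
        else:
            g_lo = mid
    return g_hi

def calibrate_gampa(membrane: MembraneParams, synapse: SynapseParams,
                    train_frequency: float = 16.0, duration: float = 1000.0,
                    dt: float = 0.01, margin: float = 0.98,
                    g_bracket=(1e-3, 50.0)) -> float:
    """Peak AMPA conductance placing the cell in the summation regime.

    Bisects the threshold strength g_single at which a single AMPA-only
    pulse first elicits a spike and returns ``margin·g_single`` (default
    0.98).  Just below threshold, a lone input produces only an EPSP while
    temporal summation — the slow NMDA component at low rates, AMPA
    overlap at high rates — recruits spiking; the near-threshold placement
    also preserves the onset spike of leaky (low-resistance) cells, whose
    train-onset transient must reach threshold before Na⁺ inactivation
    sets in.  The returned strength is validated to make a 1 s AMPA+NMDA
    train at ``train_frequency`` fire.
    """
    if not 0 < margin < 1:
        raise ValueError("margin must lie in (0, 1)")
    single = InputTrain(onsets=np.array([0.0]), frequency=train_frequency,
                        duration=60.0)
    ampa = synapse.ampa_only()

    def single_spikes(g):
        return _spikes_for_strength(g, membrane, ampa, single, 60.0, dt) > 0

    g_lo, g_hi = g_bracket
    if single_spikes(g_lo) or not single_spikes(g_hi):
        raise RuntimeError("calibration bracket does not straddle threshold")
    g_single = _bisect_threshold(single_spikes, g_lo, g_hi, rel_tol=1e-4)
    g = margin * g_single

    train = make_train(train_frequency, duration)
    both = replace(synapse, nmda_enabled=True)
    if _spikes_for_strength(g, membrane, both, train, duration, dt) == 0:
        raise RuntimeError(
            "calibrated strength does not recruit spiking from a "
            f"{train_frequency:g} Hz AMPA+NMDA train")
    return float(g)
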