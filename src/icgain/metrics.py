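"""Spike detection and response metrics.

Implements the response measures used for modulation-transfer-function
analysis: evoked and spontaneous firing rates, vector strength (mean
resultant length of spike phases relative to the stimulus period), circular
mean phase, and rate dynamic range.  Vector strength is reported as
*undefined* — not zero — unless a train elicits more than 4 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "ResponseMetrics",
    "MIN_SPIKES_FOR_VS",
    "detect_spikes",
    "vector_strength",
    "mean_phase",
    "rates",
    "dynamic_range",
]

# vector strength is only defined when a train elicits > 4 spikes
MIN_SPIKES_FOR_VS = 5


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) with their analysis window."""

    times: np.ndarray
    window: tuple = (0.0, np.inf)   # (start_ms, end_ms)
    frequency: float | None = None  # modulation / input frequency, Hz

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ResponseMetrics:
    evoked_rate: float                # spikes/s over the stimulus window
    spontaneous_rate: float | None    # spikes/s between stimuli; None if no quiet windows
    vector_strength: float | None     # None when the spike-count gate fails
    mean_phase: float | None          # radians in [0, 2π)
    spike_count: int = 0


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = 0.0,
                  lockout: float = 1.0) -> SpikeTrain:
    """One spike per upward threshold crossing, with a refractory lockout.

    The spike time is the linearly interpolated crossing time; crossings
    within ``lockout`` ms of the previous accepted spike are discarded.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage trace must be finite")
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return SpikeTrain(times=np.empty(0), window=(t[0], t[-1]))
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    crossing = t[idx] + frac * (t[idx + 1] - t[idx])
    accepted = [crossing[0]]
    for tc in crossing[1:]:
        if tc - accepted[-1] >= lockout:
            accepted.append(tc)
    return SpikeTrain(times=np.asarray(accepted), window=(t[0], t[-1]))


def _phases(times: np.ndarray, frequency: float,
            t_ref: float = 0.0) -> np.ndarray:
    """Spike phases (radians) relative to cycle start at ``t_ref``.

    Phase 0 corresponds to each input-pulse onset / modulation-cycle start.
    """
    return np.mod(2.0 * np.pi * frequency * (times - t_ref) / 1000.0,
                  2.0 * np.pi)


def vector_strength(spikes: SpikeTrain, frequency: float | None = None,
                    min_spikes: int = MIN_SPIKES_FOR_VS) -> float | None:
    """Mean resultant length of spike phases: VS = |Σ e^{i·2πf·t_k}| / N.

    Returns ``None`` (undefined) when fewer than ``min_spikes`` spikes are
    available — a low-count train carries no usable phase information.
    """
    f = frequency if frequency is not None else spikes.frequency
    if f is None or not f > 0:
        raise ValueError("a positive frequency is required")
    if len(spikes) < min_spikes:
        return None
    ph = _phases(spikes.times, f)
    return float(np.abs(np.exp(1j * ph).mean()))


def mean_phase(spikes: SpikeTrain, frequency: float | None = None,
               min_spikes: int = MIN_SPIKES_FOR_VS) -> float | None:
    """Circular mean phase in [0, 2π); undefined when VS is undefined."""
    f = frequency if frequency is not None else spikes.frequency
    if f is None or not f > 0:
        raise ValueError("a positive frequency is required")
    if len(spikes) < min_spikes:
        return None
    ph = _phases(spikes.times, f)
    resultant = np.exp(1j * ph).mean()
    return float(np.mod(np.angle(resultant), 2.0 * np.pi))


def _window_rates(times: np.ndarray, windows) -> float | None:
    per_window = []
    for start, end in windows:
        if not end > start:
            raise ValueError("zero- or negative-length window")
        count = np.count_nonzero((times >= start) & (times < end))
        per_window.append(count / ((end - start) / 1000.0))
    if not per_window:
        return None
    return float(np.mean(per_window))


def rates(spikes: SpikeTrain, stimulus_windows, quiet_windows=()) :
    """(evoked rate, spontaneous rate) in spikes/s.

    Each rate is the mean of per-window rates across repetitions.  The
    spontaneous rate is ``None`` when no quiet windows are supplied.
    Windows must be disjoint between the two classes.
    """
    stim = [tuple(w) for w in stimulus_windows]
    quiet = [tuple(w) for w in quiet_windows]
    for s in stim:
        for q in quiet:
            if s[0] < q[1] and q[0] < s[1]:
                raise ValueError("stimulus and quiet windows overlap")
    evoked = _window_rates(spikes.times, stim)
    if evoked is None:
        raise ValueError("at least one stimulus window is required")
    spont = _window_rates(spikes.times, quiet)
    return evoked, spont


def dynamic_range(rate_mtf) -> float:
    """Max − min firing rate across a rate modulation transfer function."""
    r = np.asarray(rate_mtf, dtype=float)
    if r.size < 2:
        raise ValueError("dynamic range needs rates at >= 2 frequencies")
    return float(np.max(r) - np.min(r))
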