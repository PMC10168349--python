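"""EPSC/EPSP waveform measurement and fitting.

Synaptic events are summarized by a product-of-exponentials fit

    f(x) = y0 + amp · (1 − e^{−(x−x0)/τ_rise}) · e^{−(x−x0)/τ_decay}

(f ≡ y0 for x < x0) and by direct waveform metrics: amplitude from a
pre-event baseline, halfwidth at half amplitude, 10–90% rise time, and a
single-exponential decay time constant.  Train responses are quantified by
per-peak amplitudes measured from the pre-train baseline and by the area
under the curve — the measures used to detect temporal summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EPSCFit",
    "WaveformMetrics",
    "TrainSummation",
    "FitError",
    "epsc_model",
    "fit_epsc",
    "measure_waveform",
    "average_sweeps",
    "summation_metrics",
    "lowpass_filter",
]


class FitError(RuntimeError):
    """Raised when an event fit cannot be performed or fails to converge."""


@dataclass(frozen=True)
class EPSCFit:
    y0: float         # baseline (pA or mV)
    amp: float        # amplitude scale; sign encodes polarity
    x0: float         # onset time (ms)
    tau_rise: float   # ms
    tau_decay: float  # ms
    residual: float   # RMS residual of the fit

    def __call__(self, x):
        return epsc_model(np.asarray(x, dtype=float), self.y0, self.amp,
                          self.x0, self.tau_rise, self.tau_decay)


@dataclass(frozen=True)
class WaveformMetrics:
    amplitude: float          # extremum − baseline mean (signed)
    halfwidth: float | None   # ms; None when no half-amplitude crossings
    rise_time: float          # ms, 10→90% by default
    decay_tau: float          # ms, single-exponential fit from the peak


@dataclass(frozen=True)
class TrainSummation:
    peak_amplitudes: np.ndarray  # per pulse, from the pre-train baseline
    auc: float                   # trapezoidal area of (trace − baseline)


def epsc_model(x, y0, amp, x0, tau_rise, tau_decay):
    """The event template; zero contribution before onset ``x0``."""
    dx = np.maximum(x - x0, 0.0)
    rise = -np.expm1(-dx / tau_rise)
    return y0 + amp * rise * np.exp(-dx / tau_decay) * (x >= x0)


def fit_epsc(t, y, onset_guess: float | None = None) -> EPSCFit:
    """Least-squares fit of the event template to a monophasic trace.

    Initialization: baseline from the pre-onset segment, amplitude from the
    extremum, τ_rise = 1 ms, τ_decay from the time to half decay.  Bounded
    (both taus positive); raises :class:`FitError` for flat traces or
    non-convergence rather than returning a degenerate fit.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.size < 6:
        raise ValueError("t and y must be equal-length vectors (n >= 6)")

    if onset_guess is None:
        onset_guess = t[0] + 0.1 * (t[-1] - t[0])
    pre = y[t < onset_guess]
    y0_init = float(np.mean(pre)) if pre.size else float(y[0])
    dev = y - y0_init
    peak_idx = int(np.argmax(np.abs(dev)))
    amp_init = float(dev[peak_idx])
    if abs(amp_init) < 1e-12 or np.ptp(y) < 1e-12:
        raise FitError("flat or zero-amplitude trace; nothing to fit")

    # time from the peak to half decay initializes tau_decay
    post = dev[peak_idx:]
    below = np.nonzero(np.abs(post) <= abs(amp_init) / 2)[0]
    if below.size:
        tau_d_init = max(float(t[peak_idx + below[0]] - t[peak_idx]), 0.5)
    else:
        tau_d_init = max(float(t[-1] - t[peak_idx]), 0.5)

    p0 = [y0_init, amp_init, float(onset_guess), 1.0, tau_d_init]
    span = t[-1] - t[0]
    lower = [-np.inf, -np.inf, t[0] - span, 1e-4, 1e-3]
    upper = [np.inf, np.inf, t[-1], 10.0 * span, 100.0 * span]
    try:
        popt, _ = curve_fit(epsc_model, t, y, p0=p0, bounds=(lower, upper),
                            maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"event fit did not converge: {err}") from err
    resid = float(np.sqrt(np.mean((epsc_model(t, *popt) - y) ** 2)))
    return EPSCFit(y0=float(popt[0]), amp=float(popt[1]), x0=float(popt[2]),
                   tau_rise=float(popt[3]), tau_decay=float(popt[4]),
                   residual=resid)


def _crossing_times(t, y, level, rising: bool):
    """Linearly interpolated times where y crosses ``level``."""
    y = np.asarray(y)
    if rising:
        idx = np.nonzero((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        idx = np.nonzero((y[:-1] >= level) & (y[1:] < level))[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (level - y[idx]) / (y[idx + 1] - y[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def measure_waveform(t, y, baseline_window=(0.0, 5.0),
                     polarity: str = "auto",
                     rise_fractions=(0.1, 0.9)) -> WaveformMetrics:
    """Direct metrics of a monophasic event.

    amplitude: extremum − baseline mean (signed).  halfwidth: interval
    between the half-amplitude crossings flanking the peak (None when the
    trace never returns to half amplitude).  rise time: interval between
    the ``rise_fractions`` amplitude crossings before the peak (10–90% by
    default; pass (0.2, 0.8) for 20–80%).  decay_tau: single-exponential
    least-squares fit from the peak to the return toward baseline.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    b0, b1 = baseline_window
    base_mask = (t >= b0) & (t < b1)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(y[base_mask].mean())
    dev = y - baseline
    if polarity == "auto":
        sign = 1.0 if np.max(dev) >= -np.min(dev) else -1.0
    elif polarity in ("positive", "+"):
        sign = 1.0
    elif polarity in ("negative", "-"):
        sign = -1.0
    else:
        raise ValueError("polarity must be 'auto', 'positive' or 'negative'")
    v = sign * dev  # positive-going event
    peak_idx = int(np.argmax(v))
    amp = float(v[peak_idx])

    half = amp / 2.0
    up = _crossing_times(t[:peak_idx + 1], v[:peak_idx + 1], half, True)
    down = _crossing_times(t[peak_idx:], v[peak_idx:], half, False)
    halfwidth = float(down[0] - up[-1]) if up.size and down.size else None

    lo, hi = rise_fractions
    t_lo = _crossing_times(t[:peak_idx + 1], v[:peak_idx + 1], lo * amp, True)
    t_hi = _crossing_times(t[:peak_idx + 1], v[:peak_idx + 1], hi * amp, True)
    rise_time = float(t_hi[-1] - t_lo[-1]) if t_lo.size and t_hi.size else np.nan

    # decay: fit v = amp·e^{−(t−t_peak)/τ} down to 10% of the peak
    post = slice(peak_idx, None)
    vp, tp = v[post], t[post]
    end = np.nonzero(vp <= 0.1 * amp)[0]
    stop = end[0] + 1 if end.size else vp.size
    vp, tp = vp[:stop], tp[:stop]
    keep = vp > 0
    if keep.sum() >= 3:
        slope, intercept = np.polyfit(tp[keep] - tp[0], np.log(vp[keep]), 1)
        decay_tau = float(-1.0 / slope) if slope < 0 else np.nan
    else:
        decay_tau = np.nan
    return WaveformMetrics(amplitude=sign * amp, halfwidth=halfwidth,
                           rise_time=rise_time, decay_tau=decay_tau)


def average_sweeps(sweeps) -> np.ndarray:
    """Pointwise mean of equally sampled sweeps (rows)."""
    arrs = [np.asarray(s, dtype=float) for s in sweeps]
    if not arrs:
        raise ValueError("no sweeps to average")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("sweeps differ in length")
    return np.mean(np.vstack(arrs), axis=0)


def summation_metrics(t, y, pulse_onsets, baseline_window,
                      post_window: float | None = None,
                      polarity: str = "auto") -> TrainSummation:
    """Per-peak amplitudes and AUC of a pulse-train response.

    Peak k is the extremum of the trace within [onset_k, onset_{k+1})
    (the last window extends ``post_window`` ms past the final onset,
    default one inter-pulse interval), measured from the pre-train baseline
    mean.  AUC is the trapezoidal integral of (trace − baseline) from the
    first onset to the end of the last window.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    onsets = np.sort(np.asarray(pulse_onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("a train needs at least 2 pulses")
    b0, b1 = baseline_window
    base_mask = (t >= b0) & (t < b1)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(y[base_mask].mean())
    if polarity == "auto":
        dev = y - baseline
        sign = 1.0 if np.max(dev) >= -np.min(dev) else -1.0
    else:
        sign = 1.0 if polarity in ("positive", "+") else -1.0

    ipi = float(np.median(np.diff(onsets)))
    end_time = onsets[-1] + (post_window if post_window is not None else ipi)
    edges = np.append(onsets, end_time)
    peaks = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t >= a) & (t < b)
        if not mask.any():
            raise ValueError("a pulse window contains no samples")
        peaks.append(sign * np.max(sign * (y[mask] - baseline)))
    auc_mask = (t >= onsets[0]) & (t <= end_time)
    auc = float(np.trapezoid(y[auc_mask] - baseline, t[auc_mask]))
    return TrainSummation(peak_amplitudes=np.asarray(peaks), auc=auc)


def lowpass_filter(t, y, cutoff_khz: float = 3.0, order: int = 4):
    """Zero-phase Butterworth low-pass, cutoff in kHz (time in ms)."""
    t = np.asarray(t, dtype=float)
    fs_khz = 1.0 / np.median(np.diff(t))  # samples per ms = kHz
    sos = butter(order, cutoff_khz, fs=fs_khz, output="sos")
    return sosfiltfilt(sos, np.asarray(y, dtype=float))
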