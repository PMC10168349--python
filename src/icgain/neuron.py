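"""Single-compartment conductance-based model neuron.

The cell is a Wang–Buzsáki-type fast-spiking neuron: transient Na⁺ and
delayed-rectifier K⁺ conductances with Hodgkin–Huxley kinetics, a passive
leak, and an excitatory synaptic conductance supplied externally.  The
membrane equation is

    Cm dV/dt = −INa − IK − IL − Isyn + Iapp

with INa = gNa·m∞³·h·(V−ENa), IK = gK·n⁴·(V−EK), IL = gL·(V−EL).  Na⁺
activation m is instantaneous (replaced by its steady state m∞); the h and
n gates follow first-order kinetics scaled by the dimensionless rate factor
φ.  Leak conductance gL is the knob for membrane resistance, mimicking the
diversity of input resistances found across inferior colliculus neurons.

Units are fixed throughout: mV, ms, mS/cm², μA/cm², μF/cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "NeuronState",
    "SimulationResult",
    "IntegrationError",
    "rate_functions",
    "m_inf",
    "gate_steady_state",
    "derivatives",
    "rest_state",
    "integrate",
    "membrane_resistance",
]


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneParams:
    """Passive and active membrane parameters (densities per cm²).

    Defaults are the fast-spiking interneuron values: Cm = 1 μF/cm²,
    gNa = 35 mS/cm² (ENa = 55 mV), gK = 9 mS/cm² (EK = −90 mV),
    EL = −65 mV, φ = 5.  ``gL`` defaults to 0.7 mS/cm², which for a 15 μm
    spherical soma corresponds to ~200 MΩ input resistance.
    """

    Cm: float = 1.0          # μF/cm²
    gNa: float = 35.0        # mS/cm²
    ENa: float = 55.0        # mV
    gK: float = 9.0          # mS/cm²
    EK: float = -90.0        # mV
    gL: float = 0.7          # mS/cm²
    EL: float = -65.0        # mV
    phi: float = 5.0         # dimensionless gating rate scale
    diameter: float = 15.0   # μm, soma modelled as a sphere

    def __post_init__(self) -> None:
        if not (self.Cm > 0):
            raise ValueError("Cm must be positive")
        if self.gNa < 0 or self.gK < 0 or self.gL < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.diameter > 0):
            raise ValueError("diameter must be positive")
        if not (self.ENa > self.EK):
            raise ValueError("ENa must exceed EK")

    def with_leak(self, gL: float) -> "MembraneParams":
        """Copy of the parameters with a different leak conductance."""
        return replace(self, gL=gL)


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous dynamical state: V (mV) and the h, n gates in [0, 1]."""

    V: float
    h: float
    n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0 and 0.0 <= self.n <= 1.0):
            raise ValueError("gating variables must lie in [0, 1]")


@dataclass
class SimulationResult:
    """Output of :func:`integrate` on a uniform time grid."""

    t: np.ndarray        # ms
    V: np.ndarray        # mV
    h: np.ndarray
    n: np.ndarray
    g_syn: np.ndarray    # total synaptic conductance on the grid, mS/cm²
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    dt: float = 0.0

    def to_table(self) -> np.ndarray:
        """Columns (time_ms, V_mV, h, n, gsyn_mS_cm2) for delimited output."""
        return np.column_stack([self.t, self.V, self.h, self.n, self.g_syn])

    def save(self, path, spikes_path=None) -> None:
        np.savetxt(path, self.to_table(), delimiter="\t",
                   header="time_ms\tV_mV\th\tn\tgsyn_mS_cm2", comments="")
        if spikes_path is not None:
            np.savetxt(spikes_path, self.spike_times.reshape(-1, 1),
                       delimiter="\t", header="spike_time_ms", comments="")


class IntegrationError(RuntimeError):
    """Raised when the membrane potential becomes non-finite."""

    def __init__(self, t_fail: float):
        self.t_fail = t_fail
        super().__init__(f"membrane potential became non-finite at t = {t_fail:g} ms")


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def _ratio_expm1(u):
    """u / (1 − e^{−u}) with the removable singularity at u = 0 filled in."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-7
    # second-order series keeps the branch continuous at the switch point
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 + u / 2.0 + u * u / 12.0,
                   safe / -np.expm1(-safe))
    return out


def rate_functions(V):
    """Voltage-dependent transition rates (per ms) of the m, h, n gates.

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.
    Accepts scalars or arrays.  The 0/0 points of αm (V = −35 mV) and
    αn (V = −34 mV) evaluate to their finite limits (1.0 and 0.1).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    alpha_m = _ratio_expm1(0.1 * (V + 35.0))
    beta_m = 4.0 * np.exp(-(V + 60.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 58.0) / 20.0)
    beta_h = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    alpha_n = 0.1 * _ratio_expm1(0.1 * (V + 34.0))
    beta_n = 0.125 * np.exp(-(V + 44.0) / 80.0)
    if V.ndim == 0:
        return tuple(float(x) for x in
                     (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n))
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def m_inf(V):
    """Steady-state Na⁺ activation m∞ = αm/(αm+βm); monotone in V, in [0, 1]."""
    am, bm, *_ = rate_functions(V)
    return am / (am + bm)


def gate_steady_state(V):
    """Steady-state values (m∞, h∞, n∞) at voltage ``V``."""
    am, bm, ah, bh, an, bn = rate_functions(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def derivatives(state: NeuronState, params: MembraneParams,
                Isyn: float = 0.0, Iapp: float = 0.0):
    """Time derivatives (dV/dt, dh/dt, dn/dt) at a given state.

    ``Isyn`` is the synaptic current in μA/cm² (positive = outward, i.e. it
    enters the membrane equation with a minus sign, so an excitatory
    conductance g·(V−Esyn) with V < Esyn yields Isyn < 0 and depolarizes).
    """
    V, h, n = state.V, state.h, state.n
    am, bm, ah, bh, an, bn = rate_functions(V)
    m = am / (am + bm)
    INa = params.gNa * m ** 3 * h * (V - params.ENa)
    IK = params.gK * n ** 4 * (V - params.EK)
    IL = params.gL * (V - params.EL)
    dV = (-INa - IK - IL - Isyn + Iapp) / params.Cm
    dh = params.phi * (ah * (1.0 - h) - bh * h)
    dn = params.phi * (an * (1.0 - n) - bn * n)
    return dV, dh, dn


def rest_state(params: MembraneParams) -> NeuronState:
    """Resting state solved from the full steady-state condition.

    Finds V_rest with h = h∞(V), n = n∞(V) and total membrane current zero,
    by root-finding on the steady-state I–V curve between EK and ENa.
    """

    def net_current(V: float) -> float:
        m, h, n = gate_steady_state(V)
        return -(params.gNa * m ** 3 * h * (V - params.ENa)
                 + params.gK * n ** 4 * (V - params.EK)
                 + params.gL * (V - params.EL))

    # bracket the rest point on a coarse scan below spike threshold
    grid = np.linspace(params.EK + 1e-6, -40.0, 200)
    vals = [net_current(v) for v in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            V0 = float(lo)
            break
        if flo * fhi < 0:
            V0 = brentq(net_current, lo, hi, xtol=1e-10)
            break
    else:
        raise RuntimeError("no resting state found below -40 mV")
    _, h0, n0 = gate_steady_state(V0)
    return NeuronState(V=float(V0), h=float(h0), n=float(n0))


# ---------------------------------------------------------------------------
# Fixed-step RK4 integration (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rates_scalar(V):
    u = 0.1 * (V + 35.0)
    if abs(u) < 1e-7:
        am = 1.0 + u / 2.0 + u * u / 12.0
    else:
        am = u / (1.0 - np.exp(-u))
    bm = 4.0 * np.exp(-(V + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 58.0) / 20.0)
    bh = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    w = 0.1 * (V + 34.0)
    if abs(w) < 1e-7:
        an = 0.1 * (1.0 + w / 2.0 + w * w / 12.0)
    else:
        an = 0.1 * w / (1.0 - np.exp(-w))
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _deriv_scalar(V, h, n, gsyn, Esyn, Iapp,
                  Cm, gNa, ENa, gK, EK, gL, EL, phi):
    am, bm, ah, bh, an, bn = _rates_scalar(V)
    m = am / (am + bm)
    INa = gNa * m * m * m * h * (V - ENa)
    IK = gK * n * n * n * n * (V - EK)
    IL = gL * (V - EL)
    Isyn = gsyn * (V - Esyn)
    dV = (-INa - IK - IL - Isyn + Iapp) / Cm
    dh = phi * (ah * (1.0 - h) - bh * h)
    dn = phi * (an * (1.0 - n) - bn * n)
    return dV, dh, dn


@njit(cache=True)
def _rk4_loop(V0, h0, n0, gsyn_half, Iapp_half, Esyn, dt, n_steps,
              Cm, gNa, ENa, gK, EK, gL, EL, phi):
    """RK4 over n_steps; gsyn/Iapp sampled on the half-step grid (2n+1 pts).

    Returns (V, h, n, fail_index); fail_index = −1 on success, else the step
    at which V became non-finite.
    """
    V = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    n = np.empty(n_steps + 1)
    V[0], h[0], n[0] = V0, h0, n0
    for i in range(n_steps):
        v, hh, nn = V[i], h[i], n[i]
        g0 = gsyn_half[2 * i]
        g1 = gsyn_half[2 * i + 1]
        g2 = gsyn_half[2 * i + 2]
        I0 = Iapp_half[2 * i]
        I1 = Iapp_half[2 * i + 1]
        I2 = Iapp_half[2 * i + 2]
        k1v, k1h, k1n = _deriv_scalar(v, hh, nn, g0, Esyn, I0,
                                      Cm, gNa, ENa, gK, EK, gL, EL, phi)
        k2v, k2h, k2n = _deriv_scalar(v + 0.5 * dt * k1v, hh + 0.5 * dt * k1h,
                                      nn + 0.5 * dt * k1n, g1, Esyn, I1,
                                      Cm, gNa, ENa, gK, EK, gL, EL, phi)
        k3v, k3h, k3n = _deriv_scalar(v + 0.5 * dt * k2v, hh + 0.5 * dt * k2h,
                                      nn + 0.5 * dt * k2n, g1, Esyn, I1,
                                      Cm, gNa, ENa, gK, EK, gL, EL, phi)
        k4v, k4h, k4n = _deriv_scalar(v + dt * k3v, hh + dt * k3h,
                                      nn + dt * k3n, g2, Esyn, I2,
                                      Cm, gNa, ENa, gK, EK, gL, EL, phi)
        V[i + 1] = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        h[i + 1] = hh + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        n[i + 1] = nn + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        if not np.isfinite(V[i + 1]):
            return V, h, n, i + 1
    return V, h, n, -1


def _as_half_grid(x, n_half: int, name: str) -> np.ndarray:
    if x is None:
        return np.zeros(n_half)
    if np.isscalar(x):
        return np.full(n_half, float(x))
    x = np.asarray(x, dtype=float)
    if x.shape != (n_half,):
        raise ValueError(
            f"{name} must be a scalar or an array of length {n_half} "
            "(the half-step grid 2*n_steps+1)")
    return x


def integrate(params: MembraneParams,
              synapse_drive=None,
              Iapp=0.0,
              duration: float = 1000.0,
              dt: float = 0.01,
              initial="steady",
              Esyn: float = 0.0,
              spike_threshold: float = 0.0) -> SimulationResult:
    """Integrate the membrane equation with fixed-step RK4.

    Parameters
    ----------
    synapse_drive
        ``None``, or a pair ``(gAMPA, gNMDA)`` of conductance arrays
        (mS/cm²) sampled on the half-step grid of ``2*n_steps + 1`` points
        spaced ``dt/2`` apart (see :func:`icgain.stimulus.half_grid`).
    Iapp
        Applied current (μA/cm²): scalar or half-step-grid array.
    initial
        ``"steady"`` (relax to the root-found rest state) or a
        :class:`NeuronState`.

    The integration is deterministic; halving ``dt`` at default settings
    leaves spike counts unchanged and moves spike times by < 0.1 ms.
    """
    if not (dt > 0 and duration > 0):
        raise ValueError("dt and duration must be positive")
    n_steps = int(round(duration / dt))
    n_half = 2 * n_steps + 1
    if synapse_drive is None:
        g_half = np.zeros(n_half)
    else:
        gA = _as_half_grid(synapse_drive[0], n_half, "gAMPA")
        gN = _as_half_grid(synapse_drive[1], n_half, "gNMDA")
        g_half = gA + gN
    Iapp_half = _as_half_grid(Iapp, n_half, "Iapp")

    if initial == "steady":
        state = rest_state(params)
    elif isinstance(initial, NeuronState):
        state = initial
    else:
        raise ValueError("initial must be 'steady' or a NeuronState")

    V, h, n = _run_kernel(params, state, g_half, Iapp_half, Esyn, dt, n_steps)
    t = np.arange(n_steps + 1) * dt
    g_full = g_half[::2]
    # local import: metrics is a lower layer with no dependency on this module
    from .metrics import detect_spikes
    spikes = detect_spikes(t, V, threshold=spike_threshold).times
    return SimulationResult(t=t, V=V, h=h, n=n, g_syn=g_full,
                            spike_times=spikes, dt=dt)


def _run_kernel(params, state, g_half, Iapp_half, Esyn, dt, n_steps):
    V, h, n, fail = _rk4_loop(state.V, state.h, state.n, g_half, Iapp_half,
                              float(Esyn), float(dt), n_steps,
                              params.Cm, params.gNa, params.ENa, params.gK,
                              params.EK, params.gL, params.EL, params.phi)
    if fail >= 0:
        raise IntegrationError(fail * dt)
    return V, h, n


# ---------------------------------------------------------------------------
# Passive-property conversion
# ---------------------------------------------------------------------------

def membrane_resistance(gL: float, diameter: float = 15.0) -> float:
    """Input resistance (MΩ) of a spherical soma from its leak density.

    R = 1 / (gL · A) with surface area A = π·d².  For d = 15 μm this maps
    gL = 0.282, 0.50, 0.75, 1.99, 5.3 mS/cm² onto 502, 283, 189, 71 and
    27 MΩ (nearest integer).
    """
    if not (gL > 0 and diameter > 0):
        raise ValueError("gL and diameter must be positive")
    area_cm2 = np.pi * (diameter * 1e-4) ** 2     # μm → cm
    conductance_S = gL * 1e-3 * area_cm2          # mS → S
    return 1.0 / conductance_S / 1e6              # Ω → MΩ
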