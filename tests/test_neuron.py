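"""Model-neuron unit tests: gating kinetics, membrane equation, integration
accuracy, and the leak-to-resistance conversion."""

import numpy as np
import pytest

from icgain.neuron import (IntegrationError, MembraneParams, NeuronState,
                           derivatives, gate_steady_state, integrate, m_inf,
                           membrane_resistance, rate_functions, rest_state)

# independent closed-form evaluation of the six printed rate formulas at
# V = -65 mV (17 significant digits, frozen from a symbolic computation)
RATES_AT_MINUS_65 = (
    0.15718708947376786,    # alpha_m
    5.2807711537364810,     # beta_m
    0.099334728401528007,   # alpha_h
    0.024127021417669201,   # beta_h
    0.014624054743978894,   # alpha_n
    0.16252205852106139,    # beta_n
)


class TestRateFunctions:
    def test_removable_singularities_are_finite_limits(self):
        am, *_ = rate_functions(-35.0)
        assert am == pytest.approx(1.0, abs=1e-12)
        an = rate_functions(-34.0)[4]
        assert an == pytest.approx(0.1, abs=1e-12)
        # continuous across the singular points
        for v0, idx, lim in ((-35.0, 0, 1.0), (-34.0, 4, 0.1)):
            near = rate_functions(v0 + 1e-6)[idx]
            assert near == pytest.approx(lim, rel=1e-5)

    def test_beta_m_at_minus_60(self):
        assert rate_functions(-60.0)[1] == pytest.approx(4.0, abs=1e-12)

    def test_full_rate_vector_at_minus_65(self):
        assert rate_functions(-65.0) == pytest.approx(RATES_AT_MINUS_65,
                                                      rel=1e-12)

    def test_rates_nonnegative_and_finite_on_grid(self):
        rates = rate_functions(np.linspace(-120.0, 60.0, 3601))
        for r in rates:
            assert np.all(np.isfinite(r))
            assert np.all(r >= 0)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            rate_functions(np.nan)


class TestMInf:
    def test_limits(self):
        assert m_inf(200.0) == pytest.approx(1.0, abs=1e-6)
        assert m_inf(-200.0) == pytest.approx(0.0, abs=1e-6)

    def test_value_at_minus_35(self):
        # alpha_m = 1, beta_m = 4 e^{-25/18}
        expected = 1.0 / (1.0 + 4.0 * np.exp(-25.0 / 18.0))
        assert m_inf(-35.0) == pytest.approx(expected, rel=1e-12)
        assert m_inf(-35.0) == pytest.approx(0.50064863157839030, rel=1e-12)

    def test_monotone_in_voltage(self):
        v = np.linspace(-100.0, 40.0, 1401)
        m = m_inf(v)
        assert np.all(np.diff(m) >= 0)


class TestDerivatives:
    def test_rest_state_is_fixed_point(self, membrane):
        rest = rest_state(membrane)
        dV, dh, dn = derivatives(rest, membrane)
        assert abs(dV) < 1e-7
        assert abs(dh) < 1e-12 and abs(dn) < 1e-12

    def test_excitatory_conductance_depolarizes(self, membrane):
        rest = rest_state(membrane)
        base, *_ = derivatives(rest, membrane)
        # excitatory current at V < Esyn=0: Isyn = g (V - 0) < 0
        g = 0.1
        driven, *_ = derivatives(rest, membrane, Isyn=g * (rest.V - 0.0))
        assert driven > base

    def test_el_not_fixed_point_of_full_model(self, membrane):
        # active conductances shift rest slightly away from EL
        m, h, n = gate_steady_state(membrane.EL)
        dV, _, _ = derivatives(NeuronState(membrane.EL, h, n), membrane)
        assert dV != pytest.approx(0.0, abs=1e-6)


class TestIntegrate:
    def test_passive_limit_matches_rc_solution(self):
        # gNa = gK = 0: C dV/dt = -gL (V - EL) + I, charging toward
        # EL + I/gL with time constant C/gL
        p = MembraneParams(gNa=0.0, gK=0.0, gL=0.5, EL=-65.0)
        I = 2.0
        res = integrate(p, Iapp=I, duration=50.0, dt=0.01,
                        initial=NeuronState(-65.0, 0.5, 0.5))
        tau = p.Cm / p.gL
        target = p.EL + I / p.gL
        analytic = target + (p.EL - target) * np.exp(-res.t / tau)
        assert np.max(np.abs(res.V - analytic) / np.abs(analytic)) < 1e-6

    def test_no_drive_stays_at_rest(self, membrane):
        rest = rest_state(membrane)
        res = integrate(membrane, duration=500.0, dt=0.01)
        assert res.spike_times.size == 0
        assert abs(res.V[-1] - rest.V) < 0.5

    def test_tonic_spiking_above_rheobase(self, membrane):
        res = integrate(membrane, Iapp=12.0, duration=800.0, dt=0.01)
        isi = np.diff(res.spike_times[res.spike_times > 100.0])
        assert isi.size > 10
        assert isi.std() / isi.mean() < 1e-3

    def test_deterministic(self, membrane):
        a = integrate(membrane, Iapp=12.0, duration=200.0, dt=0.01)
        b = integrate(membrane, Iapp=12.0, duration=200.0, dt=0.01)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_gates_bounded(self, membrane):
        res = integrate(membrane, Iapp=15.0, duration=500.0, dt=0.01)
        for g in (res.h, res.n):
            assert g.min() >= -1e-9
            assert g.max() <= 1.0 + 1e-9

    def test_recovers_after_subthreshold_pulse(self, membrane):
        rest = rest_state(membrane)
        n_half = 2 * 50000 + 1
        Iapp = np.zeros(n_half)
        # 5 ms, 3 uA/cm^2 pulse at t = 100 ms (half-grid spacing dt/2)
        Iapp[int(100 / 0.005):int(105 / 0.005)] = 3.0
        res = integrate(membrane, Iapp=Iapp, duration=500.0, dt=0.01)
        assert res.spike_times.size == 0
        assert abs(res.V[-1] - rest.V) < 0.5

    def test_blowup_reported_with_time(self, membrane):
        with pytest.raises(IntegrationError) as err:
            integrate(membrane, Iapp=1e9, duration=10.0, dt=0.5)
        assert err.value.t_fail <= 10.0

    def test_invalid_grid_rejected(self, membrane):
        with pytest.raises(ValueError):
            integrate(membrane, duration=-1.0)
        with pytest.raises(ValueError):
            integrate(membrane, Iapp=np.zeros(7), duration=10.0, dt=0.01)


class TestMembraneResistance:
    @pytest.mark.parametrize("gl, expected", [
        (0.282, 502), (0.50, 283), (0.75, 189), (1.99, 71), (5.3, 27)])
    def test_printed_values(self, gl, expected):
        assert round(membrane_resistance(gl, 15.0)) == expected

    def test_reciprocal_in_gl(self):
        assert membrane_resistance(1.0, 15.0) == pytest.approx(
            2.0 * membrane_resistance(2.0, 15.0), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            membrane_resistance(0.0, 15.0)
        with pytest.raises(ValueError):
            membrane_resistance(1.0, -1.0)


class TestParamValidation:
    def test_defaults_are_canonical(self):
        p = MembraneParams()
        assert (p.Cm, p.gNa, p.ENa, p.gK, p.EK, p.EL) == \
            (1.0, 35.0, 55.0, 9.0, -90.0, -65.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MembraneParams(Cm=0.0)
        with pytest.raises(ValueError):
            MembraneParams(gNa=-1.0)
        with pytest.raises(ValueError):
            MembraneParams(ENa=-100.0)  # below EK
        with pytest.raises(ValueError):
            NeuronState(V=-65.0, h=1.5, n=0.0)
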