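"""Input trains, conductance waveforms (linear and saturating), and the
synaptic-strength calibration."""

import numpy as np
import pytest

from icgain.neuron import integrate
from icgain.stimulus import (InputTrain, SynapseParams, conductance_waveform,
                             drive_waveforms, frequency_grid, half_grid,
                             make_train, peak_normalization,
                             saturating_waveform)


class TestMakeTrain:
    def test_16hz_one_second(self):
        tr = make_train(16.0, 1000.0)
        assert tr.onsets.size == 16
        assert np.allclose(tr.onsets, 62.5 * np.arange(16))

    def test_512hz_one_second(self):
        assert make_train(512.0, 1000.0).onsets.size == 512

    def test_floor_rule(self):
        assert make_train(100.0, 55.0).onsets.size == 5

    def test_period_below_dt_rejected(self):
        with pytest.raises(ValueError):
            make_train(2e5, 100.0, dt=0.01)

    def test_invalid_onsets_rejected(self):
        with pytest.raises(ValueError):
            InputTrain(onsets=np.array([5.0, 1.0]), frequency=1.0,
                       duration=10.0)


class TestFrequencyGrid:
    def test_standard_grid(self):
        f = frequency_grid(16.0, 512.0, 4)
        assert f.size == 21
        assert f[0] == pytest.approx(16.0)
        assert f[-1] == pytest.approx(512.0)

    def test_single_octave(self):
        assert frequency_grid(16.0, 32.0, 1) == pytest.approx([16.0, 32.0])

    def test_constant_ratio(self):
        f = frequency_grid(16.0, 512.0, 4)
        assert np.allclose(np.diff(np.log2(f)), 0.25)


class TestConductanceWaveform:
    def test_single_pulse_peaks_at_gmax(self):
        syn = SynapseParams(gAMPA_max=0.3)
        train = InputTrain(onsets=np.array([5.0]), frequency=16.0,
                           duration=50.0)
        t = np.arange(0.0, 50.0, 0.0005)
        gA, gN = conductance_waveform(train, syn, t)
        assert gA.max() == pytest.approx(syn.gAMPA_max, rel=1e-6)
        assert gN.max() == pytest.approx(syn.gNMDA_max, rel=1e-4)

    def test_nmda_ratio_zero_gives_flat_nmda(self):
        syn = SynapseParams(nmda_ratio=0.0)
        train = make_train(64.0, 200.0)
        _, gN = conductance_waveform(train, syn, np.arange(0, 200, 0.01))
        assert np.all(gN == 0.0)

    def test_linearity_of_two_pulse_train(self):
        syn = SynapseParams(gAMPA_max=0.2)
        t = np.arange(0.0, 120.0, 0.01)
        both = InputTrain(onsets=np.array([10.0, 11.0]), frequency=1.0,
                          duration=120.0)
        first = InputTrain(onsets=np.array([10.0]), frequency=1.0,
                           duration=120.0)
        second = InputTrain(onsets=np.array([11.0]), frequency=1.0,
                            duration=120.0)
        for component in range(2):
            g_both = conductance_waveform(both, syn, t)[component]
            g_sum = (conductance_waveform(first, syn, t)[component]
                     + conductance_waveform(second, syn, t)[component])
            assert np.allclose(g_both, g_sum, rtol=1e-12, atol=1e-15)

    def test_two_close_pulses_match_analytic_superposition(self):
        # slow decay, 1 ms apart: compare against brute-force evaluation of
        # the two-term closed form on a dense grid
        syn = SynapseParams(gAMPA_max=1.0, tau_rise_ampa=0.5,
                            tau_decay_ampa=50.0)
        onsets = np.array([10.0, 11.0])
        train = InputTrain(onsets=onsets, frequency=1.0, duration=300.0)
        t = np.arange(0.0, 300.0, 0.001)
        gA, _ = conductance_waveform(train, syn, t)
        _, norm = peak_normalization(0.5, 50.0)

        def unit(dt_):
            dt_ = np.maximum(dt_, 0.0)
            return ((1 - np.exp(-dt_ / 0.5)) * np.exp(-dt_ / 50.0)
                    * (dt_ > 0))

        brute = norm * (unit(t - 10.0) + unit(t - 11.0))
        assert np.max(gA) == pytest.approx(np.max(brute), rel=1e-6)
        assert np.allclose(gA, brute, atol=1e-9)

    def test_waveform_nonnegative(self):
        syn = SynapseParams()
        train = make_train(512.0, 500.0)
        gA, gN = conductance_waveform(train, syn, np.arange(0, 500, 0.01))
        assert gA.min() >= 0 and gN.min() >= 0

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(tau_rise_ampa=3.0, tau_decay_ampa=2.0)


class TestPeakNormalization:
    def test_against_bruteforce_grid_maximization(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tau_r = rng.uniform(0.1, 10.0)
            tau_d = tau_r * rng.uniform(1.5, 50.0)
            t_star, norm = peak_normalization(tau_r, tau_d)
            t = np.linspace(0.0, t_star * 6, 400001)
            unit = (1 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)
            assert 1.0 / norm == pytest.approx(unit.max(), rel=1e-4)
            assert t[np.argmax(unit)] == pytest.approx(t_star, rel=1e-2)


class TestSaturatingWaveform:
    def test_matches_linear_for_single_pulse(self):
        syn = SynapseParams()
        train = InputTrain(onsets=np.array([2.0]), frequency=16.0,
                           duration=100.0)
        t = np.arange(0.0, 100.0, 0.01)
        lin = conductance_waveform(train, syn, t)
        sat = saturating_waveform(train, syn, t)
        assert np.allclose(lin[0], sat[0]) and np.allclose(lin[1], sat[1])

    def test_bounded_by_gmax_for_fast_train(self):
        syn = SynapseParams(gAMPA_max=0.4)
        train = make_train(512.0, 1000.0)
        t = np.arange(0.0, 1000.0, 0.01)
        gA, gN = saturating_waveform(train, syn, t)
        assert gA.max() <= syn.gAMPA_max * (1 + 1e-9)
        assert gN.max() <= syn.gNMDA_max * (1 + 1e-9)

    def test_linear_sum_exceeds_saturating_for_overlap(self):
        syn = SynapseParams(gAMPA_max=0.4)
        train = make_train(256.0, 500.0)
        t = np.arange(0.0, 500.0, 0.01)
        lin_N = conductance_waveform(train, syn, t)[1]
        sat_N = saturating_waveform(train, syn, t)[1]
        assert lin_N.max() > syn.gNMDA_max  # unbounded accumulation
        assert np.all(sat_N <= lin_N + 1e-12)


class TestCalibration:
    def test_calibrated_strength_properties(self, membrane, synapse,
                                            g_reference):
        """A single pulse stays subthreshold; the 16 Hz AMPA+NMDA train
        recruits spiking through summation."""
        mem = membrane.with_leak(0.7)
        syn = synapse.with_strength(g_reference)
        single = InputTrain(onsets=np.array([0.0]), frequency=16.0,
                            duration=60.0)
        drive = drive_waveforms(single, syn.ampa_only(), 60.0, 0.01)
        res = integrate(mem, synapse_drive=drive, duration=60.0, dt=0.01)
        assert res.spike_times.size == 0

        train = make_train(16.0, 1000.0)
        drive = drive_waveforms(train, syn, 1000.0, 0.01)
        res = integrate(mem, synapse_drive=drive, duration=1000.0, dt=0.01)
        assert res.spike_times.size >= 1
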