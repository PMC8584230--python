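"""Measurement pipeline: subtraction, smoothing, fits, spikes, bursts."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from lpmod.analysis import (
    BurstMetrics,
    average_sweeps,
    burst_metrics,
    detect_spikes,
    difference_current,
    fit_iv_logistic,
    fit_slow_decay,
    peak_from_fit,
    peak_phase,
    savgol_smooth,
)
from lpmod.neuron import SynapseSpec
from lpmod.stimuli import PeriodicWaveSpec, make_periodic_waveform
from lpmod.synth import surrogate_lp_waveform


def iv_curve(v, g, e_rev, v_half, k):
    return g * (v - e_rev) / (1.0 + np.exp(-(v - v_half) / k))


class TestDifferenceCurrent:
    def test_identity_and_zero(self):
        x = np.sin(np.linspace(0, 5, 100))
        np.testing.assert_array_equal(difference_current(x, x), 0 * x)
        np.testing.assert_array_equal(difference_current(x, 0 * x), x)

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(5) * 0.1
        t2 = t1 + 0.05
        with pytest.raises(ValueError):
            difference_current(np.ones(5), np.ones(5), t1, t2)
        with pytest.raises(ValueError):
            difference_current(np.ones(5), np.ones(6))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x1, x2, c1, c2 = rng.normal(size=(4, 50))
        np.testing.assert_allclose(
            difference_current(2 * x1 + 3 * x2, 2 * c1 + 3 * c2),
            2 * difference_current(x1, c1) + 3 * difference_current(x2, c2),
            atol=1e-12,
        )


class TestSavgol:
    def test_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 1, 500)
        y = 3 * t**4 - t**3 + 2 * t - 5
        sm = savgol_smooth(y, poly_order=5, frame_length=51)
        interior = slice(25, -25)
        np.testing.assert_allclose(sm[interior], y[interior], atol=1e-9)

    def test_constant_unchanged(self):
        y = np.full(300, 2.5)
        np.testing.assert_allclose(savgol_smooth(y, 5, 101), y)

    def test_even_frame_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(100), 5, 50)

    def test_noise_variance_reduction_matches_filter_gain(self):
        """White-noise variance shrinks by sum(c^2), the filter's gain."""
        rng = np.random.default_rng(42)
        gain = np.sum(savgol_coeffs(901, 3) ** 2)
        noise = rng.normal(0, 1.0, 200_000)
        sm = savgol_smooth(noise, poly_order=3, frame_length=901)
        ratio = np.var(sm[901:-901]) / np.var(noise)
        assert ratio == pytest.approx(gain, rel=0.10)


class TestAverageSweeps:
    def test_identical_sweeps(self):
        sweeps = np.tile(np.arange(10.0), (5, 1))
        np.testing.assert_array_equal(average_sweeps(sweeps, "last_n", 3),
                                      np.arange(10.0))

    def test_scaled_sweeps_mean(self):
        sweeps = np.arange(1.0, 6.0)[:, None] * np.ones(8)
        np.testing.assert_allclose(average_sweeps(sweeps, "last_n", 3),
                                   4.0 * np.ones(8))

    def test_first_selector(self):
        sweeps = np.arange(1.0, 6.0)[:, None] * np.ones(8)
        np.testing.assert_allclose(average_sweeps(sweeps, "first"), np.ones(8))

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            average_sweeps(np.ones((2, 10)), "last_n", 3)

    def test_noise_reduction_scales_with_sqrt_n(self):
        rng = np.random.default_rng(3)
        sweeps = rng.normal(0, 1.0, (9, 20_000))
        sd = np.std(average_sweeps(sweeps, "last_n", 9))
        assert sd == pytest.approx(1.0 / 3.0, rel=0.15)


class TestIvFit:
    TRUE = dict(g=2.0, e_rev=10.0, v_half=-30.0, k=6.0)

    def test_noiseless_roundtrip(self):
        v = np.linspace(-80, 20, 500)
        i = iv_curve(v, **self.TRUE)
        fit = fit_iv_logistic(v, i)
        assert fit.converged
        for name, val in self.TRUE.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-3)

    def test_noisy_recovery(self):
        v = np.linspace(-80, 20, 500)
        clean = iv_curve(v, **self.TRUE)
        sd = 0.02 * np.abs(clean).max()
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_iv_logistic(v, clean + rng.normal(0, sd, v.size))
            if all(abs(getattr(fit, k) - val) <= 0.05 * abs(val)
                   for k, val in self.TRUE.items()):
                ok += 1
        assert ok >= 19

    def test_deterministic(self):
        v = np.linspace(-80, 20, 300)
        i = iv_curve(v, **self.TRUE) + np.sin(v)
        f1, f2 = fit_iv_logistic(v, i), fit_iv_logistic(v, i)
        assert (f1.g, f1.e_rev, f1.v_half, f1.k) == (f2.g, f2.e_rev,
                                                     f2.v_half, f2.k)

    def test_null_signal_degenerate(self):
        v = np.linspace(-80, 20, 100)
        fit = fit_iv_logistic(v, np.zeros_like(v))
        assert abs(fit.g) < 1e-6

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_iv_logistic(np.linspace(-5, 5, 100), np.zeros(100))
        with pytest.raises(ValueError):
            fit_iv_logistic(np.linspace(-80, 20, 5), np.zeros(5))

    def test_summary_mentions_parameters(self):
        v = np.linspace(-80, 20, 200)
        fit = fit_iv_logistic(v, iv_curve(v, **self.TRUE))
        s = fit.summary()
        assert "E_rev" in s and "V_half" in s and "converged" in s


class TestPeakFromFit:
    def test_interior_minimum(self):
        fit = fit_iv_logistic(
            np.linspace(-80, 20, 300),
            iv_curve(np.linspace(-80, 20, 300), 1.0, 0.0, -30.0, 6.0),
        )
        peak = peak_from_fit(fit, (-80.0, 20.0))
        assert -30.0 < peak.v_imax < 0.0
        assert not peak.at_boundary

    def test_scaling_in_conductance(self):
        from lpmod.analysis import IVFit

        f1 = IVFit(g=1.0, e_rev=0.0, v_half=-30.0, k=6.0, rss=0.0,
                   converged=True)
        f2 = IVFit(g=2.0, e_rev=0.0, v_half=-30.0, k=6.0, rss=0.0,
                   converged=True)
        p1, p2 = peak_from_fit(f1), peak_from_fit(f2)
        assert p2.i_max == pytest.approx(2 * p1.i_max)
        assert p2.v_imax == p1.v_imax

    def test_agrees_with_dense_grid_search(self):
        from lpmod.analysis import IVFit

        rng = np.random.default_rng(11)
        for _ in range(100):
            fit = IVFit(g=rng.uniform(0.5, 5), e_rev=rng.uniform(0, 40),
                        v_half=rng.uniform(-50, -10), k=rng.uniform(2, 12),
                        rss=0.0, converged=True)
            peak = peak_from_fit(fit, (-80.0, 20.0))
            v = np.arange(-80, 20.0005, 0.001)
            v_oracle = v[np.argmin(fit.predict(v))]
            assert abs(peak.v_imax - v_oracle) <= 0.1 + 1e-9


class TestSlowDecay:
    def test_exponential_roundtrip(self):
        t = np.arange(0, 30.0, 1.0)
        y = np.exp(-t / 8.0)
        fit = fit_slow_decay(y, t)
        assert fit.converged and not fit.degenerate
        assert fit.lambda_ == pytest.approx(1 / 8.0, rel=5e-3)

    def test_offset_decay(self):
        t = np.arange(0, 30.0, 1.0)
        y = 2.0 * (0.6 * np.exp(-t / 5.0) + 0.4)
        fit = fit_slow_decay(y, t)
        assert fit.i_inf == pytest.approx(0.4, rel=1e-3)
        assert fit.lambda_ == pytest.approx(0.2, rel=1e-3)

    def test_constant_input_degenerate(self):
        fit = fit_slow_decay(np.full(10, 3.0), np.arange(10.0))
        assert fit.degenerate
        assert fit.lambda_ == 0.0
        assert fit.i0 == fit.i_inf

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            fit_slow_decay([1.0, 0.5], [0.0, 1.0])


class TestPeakPhase:
    def make_cmd(self, period=1.0, n_cycles=6):
        spec = PeriodicWaveSpec(unitary_shape=surrogate_lp_waveform(),
                                period=period, n_cycles=n_cycles)
        return make_periodic_waveform(spec)

    def test_minimum_at_trough_gives_phase_zero(self):
        cmd = self.make_cmd()
        n = cmd.meta["n_cycle"]
        # command trough is at phase 0 of each cycle by construction
        i = -np.cos(2 * np.pi * np.arange(len(cmd.v)) / n) - 2.0
        res = peak_phase(i, cmd, 1.0, smooth=False)
        assert res.phase == pytest.approx(0.0, abs=2e-3)

    def test_midcycle_minimum_gives_half(self):
        cmd = self.make_cmd()
        n = cmd.meta["n_cycle"]
        i = np.cos(2 * np.pi * np.arange(len(cmd.v)) / n) - 2.0
        res = peak_phase(i, cmd, 1.0, smooth=False)
        assert res.phase == pytest.approx(0.5, abs=2e-3)

    def test_shift_moves_phase_exactly(self):
        cmd = self.make_cmd()
        n = cmd.meta["n_cycle"]
        i = -np.cos(2 * np.pi * np.arange(len(cmd.v)) / n) - 2.0
        shifted = np.roll(i, n // 4)
        r0 = peak_phase(i, cmd, 1.0, smooth=False)
        r1 = peak_phase(shifted, cmd, 1.0, smooth=False)
        assert (r1.phase - r0.phase) % 1.0 == pytest.approx(0.25, abs=2e-3)

    def test_no_inward_current_rejected(self):
        cmd = self.make_cmd()
        with pytest.raises(ValueError):
            peak_phase(np.ones(len(cmd.v)), cmd, 1.0, smooth=False)


class TestSpikes:
    def test_flat_trace_no_spikes(self):
        assert detect_spikes(np.full(1000, -60.0)).size == 0

    def test_counts_clean_deflections(self):
        t = np.arange(0, 1.0, 1e-4)
        v = np.full_like(t, -60.0)
        for k in range(5):
            v[(t > 0.1 + 0.15 * k) & (t < 0.105 + 0.15 * k)] = 30.0
        assert detect_spikes(v, t).size == 5

    def test_robust_to_subthreshold_noise(self):
        t = np.arange(0, 1.0, 1e-4)
        clean = np.full_like(t, -60.0)
        for k in range(4):
            clean[(t > 0.1 + 0.2 * k) & (t < 0.11 + 0.2 * k)] = 30.0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            v = clean + rng.normal(0, 1.0, t.size)
            assert detect_spikes(v, t, threshold=-10.0).size == 4


class TestBurstMetrics:
    SYN = SynapseSpec(period=1.0, duty=0.5)

    def test_uniform_train_frequency(self):
        spikes = 0.4 + np.arange(5) * 0.02  # in cycle 0, 20 ms ISI
        bm = burst_metrics(spikes, self.SYN, [0])
        np.testing.assert_allclose(bm.f_inst[0], 50.0)
        assert bm.spike_count[0] == 5
        assert bm.spike_count[0] == len(bm.f_inst[0]) + 1

    def test_single_spike_cycle(self):
        bm = burst_metrics([1.5], self.SYN, [1])
        assert bm.spike_count[0] == 1
        assert bm.f_inst[0].size == 0
        assert bm.onset_phase[0] == bm.end_phase[0]

    def test_empty_cycle_reported_not_raised(self):
        bm = burst_metrics([0.5], self.SYN, [0, 1])
        assert bm.spike_count == [1, 0]
        assert bm.onset_phase[1] is None

    def test_phase_reference_is_conductance_peak(self):
        # synaptic peak at duty*period/2 = 0.25 s; spike at 0.5 s -> 0.25
        bm = burst_metrics([0.5], self.SYN, [0])
        assert bm.onset_phase[0] == pytest.approx(0.25)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            burst_metrics([0.5, 0.4], self.SYN, [0])
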