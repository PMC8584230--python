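"""Kinetic core: gates, time constants, GHK flux, calcium pool, kernels."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lpmod import _kernels as K
from lpmod.clamp import pack_channels
from lpmod.config import clamp_model_from_config, load_packaged_config, _tau
from lpmod.gating import (
    CalciumPoolSpec,
    CalciumState,
    ChannelSpec,
    GateSpec,
    GhkSpec,
    InvalidStateError,
    TauSpec,
    ca_inactivation,
    calcium_step,
    gate_step,
    ghk_current,
    ghk_flux_density,
    ghk_reversal,
    logistic_gate,
    ohmic_current,
    tau_eval,
)

# the clamp-model transient-current inactivation time constant
TAU_H_MIT = TauSpec(base=100.0, sech_amp=600.0, sech_v0=-30.0, sech_scale=10.0,
                    log_amp=200.0, log_v0=-30.0, log_scale=5.0)


class TestGates:
    def test_logistic_midpoint(self):
        g = GateSpec(form="logistic", v_half=-30.0, k=6.0)
        assert logistic_gate(-30.0, g) == pytest.approx(0.5)

    def test_saturation(self):
        g = GateSpec(form="logistic", v_half=0.0, k=10.0)
        assert logistic_gate(1e4, g) == pytest.approx(1.0)
        assert logistic_gate(-1e4, g) == pytest.approx(0.0)

    def test_rectified_gate_clamps_at_zero(self):
        """A floor-offset gate saturates at 0, never at -offset."""
        g = GateSpec(form="logistic", v_half=-61.0, k=-2.8, floor_offset=0.1)
        assert logistic_gate(0.0, g) == 0.0
        assert logistic_gate(-80.0, g) == pytest.approx(0.9, abs=2e-3)

    def test_tanh_plus_orientation(self):
        """Hyperpolarization-activated gate: on below v_half, off above."""
        g = GateSpec(form="tanh_plus", v_half=-58.0, k=-10.0)
        assert logistic_gate(-40.0, g) == 0.0
        assert 0.0 < logistic_gate(-70.0, g) < 1.0

    @given(v=st.floats(-120, 60), vh=st.floats(-80, 0),
           k=st.sampled_from([-12.0, -5.0, 2.0, 18.0]))
    def test_gate_bounds(self, v, vh, k):
        g = GateSpec(form="logistic", v_half=vh, k=k)
        assert 0.0 <= logistic_gate(v, g) <= 1.0


class TestTau:
    def test_transient_inactivation_limits(self):
        """Reconstructed time constant: 100 ms at -inf, 300 ms at +inf."""
        assert tau_eval(-1e4, TAU_H_MIT) == pytest.approx(100.0)
        assert tau_eval(1e4, TAU_H_MIT) == pytest.approx(300.0)

    def test_transient_inactivation_center(self):
        # sum of base, full sech term and half the logistic term
        assert tau_eval(-30.0, TAU_H_MIT) == pytest.approx(100 + 600 + 100)

    def test_constant_form(self):
        t = TauSpec(base=2.0)
        assert np.all(tau_eval(np.linspace(-120, 60, 7), t) == 2.0)

    @pytest.mark.parametrize("config", ["table2_clamp_model",
                                        "table3_neuron_model"])
    def test_all_shipped_taus_positive(self, config):
        doc = load_packaged_config(config)
        v = np.linspace(-120.0, 60.0, 721)
        for ch in doc["model"]["channels"]:
            for key in ("tau_m", "tau_h"):
                if key in ch:
                    tau = _tau(ch[key], key)
                    assert np.all(tau_eval(v, tau) > 0.0), (ch["name"], key)


class TestGateStep:
    GATE = GateSpec(form="logistic", v_half=-30.0, k=6.0)
    TAU = TauSpec(base=2.0)

    def test_fixed_point(self):
        x = logistic_gate(-25.0, self.GATE)
        assert gate_step(x, -25.0, 0.7, self.GATE, self.TAU) == pytest.approx(x)

    def test_large_dt_saturates(self):
        x = gate_step(0.1, -25.0, 1e6, self.GATE, self.TAU)
        assert x == pytest.approx(logistic_gate(-25.0, self.GATE))

    def test_closed_form_relaxation(self):
        """x: 0 -> 1 with tau = dt = 2 ms gives 1 - 1/e exactly."""
        gate = GateSpec(form="logistic", v_half=-30.0, k=6.0)
        x = gate_step(0.0, 1e5, 2.0, gate, self.TAU)
        assert x == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    @given(n=st.integers(1, 20), dt=st.floats(0.01, 5.0),
           v=st.floats(-80, 20), x0=st.floats(0, 1))
    def test_semigroup_at_constant_voltage(self, n, dt, v, x0):
        """n small steps equal one big step (the update is exact)."""
        x = x0
        for _ in range(n):
            x = gate_step(x, v, dt, self.GATE, TAU_H_MIT)
        once = gate_step(x0, v, n * dt, self.GATE, TAU_H_MIT)
        assert x == pytest.approx(once, abs=1e-12)


class TestOhmic:
    def test_zero_at_reversal(self):
        ch = ChannelSpec(name="x", gbar=2.0, e_rev=35.0)
        assert ohmic_current(35.0, 1.0, 1.0, ch) == 0.0

    def test_full_activation_linear(self):
        ch = ChannelSpec(name="x", gbar=2.0, e_rev=35.0)
        assert ohmic_current(-20.0, 1.0, 1.0, ch) == pytest.approx(2.0 * -55.0)

    def test_persistent_current_inward_below_reversal(self):
        """Hand oracle: gbar * S((v+19)/18) * (v - 35) at v = -20."""
        ch = ChannelSpec(
            name="I_MI", gbar=0.125, e_rev=35.0,
            m_gate=GateSpec(form="logistic", v_half=-19.0, k=18.0),
            m_tau=TauSpec(base=2.0),
        )
        m = logistic_gate(-20.0, ch.m_gate)
        i = ohmic_current(-20.0, m, 1.0, ch)
        expected = 0.125 * (1 / (1 + np.exp(1 / 18))) * (-55.0)
        assert i == pytest.approx(expected)
        assert i < 0.0


class TestGhk:
    GHK = GhkSpec()

    @given(ci=st.floats(1e-4, 1.0), co=st.floats(1.0, 20.0))
    def test_reversal_matches_nernst(self, ci, co):
        ghk = GhkSpec(ca_out=co)
        vrev = ghk_reversal(ci, ghk)
        # zero flux at the Nernst potential, and sign change across it
        assert abs(ghk_flux_density(vrev, ci, ghk)) < 1e-10
        assert ghk_flux_density(vrev - 0.02, ci, ghk) < 0
        assert ghk_flux_density(vrev + 0.02, ci, ghk) > 0

    def test_inward_at_hyperpolarized(self):
        assert ghk_current(-80.0, 1.0, 1.0, 0.02, self.GHK) < 0.0

    def test_continuity_across_series_boundary(self):
        """The series/exact branch switch is invisible at the 1e-8 level."""
        ghk = self.GHK
        v_eps = 1e-4 / ghk.zeta_per_mv
        for sign in (1.0, -1.0):
            a = ghk_flux_density(sign * v_eps * 0.999999, 0.02, ghk)
            b = ghk_flux_density(sign * v_eps * 1.000001, 0.02, ghk)
            assert a == pytest.approx(b, rel=1e-8)

    def test_series_matches_direct_formula(self):
        """Inside the window the series equals the constant-field formula
        evaluated directly (oracle has its own cancellation at ~1e-12)."""
        from lpmod.gating import FARADAY

        ghk = self.GHK
        zeta = 0.5e-4
        direct = ghk.p_mps * FARADAY * zeta / (1 - np.exp(-zeta)) * \
            (0.02 - ghk.ca_out * np.exp(-zeta))
        impl = ghk_flux_density(zeta / ghk.zeta_per_mv, 0.02, ghk)
        assert impl == pytest.approx(direct, rel=1e-9)

    def test_prefactor_modes_scale_by_valence(self):
        f = GhkSpec(prefactor_mode="f_zeta")
        zf = GhkSpec(prefactor_mode="zf_zeta")
        assert ghk_flux_density(-50.0, 0.02, zf) == pytest.approx(
            2.0 * ghk_flux_density(-50.0, 0.02, f))

    def test_nonpositive_calcium_rejected(self):
        with pytest.raises(InvalidStateError):
            ghk_flux_density(-50.0, 0.0, self.GHK)


class TestCalciumPool:
    POOL = CalciumPoolSpec()

    def test_fixed_point(self):
        s = calcium_step(CalciumState(ca_in=0.02), 0.0, 10.0, self.POOL)
        assert s.ca_in == pytest.approx(0.02)

    def test_relaxation_to_rest(self):
        """With no current, [Ca] relaxes to rest with tau = 12 s."""
        s = CalciumState(ca_in=0.04)
        dt = 1000.0  # ms
        s = calcium_step(s, 0.0, dt, self.POOL)
        expected = 0.02 + 0.02 * np.exp(-dt / 12000.0)
        assert s.ca_in == pytest.approx(expected, rel=1e-12)

    def test_steady_state_balances_influx(self):
        """Constant inward current: [Ca] rises monotonically to the level
        where clearance balances influx."""
        i_dens = -5.0  # A/m^2 inward
        pool = self.POOL
        influx = -pool.effective_flux_coeff * i_dens * 1e-3  # mM/ms
        target = pool.ca_inf + pool.tau_ca_ms * influx
        s = CalciumState(ca_in=0.02)
        prev = s.ca_in
        for _ in range(100):
            s = calcium_step(s, i_dens, 2000.0, pool)
            assert s.ca_in >= prev
            prev = s.ca_in
        assert s.ca_in == pytest.approx(target, rel=1e-6)

    def test_floor_clamps_with_warning(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            s = calcium_step(CalciumState(ca_in=0.001), 1e4, 5000.0, self.POOL)
        assert s.ca_in == self.POOL.floor
        assert any("floor" in str(w.message) for w in rec)

    def test_hill_inactivation_values(self):
        g = GateSpec(form="hill", ca_half=0.015, hill=4.0)
        assert ca_inactivation(0.015, g) == pytest.approx(0.5)
        assert ca_inactivation(1e-9, g) == pytest.approx(1.0)
        assert ca_inactivation(0.02, g) == pytest.approx(81.0 / 337.0)


class TestKernelAgreement:
    """The compiled clamp kernel reproduces the reference numpy updates."""

    def test_kernel_matches_reference_loop(self):
        doc = load_packaged_config("table2_clamp_model")
        model = clamp_model_from_config(doc, mi_t_mode="ghk_ca")
        rng = np.random.default_rng(7)
        # a wandering voltage trajectory exercising all branches
        v = np.cumsum(rng.normal(0, 2.0, 400)) - 40.0
        v = np.clip(v, -90.0, 30.0)
        dt = 0.2  # ms

        P = pack_channels(model.channels)
        pool = model.pool
        cur, ca_tr, err = K.clamp_kernel(
            v, dt, P, True, pool.ca_inf, pool.tau_ca_ms,
            pool.effective_flux_coeff, pool.floor,
            np.zeros(2), np.ones(2), 0.0, False,
        )
        assert err == -1

        # reference: pure-python loop over the public gating functions
        mi, mit = model.channels
        m = [ch.m_gate.steady_state(v[0], ca=pool.ca_inf) for ch in (mi, mit)]
        h = [1.0, mit.h_gate.steady_state(v[0])]
        state = CalciumState(ca_in=pool.ca_inf)
        for i, vi in enumerate(v):
            if i > 0:
                m[0] = gate_step(m[0], vi, dt, mi.m_gate, mi.m_tau)
                m[1] = gate_step(m[1], vi, dt, mit.m_gate, mit.m_tau)
                h[1] = gate_step(h[1], vi, dt, mit.h_gate, mit.h_tau)
            i_mi = ohmic_current(vi, m[0], 1.0, mi)
            i_mit = ghk_current(vi, m[1], h[1], state.ca_in, mit.ghk) * \
                ca_inactivation(state.ca_in, mit.ca_h_gate)
            if i > 0:
                dens = i_mit * 1e-9 / (mit.ghk.area_um2 * 1e-12)
                state = calcium_step(state, dens, dt, pool)
            assert cur[0, i] == pytest.approx(i_mi, rel=1e-12, abs=1e-15)
            assert cur[1, i] == pytest.approx(i_mit, rel=1e-9, abs=1e-15)
            assert ca_tr[i] == pytest.approx(state.ca_in, rel=1e-9)
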