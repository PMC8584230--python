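"""Numba inner loops for the clamp and two-compartment neuron simulations.

State updates are sequential in time and cannot be vectorised, so the per-step
work is compiled. Channels are packed into a flat float64 parameter matrix
(one row per channel, column layout below); the pure-numpy reference
implementations live in :mod:`lpmod.gating` and the test suite asserts the
kernels agree with them.

Column layout (keep in sync with ``pack_channels`` in clamp.py/neuron.py):
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- channel matrix columns ---------------------------------------------------
AMP = 0  # ohmic: total gbar (nS or uS); ghk: effective area in m^2
EREV = 1
EXP_A = 2
EXP_B = 3
COMP = 4  # 0 = soma/neurite, 1 = axon
GHK_MODE = 5
CA_PERM = 6
M_FORM = 7  # 0 logistic(v), 1 tanh+(v), 2 hill(ca), 3 logistic(ca), 4 const
M_VHALF = 8
M_K = 9
M_FLOOR = 10
M_CAHALF = 11
M_HILL = 12
M_CAKD = 13  # <= 0 means absent
MT_BASE = 14
MT_SECH_AMP = 15
MT_SECH_V0 = 16
MT_SECH_SC = 17
MT_LOG_AMP = 18
MT_LOG_V0 = 19
MT_LOG_SC = 20
H_PRESENT = 21
H_FORM = 22
H_VHALF = 23
H_K = 24
H_FLOOR = 25
H_CAHALF = 26
H_HILL = 27
HT_BASE = 28
HT_SECH_AMP = 29
HT_SECH_V0 = 30
HT_SECH_SC = 31
HT_LOG_AMP = 32
HT_LOG_V0 = 33
HT_LOG_SC = 34
CAH_INST = 35  # instantaneous hill([Ca]) multiplier on the current
CAH_CAHALF = 36
CAH_HILL = 37
GHK_PREF = 38  # P * F * (z or 1), SI
GHK_ZETA_PER_MV = 39
GHK_CAOUT = 40
NCOL = 41


@njit(cache=True, fastmath=False)
def _sigm(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, fastmath=False)
def _steady(form, vhalf, k, floor, cahalf, hill, cakd, v, ca):
    if form == 4:
        return 1.0
    if form == 2:
        x = 1.0 / (1.0 + (ca / cahalf) ** hill)
    else:
        u = ca if form == 3 else v
        arg = (u - vhalf) / k
        if form == 1:
            x = np.tanh(arg)
            if x < 0.0:
                x = 0.0
        else:
            x = _sigm(arg)
    if floor > 0.0:
        x = x - floor
        if x < 0.0:
            x = 0.0
    if cakd > 0.0:
        x = x * ca / (ca + cakd)
    return x


@njit(cache=True, fastmath=False)
def _tau(base, samp, sv0, ssc, lamp, lv0, lsc, v):
    t = base
    if samp != 0.0:
        t += samp / np.cosh((v - sv0) / ssc)
    if lamp != 0.0:
        t += lamp * _sigm((v - lv0) / lsc)
    return t


@njit(cache=True, fastmath=False)
def _ghk_density(v, ca, pref, zeta_per_mv, ca_out):
    zeta = zeta_per_mv * v
    if abs(zeta) < 1e-4:
        series = 1.0 + zeta / 2.0 + zeta * zeta / 12.0
        return pref * series * (ca - ca_out * np.exp(-zeta))
    return pref * zeta / (1.0 - np.exp(-zeta)) * (ca - ca_out * np.exp(-zeta))


@njit(cache=True, fastmath=False)
def _gate_updates(P, c, v, ca, dt, m, h):
    """Exponential-Euler update of channel c's gates at voltage v."""
    if P[c, M_FORM] != 4.0:
        minf = _steady(
            int(P[c, M_FORM]), P[c, M_VHALF], P[c, M_K], P[c, M_FLOOR],
            P[c, M_CAHALF], P[c, M_HILL], P[c, M_CAKD], v, ca,
        )
        tm = _tau(
            P[c, MT_BASE], P[c, MT_SECH_AMP], P[c, MT_SECH_V0], P[c, MT_SECH_SC],
            P[c, MT_LOG_AMP], P[c, MT_LOG_V0], P[c, MT_LOG_SC], v,
        )
        m[c] = minf + (m[c] - minf) * np.exp(-dt / tm)
    if P[c, H_PRESENT] > 0.0:
        hinf = _steady(
            int(P[c, H_FORM]), P[c, H_VHALF], P[c, H_K], P[c, H_FLOOR],
            P[c, H_CAHALF], P[c, H_HILL], -1.0, v, ca,
        )
        th = _tau(
            P[c, HT_BASE], P[c, HT_SECH_AMP], P[c, HT_SECH_V0], P[c, HT_SECH_SC],
            P[c, HT_LOG_AMP], P[c, HT_LOG_V0], P[c, HT_LOG_SC], v,
        )
        h[c] = hinf + (h[c] - hinf) * np.exp(-dt / th)


@njit(cache=True, fastmath=False)
def _init_gates(P, v, ca, m, h):
    for c in range(P.shape[0]):
        m[c] = _steady(
            int(P[c, M_FORM]), P[c, M_VHALF], P[c, M_K], P[c, M_FLOOR],
            P[c, M_CAHALF], P[c, M_HILL], P[c, M_CAKD], v, ca,
        )
        if P[c, H_PRESENT] > 0.0:
            h[c] = _steady(
                int(P[c, H_FORM]), P[c, H_VHALF], P[c, H_K], P[c, H_FLOOR],
                P[c, H_CAHALF], P[c, H_HILL], -1.0, v, ca,
            )
        else:
            h[c] = 1.0


@njit(cache=True, fastmath=False)
def _channel_current(P, c, v, ca, m, h):
    """Current in nA (and its pool-feeding density in A/m^2)."""
    ga = m[c] ** int(P[c, EXP_A])
    if P[c, EXP_B] > 0.0:
        ga *= h[c]
    if P[c, CAH_INST] > 0.0:
        ga *= 1.0 / (1.0 + (ca / P[c, CAH_CAHALF]) ** P[c, CAH_HILL])
    if P[c, GHK_MODE] > 0.0:
        dens = ga * _ghk_density(
            v, ca, P[c, GHK_PREF], P[c, GHK_ZETA_PER_MV], P[c, GHK_CAOUT]
        )
        i_na = dens * P[c, AMP] * 1e9  # A/m^2 * m^2 -> A -> nA
        return i_na, dens
    i_na = P[c, AMP] * ga * (v - P[c, EREV])
    return i_na, 0.0


@njit(cache=True, fastmath=False)
def clamp_kernel(
    v_cmd, dt, P,
    use_pool, ca_inf, tau_ca, flux_coeff, ca_floor,
    m0, h0, ca0, use_init,
):
    """Integrate channel gates under a prescribed voltage command.

    v_cmd in mV on a uniform grid of dt ms. Returns (i_per_channel [nch, n],
    ca [n], gates_m [nch, n? no -- final only], error_step). error_step = -1
    on success, else the first step index with a non-finite state.
    """
    n = v_cmd.shape[0]
    nch = P.shape[0]
    m = np.empty(nch)
    h = np.empty(nch)
    cur = np.zeros((nch, n))
    ca_tr = np.empty(n)
    if use_init:
        ca = ca0
        for c in range(nch):
            m[c] = m0[c]
            h[c] = h0[c]
    else:
        ca = ca_inf
        _init_gates(P, v_cmd[0], ca, m, h)
    for i in range(n):
        v = v_cmd[i]
        if i > 0:
            for c in range(nch):
                _gate_updates(P, c, v, ca, dt, m, h)
        dens_sum = 0.0
        for c in range(nch):
            i_na, dens = _channel_current(P, c, v, ca, m, h)
            cur[c, i] = i_na
            if P[c, CA_PERM] > 0.0:
                dens_sum += dens
        if use_pool and i > 0:
            influx = -flux_coeff * dens_sum * 1e-3  # mM/ms
            target = ca_inf + tau_ca * influx
            ca = target + (ca - target) * np.exp(-dt / tau_ca)
            if ca < ca_floor:
                ca = ca_floor
        ca_tr[i] = ca
        if not np.isfinite(ca):
            return cur, ca_tr, i
    return cur, ca_tr, -1


@njit(cache=True, fastmath=False)
def neuron_kernel(
    n_steps, dt, P,
    c_nf, g_couple, areas_m2,
    syn_gmax, syn_erev, syn_period, syn_duty,
    ca_inf, tau_ca, flux_coeff, ca_floor,
    v0, record_stride, record_currents,
):
    """Two-compartment conductance-based neuron under periodic inhibition.

    Voltages advance by backward Euler on the linear (ohmic + synaptic +
    coupling) terms with gates frozen per step; gates advance by exponential
    Euler; GHK currents enter explicitly. Returns recorded traces and an
    error step (-1 on success).
    """
    nch = P.shape[0]
    n_rec = (n_steps + record_stride - 1) // record_stride
    vs_tr = np.empty(n_rec)
    va_tr = np.empty(n_rec)
    ca_tr = np.empty(n_rec)
    gsyn_tr = np.empty(n_rec)
    t_tr = np.empty(n_rec)
    cur_tr = np.zeros((nch if record_currents else 0, n_rec))

    m = np.empty(nch)
    h = np.empty(nch)
    vs = v0
    va = v0
    ca = ca_inf
    _init_gates(P, v0, ca, m, h)

    half_act = syn_duty * syn_period / 2.0
    k = 0
    for i in range(n_steps):
        t = i * dt
        # triangular synaptic conductance, active window at cycle start
        tc = t % syn_period
        if tc < half_act:
            gsyn = syn_gmax * tc / half_act
        elif tc < 2.0 * half_act:
            gsyn = syn_gmax * (2.0 - tc / half_act)
        else:
            gsyn = 0.0

        # gates frozen per step: update from current voltages
        for c in range(nch):
            vloc = vs if P[c, COMP] == 0.0 else va
            _gate_updates(P, c, vloc, ca, dt, m, h)

        # accumulate linear conductances and explicit (GHK) currents
        g_s = gsyn
        b_s = gsyn * syn_erev
        g_a = 0.0
        b_a = 0.0
        dens_sum = 0.0
        for c in range(nch):
            soma = P[c, COMP] == 0.0
            vloc = vs if soma else va
            if P[c, GHK_MODE] > 0.0:
                i_na, dens = _channel_current(P, c, vloc, ca, m, h)
                if soma:
                    b_s -= i_na
                else:
                    b_a -= i_na
                if P[c, CA_PERM] > 0.0:
                    dens_sum += dens
            else:
                ga = m[c] ** int(P[c, EXP_A])
                if P[c, EXP_B] > 0.0:
                    ga *= h[c]
                if P[c, CAH_INST] > 0.0:
                    ga *= 1.0 / (1.0 + (ca / P[c, CAH_CAHALF]) ** P[c, CAH_HILL])
                g_tot = P[c, AMP] * ga
                if soma:
                    g_s += g_tot
                    b_s += g_tot * P[c, EREV]
                else:
                    g_a += g_tot
                    b_a += g_tot * P[c, EREV]
                if P[c, CA_PERM] > 0.0:
                    # ohmic calcium-carrying current feeds the pool as density
                    dens_sum += g_tot * (vloc - P[c, EREV]) * 1e-9 / areas_m2[0]

        cs_dt = c_nf[0] / dt
        ca_dt = c_nf[1] / dt
        a11 = cs_dt + g_s + g_couple
        a22 = ca_dt + g_a + g_couple
        det = a11 * a22 - g_couple * g_couple
        r1 = cs_dt * vs + b_s
        r2 = ca_dt * va + b_a
        vs_new = (a22 * r1 + g_couple * r2) / det
        va_new = (g_couple * r1 + a11 * r2) / det
        vs = vs_new
        va = va_new

        influx = -flux_coeff * dens_sum * 1e-3  # mM/ms
        target = ca_inf + tau_ca * influx
        ca = target + (ca - target) * np.exp(-dt / tau_ca)
        if ca < ca_floor:
            ca = ca_floor

        if not (np.isfinite(vs) and np.isfinite(va) and np.isfinite(ca)):
            return t_tr, vs_tr, va_tr, ca_tr, gsyn_tr, cur_tr, i

        if i % record_stride == 0:
            t_tr[k] = t + dt
            vs_tr[k] = vs
            va_tr[k] = va
            ca_tr[k] = ca
            gsyn_tr[k] = gsyn
            if record_currents:
                for c in range(nch):
                    vloc = vs if P[c, COMP] == 0.0 else va
                    i_na, _ = _channel_current(P, c, vloc, ca, m, h)
                    cur_tr[c, k] = i_na
            k += 1
    return t_tr, vs_tr, va_tr, ca_tr, gsyn_tr, cur_tr, -1
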