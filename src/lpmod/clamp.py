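"""In-silico voltage-clamp rig.

Integrates a set of gated channels under a prescribed :class:`VoltageCommand`
(ideal clamp: the commanded voltage is imposed exactly, no series resistance
or space-clamp attenuation) and returns per-channel and total current traces.

The shipped clamp model is the two-current decomposition of the
modulator-activated difference current: a fast persistent inward current
(I_MI) plus a transient inactivating one (I_MI-T). The transient current can
be simulated either as an ohmic current or as a GHK calcium current coupled
to a microdomain calcium pool (``mi_t_mode = "ghk_ca"``), which adds the slow
multi-sweep decay of the total current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .gating import FARADAY, CalciumPoolSpec, ChannelSpec, GateSpec, TauSpec
from .stimuli import VoltageCommand

__all__ = [
    "ClampModel",
    "ClampTrace",
    "IntegrationError",
    "simulate_clamp",
    "sweep_mean_current",
    "iv_points",
    "pack_channels",
]


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite state."""


_FORM_CODE = {"logistic": 0.0, "tanh_plus": 1.0, "hill": 2.0}


def _gate_cols(row, gate: Optional[GateSpec], tau: Optional[TauSpec], base: int):
    # base points at the FORM column of the gate block
    if gate is None:
        row[base] = 4.0  # constant 1
        row[base + 7] = 1.0  # tau base, unused
        return
    code = _FORM_CODE[gate.form]
    if gate.form == "logistic" and gate.depends == "ca":
        code = 3.0
    row[base] = code
    row[base + 1] = gate.v_half
    row[base + 2] = gate.k
    row[base + 3] = gate.floor_offset
    row[base + 4] = gate.ca_half if gate.ca_half else 1.0
    row[base + 5] = gate.hill
    if base == K.M_FORM:
        row[K.M_CAKD] = gate.ca_gain_kd if gate.ca_gain_kd is not None else -1.0
    t = tau or TauSpec(base=1.0)
    tb = base + 7 if base == K.M_FORM else K.HT_BASE
    row[tb + 0] = t.base
    row[tb + 1] = t.sech_amp
    row[tb + 2] = t.sech_v0
    row[tb + 3] = t.sech_scale
    row[tb + 4] = t.log_amp
    row[tb + 5] = t.log_v0
    row[tb + 6] = t.log_scale


def pack_channels(
    channels: Sequence[ChannelSpec], comp_index: Optional[dict] = None
) -> np.ndarray:
    """Pack ChannelSpecs into the kernel parameter matrix."""
    P = np.zeros((len(channels), K.NCOL))
    for i, ch in enumerate(channels):
        row = P[i]
        row[K.EREV] = ch.e_rev
        row[K.EXP_A] = ch.a
        row[K.EXP_B] = ch.b
        row[K.COMP] = float(comp_index.get(ch.name, 0)) if comp_index else 0.0
        row[K.GHK_MODE] = 1.0 if ch.ghk_mode else 0.0
        row[K.CA_PERM] = 1.0 if ch.ca_permeable else 0.0
        if ch.ghk_mode:
            g = ch.ghk
            row[K.AMP] = g.area_um2 * 1e-12  # m^2
            row[K.GHK_PREF] = g.p_mps * FARADAY * (
                g.z if g.prefactor_mode == "zf_zeta" else 1.0
            )
            row[K.GHK_ZETA_PER_MV] = g.zeta_per_mv
            row[K.GHK_CAOUT] = g.ca_out
        else:
            row[K.AMP] = ch.gbar
        _gate_cols(row, ch.m_gate, ch.m_tau, K.M_FORM)
        if ch.h_gate is not None:
            row[K.H_PRESENT] = 1.0
            _gate_cols(row, ch.h_gate, ch.h_tau, K.H_FORM)
        if ch.ca_h_gate is not None:
            row[K.CAH_INST] = 1.0
            row[K.CAH_CAHALF] = ch.ca_h_gate.ca_half
            row[K.CAH_HILL] = ch.ca_h_gate.hill
    return P


@dataclass
class ClampModel:
    """A set of channels under voltage clamp, with an optional calcium pool.

    ``mi_t_mode`` records which transient-current variant the channel list
    encodes (``"ohmic"`` or ``"ghk_ca"``); the GHK variant requires a pool.
    """

    channels: list[ChannelSpec] = field(default_factory=list)
    mi_t_mode: str = "ohmic"
    pool: Optional[CalciumPoolSpec] = None

    def __post_init__(self) -> None:
        if self.mi_t_mode not in ("ohmic", "ghk_ca"):
            raise ValueError(f"unknown mi_t_mode {self.mi_t_mode!r}")
        if self.mi_t_mode == "ghk_ca" and self.pool is None:
            raise ValueError("ghk_ca variant requires a calcium pool")
        if any(ch.ghk_mode for ch in self.channels) and self.pool is None:
            raise ValueError("GHK channels require a calcium pool")

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]


@dataclass
class ClampTrace:
    """Simulated clamp currents on the command grid.

    ``i_per_channel`` is (n_channels, n_samples) in nA; ``i_total`` is their
    sum at every sample. ``ca`` is the pool concentration (mM) if a pool is
    present, else a constant array at the resting concentration.
    """

    t: np.ndarray  # s
    v: np.ndarray  # mV
    i_per_channel: np.ndarray  # nA
    i_total: np.ndarray  # nA
    ca: np.ndarray  # mM
    sweep_boundaries: np.ndarray
    channel_names: list[str]
    dt: float  # s
    meta: dict

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_boundaries)

    def sweep_slice(self, i: int) -> slice:
        b = self.sweep_boundaries
        start = int(b[i])
        stop = int(b[i + 1]) if i + 1 < len(b) else len(self.v)
        return slice(start, stop)

    def channel(self, name: str) -> np.ndarray:
        return self.i_per_channel[self.channel_names.index(name)]


def simulate_clamp(
    cmd: VoltageCommand,
    model: ClampModel,
    initial_state: Optional[dict] = None,
) -> ClampTrace:
    """Run the clamp model under a voltage command.

    Gates start at their steady-state values for the first commanded voltage
    and the pool at its resting concentration, unless ``initial_state`` (a
    dict with keys ``m``, ``h``, ``ca``) carries the final state of a
    previous run. Integration is at the command's sample interval.
    """
    P = pack_channels(model.channels)
    dt_ms = cmd.dt * 1e3
    pool = model.pool
    use_pool = pool is not None
    if use_pool:
        ca_inf, tau_ca = pool.ca_inf, pool.tau_ca_ms
        flux, floor = pool.effective_flux_coeff, pool.floor
    else:
        ca_inf, tau_ca, flux, floor = 0.02, 1.0, 0.0, 1e-6
    nch = len(model.channels)
    if initial_state is not None:
        m0 = np.asarray(initial_state["m"], dtype=float)
        h0 = np.asarray(initial_state["h"], dtype=float)
        ca0 = float(initial_state.get("ca", ca_inf))
        use_init = True
    else:
        m0 = np.zeros(nch)
        h0 = np.ones(nch)
        ca0 = ca_inf
        use_init = False
    cur, ca_tr, err = K.clamp_kernel(
        np.ascontiguousarray(cmd.v, dtype=float), dt_ms, P,
        use_pool, ca_inf, tau_ca, flux, floor,
        m0, h0, ca0, use_init,
    )
    if err >= 0:
        raise IntegrationError(f"non-finite state at step {err} (t={err * dt_ms} ms)")
    return ClampTrace(
        t=cmd.t,
        v=cmd.v,
        i_per_channel=cur,
        i_total=cur.sum(axis=0),
        ca=ca_tr,
        sweep_boundaries=cmd.sweep_boundaries,
        channel_names=model.channel_names,
        dt=cmd.dt,
        meta=dict(cmd.meta),
    )


def sweep_mean_current(trace: ClampTrace) -> np.ndarray:
    """Mean of the total current over each sweep (one value per sweep)."""
    if trace.n_sweeps == 0:
        raise ValueError("trace has no sweep boundaries")
    out = np.empty(trace.n_sweeps)
    for i in range(trace.n_sweeps):
        seg = trace.i_total[trace.sweep_slice(i)]
        if seg.size == 0:
            raise ValueError(f"sweep {i} is empty")
        out[i] = seg.mean()
    return out


def iv_points(trace: ClampTrace, segment: str, sweep_index: int):
    """(v, i) samples restricted to one ramp limb of one sweep.

    ``segment`` is ``"pos_ramp"`` or ``"neg_ramp"``. Raises ``ValueError``
    for protocols without the requested limb (e.g. waveform playback).
    """
    if segment not in ("pos_ramp", "neg_ramp"):
        raise ValueError(f"unknown segment {segment!r}")
    meta = trace.meta
    kind = meta.get("kind")
    sl = trace.sweep_slice(sweep_index)
    if kind == "ramp":
        n_up, n_down = meta["n_up"], meta["n_down"]
        if segment == "pos_ramp":
            idx = slice(sl.start, sl.start + n_up)
        else:
            idx = slice(sl.start + n_up, sl.start + n_up + n_down)
    elif kind == "ramp_hold":
        n_q = meta["n_quarter"]
        if segment == "pos_ramp":
            idx = slice(sl.start, sl.start + n_q)
        else:
            idx = slice(sl.start + 2 * n_q, sl.start + 3 * n_q)
    else:
        raise ValueError(f"protocol kind {kind!r} has no ramp segments")
    return trace.v[idx], trace.i_total[idx]
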