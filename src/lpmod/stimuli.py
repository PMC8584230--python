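"""Voltage-command construction for the in-silico voltage-clamp rig.

Three protocol families are used throughout the package:

* symmetric triangular ramps (rest -> peak -> rest, repeated with long holds
  in between, so inactivating currents recover between sweeps);
* ramp-and-hold cycles, where an up-ramp, a depolarized hold, a down-ramp and
  a hyperpolarized hold each occupy exactly 25% of the cycle and the cycle is
  repeated until the response reaches steady state;
* periodically applied slow-wave waveforms (a normalized unitary shape,
  rescaled in time to the cycle period and in voltage to a trough/peak range),
  mimicking the membrane-potential trajectory of a bursting follower neuron.

Commands are built on a uniform time grid with sample-aligned corners (ramp
durations are rounded to the nearest sample) so protocols are bit-reproducible
and analysis never has to re-derive protocol timing from the voltage trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RampSpec",
    "RampHoldSpec",
    "PeriodicWaveSpec",
    "VoltageCommand",
    "InvalidSpecError",
    "make_triangular_ramp",
    "make_ramp_and_hold",
    "make_periodic_waveform",
    "DEFAULT_DT",
]

#: Default command sampling interval, seconds (5 kHz digitization rate).
DEFAULT_DT = 2e-4


class InvalidSpecError(ValueError):
    """A protocol specification violates its invariants."""


@dataclass(frozen=True)
class RampSpec:
    """Symmetric triangular voltage ramp, repeated with rests in between.

    Parameters
    ----------
    v_start, v_peak : float
        Ramp limits in mV; the voltage rises ``v_start -> v_peak`` at
        ``slope`` and immediately falls back at ``-slope``.
    slope : float
        Ramp speed in mV/s (> 0).
    n_sweeps : int
        Number of triangular sweeps.
    inter_sweep_hold : float
        Rest duration between sweeps, seconds.
    hold_v : float
        Holding potential during the rest, mV.
    """

    v_start: float = -80.0
    v_peak: float = 20.0
    slope: float = 100.0
    n_sweeps: int = 5
    inter_sweep_hold: float = 5.0
    hold_v: float = -80.0

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_start:
            raise InvalidSpecError("v_peak must exceed v_start")
        if self.slope <= 0:
            raise InvalidSpecError("ramp slope must be positive")
        if self.n_sweeps < 1:
            raise InvalidSpecError("n_sweeps must be >= 1")
        if self.inter_sweep_hold < 0:
            raise InvalidSpecError("inter_sweep_hold must be >= 0")

    @property
    def ramp_duration(self) -> float:
        """Duration of one ramp limb, seconds."""
        return (self.v_peak - self.v_start) / self.slope


@dataclass(frozen=True)
class RampHoldSpec:
    """Ramp-and-hold cycle: up-ramp / high hold / down-ramp / low hold.

    Each of the four phases occupies exactly 25% of the cycle, so the cycle
    period is ``4 * (v_high - v_low) / slope``.
    """

    v_low: float = -80.0
    v_high: float = 20.0
    slope: float = 100.0
    n_cycles: int = 30

    def __post_init__(self) -> None:
        if self.v_high <= self.v_low:
            raise InvalidSpecError("v_high must exceed v_low")
        if self.slope <= 0:
            raise InvalidSpecError("ramp slope must be positive")
        if self.n_cycles < 1:
            raise InvalidSpecError("n_cycles must be >= 1")

    @property
    def period(self) -> float:
        """Cycle period, seconds."""
        return 4.0 * (self.v_high - self.v_low) / self.slope


@dataclass(frozen=True)
class PeriodicWaveSpec:
    """Periodic playback of a normalized unitary waveform.

    ``unitary_shape`` is a sequence of ``(phase, amplitude)`` pairs with
    phases strictly increasing in ``[0, 1)`` and amplitudes in ``[0, 1]``
    (0 at the trough, 1 at the peak). Interpolation between points is linear
    and the shape wraps periodically.
    """

    unitary_shape: Sequence[tuple[float, float]] = field(default=())
    period: float = 1.0
    v_trough: float = -60.0
    v_peak: float = -20.0
    n_cycles: int = 20

    def __post_init__(self) -> None:
        pts = np.asarray(self.unitary_shape, dtype=float)
        if pts.size == 0:
            raise InvalidSpecError("unitary_shape must not be empty")
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidSpecError("unitary_shape must be (phase, amp) pairs")
        ph, amp = pts[:, 0], pts[:, 1]
        if np.any(np.diff(ph) <= 0):
            raise InvalidSpecError("unitary_shape phases must be strictly increasing")
        if ph[0] < 0 or ph[-1] >= 1:
            raise InvalidSpecError("unitary_shape phases must lie in [0, 1)")
        if amp.min() < 0 or amp.max() > 1:
            raise InvalidSpecError("unitary_shape amplitudes must lie in [0, 1]")
        if self.period <= 0:
            raise InvalidSpecError("period must be positive")
        if self.v_peak <= self.v_trough:
            raise InvalidSpecError("v_peak must exceed v_trough")
        if self.n_cycles < 1:
            raise InvalidSpecError("n_cycles must be >= 1")


@dataclass
class VoltageCommand:
    """A sampled voltage-command trajectory.

    Attributes
    ----------
    t : ndarray
        Time in seconds, uniform grid starting at 0.
    v : ndarray
        Commanded voltage, mV.
    dt : float
        Sample interval, seconds.
    sweep_boundaries : ndarray of int
        Indices of the first sample of each sweep/cycle.
    meta : dict
        Protocol structure (kind and per-phase sample counts), stored
        explicitly so analysis never re-derives timing from the trace.
    """

    t: np.ndarray
    v: np.ndarray
    dt: float
    sweep_boundaries: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise InvalidSpecError("t and v must have equal length")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_boundaries)

    def sweep_slice(self, i: int) -> slice:
        b = self.sweep_boundaries
        start = int(b[i])
        stop = int(b[i + 1]) if i + 1 < len(b) else len(self.v)
        return slice(start, stop)


def _check_dt(dt: float) -> None:
    if not dt > 0:
        raise InvalidSpecError("dt must be positive")


def _ramp_samples(v0: float, v1: float, n: int) -> np.ndarray:
    # endpoint excluded: the extreme sample belongs to the *next* segment,
    # which starts exactly at v1
    return np.linspace(v0, v1, n, endpoint=False)


def make_triangular_ramp(spec: RampSpec, dt: float = DEFAULT_DT) -> VoltageCommand:
    """Build a repeated symmetric triangular ramp command.

    Per sweep the voltage rises ``v_start -> v_peak`` at ``spec.slope``,
    immediately falls back at the opposite slope, then rests at ``hold_v``
    for ``inter_sweep_hold`` seconds. ``max(v)`` equals ``v_peak`` exactly.
    """
    _check_dt(dt)
    n_ramp = int(round(spec.ramp_duration / dt))
    if n_ramp < 2:
        raise InvalidSpecError("dt too coarse for the requested ramp")
    n_hold = int(round(spec.inter_sweep_hold / dt))
    up = _ramp_samples(spec.v_start, spec.v_peak, n_ramp)
    down = _ramp_samples(spec.v_peak, spec.v_start, n_ramp)
    hold = np.full(n_hold, spec.hold_v)
    sweep = np.concatenate([up, down, hold])
    v = np.tile(sweep, spec.n_sweeps)
    t = np.arange(len(v)) * dt
    boundaries = np.arange(spec.n_sweeps) * len(sweep)
    meta = {
        "kind": "ramp",
        "n_up": n_ramp,
        "n_down": n_ramp,
        "n_hold": n_hold,
        "slope": spec.slope,
        "spec": spec,
    }
    return VoltageCommand(t=t, v=v, dt=dt, sweep_boundaries=boundaries, meta=meta)


def make_ramp_and_hold(spec: RampHoldSpec, dt: float = DEFAULT_DT) -> VoltageCommand:
    """Build a repeated ramp-and-hold command (four equal quarter-phases)."""
    _check_dt(dt)
    n_q = int(round((spec.v_high - spec.v_low) / spec.slope / dt))
    if n_q < 2:
        raise InvalidSpecError("dt too coarse for the requested ramp")
    up = _ramp_samples(spec.v_low, spec.v_high, n_q)
    hold_hi = np.full(n_q, spec.v_high)
    down = _ramp_samples(spec.v_high, spec.v_low, n_q)
    hold_lo = np.full(n_q, spec.v_low)
    cycle = np.concatenate([up, hold_hi, down, hold_lo])
    v = np.tile(cycle, spec.n_cycles)
    t = np.arange(len(v)) * dt
    boundaries = np.arange(spec.n_cycles) * len(cycle)
    meta = {
        "kind": "ramp_hold",
        "n_quarter": n_q,
        "slope": spec.slope,
        "spec": spec,
    }
    return VoltageCommand(t=t, v=v, dt=dt, sweep_boundaries=boundaries, meta=meta)


def make_periodic_waveform(
    spec: PeriodicWaveSpec, dt: float = DEFAULT_DT
) -> VoltageCommand:
    """Tile a unitary waveform over ``n_cycles`` cycles of ``period`` seconds.

    The unitary shape is rescaled in time to ``period`` and in amplitude to
    ``[v_trough, v_peak]``; interpolation between shape points is linear and
    the shape wraps periodically (phase 1 maps back to the first point).
    """
    _check_dt(dt)
    pts = np.asarray(spec.unitary_shape, dtype=float)
    n_cycle = int(round(spec.period / dt))
    if n_cycle < 2:
        raise InvalidSpecError("dt too coarse for the requested period")
    phase = np.arange(n_cycle) / n_cycle
    # wrap the shape for periodic interpolation
    ph = np.concatenate([pts[:, 0], [pts[0, 0] + 1.0]])
    amp = np.concatenate([pts[:, 1], [pts[0, 1]]])
    if pts[0, 0] > 0:
        ph = np.concatenate([[pts[-1, 0] - 1.0], ph])
        amp = np.concatenate([[pts[-1, 1]], amp])
    cyc_amp = np.interp(phase, ph, amp)
    cycle = spec.v_trough + cyc_amp * (spec.v_peak - spec.v_trough)
    v = np.tile(cycle, spec.n_cycles)
    t = np.arange(len(v)) * dt
    boundaries = np.arange(spec.n_cycles) * n_cycle
    meta = {"kind": "wave", "n_cycle": n_cycle, "period": spec.period, "spec": spec}
    return VoltageCommand(t=t, v=v, dt=dt, sweep_boundaries=boundaries, meta=meta)
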