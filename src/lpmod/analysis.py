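"""Measurement pipeline for clamp and neuron simulations.

Mirrors the standard work-up of two-condition voltage-clamp recordings of a
modulator-activated current:

1. subtract the control-condition current from the modulator-condition
   current (the difference current isolates the modulator-activated part);
2. smooth with a Savitzky-Golay filter;
3. average the last sweeps (last 3 for ramps, last 5 for ramp-and-hold and
   waveform protocols);
4. fit each ramp limb's I-V samples with a logistic conductance-activation
   curve  I(V) = g (V - E_rev) / (1 + exp(-(V - V_half)/k))  and read the
   peak inward current I_max and its voltage V_Imax off the fit;
5. fit the normalized per-sweep integral of the current across repeated
   ramp-and-hold sweeps with an exponential decay (slow-inactivation rate);
6. for waveform playback, locate the peak inward current's phase relative to
   the command trough;
7. for neuron runs, detect spikes and reduce them to burst metrics (onset /
   end phase relative to the synaptic-conductance peak, spike count,
   instantaneous spike frequency 1/ISI, duty cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy.signal import savgol_filter

from .clamp import ClampTrace
from .neuron import SynapseSpec
from .stimuli import VoltageCommand

__all__ = [
    "IVFit",
    "DecayFit",
    "PeakResult",
    "BurstMetrics",
    "difference_current",
    "savgol_smooth",
    "average_sweeps",
    "fit_iv_logistic",
    "peak_from_fit",
    "fit_slow_decay",
    "peak_phase",
    "detect_spikes",
    "burst_metrics",
]


def difference_current(i_mod, i_ctrl, t_mod=None, t_ctrl=None):
    """Pointwise modulator-minus-control difference current.

    If time grids are supplied they must match exactly; mismatched grids are
    an error (no silent resampling).
    """
    i_mod = np.asarray(i_mod, dtype=float)
    i_ctrl = np.asarray(i_ctrl, dtype=float)
    if i_mod.shape != i_ctrl.shape:
        raise ValueError("difference_current: traces have different lengths")
    if t_mod is not None and t_ctrl is not None:
        t_mod = np.asarray(t_mod, dtype=float)
        t_ctrl = np.asarray(t_ctrl, dtype=float)
        if t_mod.shape != t_ctrl.shape or not np.array_equal(t_mod, t_ctrl):
            raise ValueError("difference_current: time grids are not aligned")
    return i_mod - i_ctrl


def savgol_smooth(x, poly_order: int = 5, frame_length: int = 101):
    """Savitzky-Golay smoothing (local least-squares polynomial).

    The published work-up uses order 5 with frame 51 for voltage and 101 for
    current traces, and order 3 / frame 901 for waveform-playback currents.
    """
    if frame_length % 2 == 0:
        raise ValueError("frame_length must be odd")
    if frame_length <= poly_order:
        raise ValueError("frame_length must exceed poly_order")
    return savgol_filter(np.asarray(x, dtype=float), frame_length, poly_order)


def average_sweeps(trace, which: str = "last_n", n: int = 3):
    """Pointwise mean over selected equal-length sweeps.

    ``which`` is ``"last_n"`` (mean of the final ``n`` sweeps) or ``"first"``
    (the initial sweep alone). Accepts a :class:`ClampTrace` (averages
    ``i_total``) or a 2-D array (sweeps, samples).
    """
    if isinstance(trace, ClampTrace):
        nsw = trace.n_sweeps
        lengths = {trace.sweep_slice(i).stop - trace.sweep_slice(i).start
                   for i in range(nsw)}
        if len(lengths) != 1:
            raise ValueError("sweeps have unequal lengths")
        sweeps = np.stack([trace.i_total[trace.sweep_slice(i)] for i in range(nsw)])
    else:
        sweeps = np.asarray(trace, dtype=float)
        if sweeps.ndim != 2:
            raise ValueError("expected a (sweeps, samples) array or ClampTrace")
    if which == "first":
        return sweeps[0]
    if which != "last_n":
        raise ValueError(f"unknown selector {which!r}")
    if sweeps.shape[0] < n:
        raise ValueError(f"requested last {n} sweeps of {sweeps.shape[0]}")
    return sweeps[-n:].mean(axis=0)


@dataclass
class IVFit:
    """Logistic I-V fit result: I = g (V-E_rev) / (1 + exp(-(V-V_half)/k)).

    ``g`` in nS, voltages in mV. ``stderr`` holds per-parameter standard
    errors when the covariance estimate is available.
    """

    g: float
    e_rev: float
    v_half: float
    k: float
    rss: float
    converged: bool
    n_points: int = 0
    stderr: dict = field(default_factory=dict)

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        return self.g * (v - self.e_rev) / (1.0 + np.exp(-(v - self.v_half) / self.k))

    def summary(self) -> str:
        rows = [
            ("g (nS)", self.g),
            ("E_rev (mV)", self.e_rev),
            ("V_half (mV)", self.v_half),
            ("k (mV)", self.k),
        ]
        lines = ["Logistic I-V fit", "-" * 34]
        for name, val in rows:
            se = self.stderr.get(name.split()[0])
            lines.append(
                f"{name:<12} {val:>10.4f}" + (f"  +/- {se:.4f}" if se else "")
            )
        lines.append(f"{'RSS':<12} {self.rss:>10.4g}   n={self.n_points}")
        lines.append(f"converged: {self.converged}")
        return "\n".join(lines)


def _iv_residual(params, v, i):
    g = params["g"].value
    e = params["e_rev"].value
    vh = params["v_half"].value
    k = params["k"].value
    return g * (v - e) / (1.0 + np.exp(-(v - vh) / k)) - i


def fit_iv_logistic(v, i) -> IVFit:
    """Nonlinear least-squares logistic fit of (v, i) samples.

    Deterministic: identical inputs give identical outputs. Initialization:
    E_rev from the zero crossing of the most depolarized data (fallback +40),
    g from the slope of the last 20% of points, V_half at the voltage of
    half-maximal |i|, k = 5 mV. Bounds: g in [0, 1000] nS, k in [0.5, 50],
    E_rev in [-20, +80] mV. A null signal yields a degenerate g ~ 0 fit with
    ``converged`` reflecting the optimizer status.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 points for the I-V fit")
    if np.ptp(v) <= 20.0:
        raise ValueError("I-V fit requires points spanning more than 20 mV")
    order = np.argsort(v)
    v, i = v[order], i[order]

    # initialization heuristics
    tail = max(int(0.2 * v.size), 2)
    slope = np.polyfit(v[-tail:], i[-tail:], 1)[0]
    g0 = float(np.clip(abs(slope), 1e-3, 1e3))
    sign_change = np.nonzero(np.diff(np.sign(i[-tail:])))[0]
    if sign_change.size:
        j = sign_change[-1] + v.size - tail
        e0 = float(v[j])
    else:
        e0 = 40.0
    e0 = float(np.clip(e0, -19.0, 79.0))
    jh = int(np.argmin(np.abs(np.abs(i) - 0.5 * np.max(np.abs(i)))))
    vh0 = float(v[jh])

    params = Parameters()
    params.add("g", value=g0, min=0.0, max=1e3)
    params.add("e_rev", value=e0, min=-20.0, max=80.0)
    params.add("v_half", value=vh0, min=v.min() - 50.0, max=v.max() + 50.0)
    params.add("k", value=5.0, min=0.5, max=50.0)
    res = minimize(_iv_residual, params, args=(v, i), method="leastsq")
    p = res.params
    stderr = {
        name: (p[key].stderr if p[key].stderr else None)
        for name, key in (("g", "g"), ("E_rev", "e_rev"),
                          ("V_half", "v_half"), ("k", "k"))
    }
    return IVFit(
        g=p["g"].value,
        e_rev=p["e_rev"].value,
        v_half=p["v_half"].value,
        k=p["k"].value,
        rss=float(np.sum(res.residual**2)),
        converged=bool(res.success),
        n_points=int(v.size),
        stderr={k_: s for k_, s in stderr.items() if s},
    )


@dataclass
class PeakResult:
    """Peak inward current of a fitted I-V curve or a waveform cycle.

    ``i_max`` is signed (negative = inward, the convention throughout);
    ``v_imax`` is the voltage at the peak; ``phase`` (waveform traces) is the
    cycle phase of the peak relative to the command trough, in [0, 1).
    ``at_boundary`` flags a monotone curve whose minimum sits on the edge of
    the searched voltage range.
    """

    i_max: float
    v_imax: Optional[float] = None
    phase: Optional[float] = None
    at_boundary: bool = False


def peak_from_fit(fit: IVFit, v_range=(-80.0, 20.0), grid_mv: float = 0.1) -> PeakResult:
    """Most-negative value of the fitted I-V curve on a 0.1 mV grid."""
    v = np.arange(v_range[0], v_range[1] + grid_mv / 2, grid_mv)
    i = fit.predict(v)
    j = int(np.argmin(i))
    return PeakResult(
        i_max=float(i[j]),
        v_imax=float(v[j]),
        at_boundary=bool(j == 0 or j == v.size - 1),
    )


@dataclass
class DecayFit:
    """Exponential decay fit I(t) = (I0 - Iinf) exp(-lambda t) + Iinf.

    Values are normalized to the first sweep before fitting, so ``i0`` is ~1.
    ``lambda_`` is the decay rate in 1/s; ``degenerate`` marks constant input
    (no identifiable decay, lambda = 0).
    """

    i0: float
    i_inf: float
    lambda_: float
    rss: float
    converged: bool
    degenerate: bool = False

    @property
    def tau_s(self) -> float:
        return np.inf if self.lambda_ == 0 else 1.0 / self.lambda_

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return (self.i0 - self.i_inf) * np.exp(-self.lambda_ * t) + self.i_inf

    def summary(self) -> str:
        return (
            "Exponential decay fit\n"
            f"  I0 = {self.i0:.4f}, Iinf = {self.i_inf:.4f}, "
            f"lambda = {self.lambda_:.4g} 1/s (tau = {self.tau_s:.3g} s)\n"
            f"  RSS = {self.rss:.4g}, converged = {self.converged}, "
            f"degenerate = {self.degenerate}"
        )


def _decay_residual(params, t, y):
    i0 = params["i0"].value
    ii = params["i_inf"].value
    lam = params["lambda_"].value
    return (i0 - ii) * np.exp(-lam * t) + ii - y


def fit_slow_decay(sweep_values, sweep_times) -> DecayFit:
    """Fit the slow multi-sweep decay of repeated-stimulus responses.

    ``sweep_values`` are per-sweep summary values (e.g. each sweep's
    time-integrated current); they are normalized by the first sweep before
    fitting, and ``sweep_times`` (s) are measured from the first sweep.
    """
    y = np.asarray(sweep_values, dtype=float)
    t = np.asarray(sweep_times, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 sweeps for the decay fit")
    if y[0] == 0:
        raise ValueError("first sweep value is zero; cannot normalize")
    y = y / y[0]
    t = t - t[0]
    if np.ptp(y) < 1e-12:
        return DecayFit(i0=y[0], i_inf=y[0], lambda_=0.0, rss=0.0,
                        converged=True, degenerate=True)
    params = Parameters()
    params.add("i0", value=1.0)
    params.add("i_inf", value=float(y[-1]))
    span = max(t[-1], 1e-6)
    params.add("lambda_", value=2.0 / span, min=0.0, max=1e3)
    res = minimize(_decay_residual, params, args=(t, y), method="leastsq")
    p = res.params
    return DecayFit(
        i0=p["i0"].value,
        i_inf=p["i_inf"].value,
        lambda_=p["lambda_"].value,
        rss=float(np.sum(res.residual**2)),
        converged=bool(res.success),
    )


def peak_phase(
    i_trace,
    cmd: VoltageCommand,
    period: float,
    n_cycles_avg: int = 5,
    smooth: bool = True,
) -> PeakResult:
    """Phase of the peak inward current relative to the command trough.

    Per cycle, the trough is the command minimum and the peak the most
    negative (optionally smoothed) current; phase = (t_peak - t_trough) /
    period mod 1, averaged circularly over the last ``n_cycles_avg`` cycles.
    Raises if no inward deflection is present (the recording-exclusion rule).
    """
    i = np.asarray(i_trace, dtype=float)
    if smooth:
        wl = min(901, (i.size // 8) * 2 + 1)
        if wl > 3:
            i = savgol_smooth(i, poly_order=3, frame_length=wl)
    n_per = int(round(period / cmd.dt))
    n_cyc = len(cmd.sweep_boundaries)
    use = range(max(0, n_cyc - n_cycles_avg), n_cyc)
    phases, peaks = [], []
    for c in use:
        sl = cmd.sweep_slice(c)
        seg_i = i[sl]
        seg_v = cmd.v[sl]
        if seg_i.min() >= 0:
            raise ValueError("no inward difference current in cycle %d" % c)
        j_peak = int(np.argmin(seg_i))
        j_trough = int(np.argmin(seg_v))
        phases.append(((j_peak - j_trough) / n_per) % 1.0)
        peaks.append(seg_i[j_peak])
    ang = 2 * np.pi * np.asarray(phases)
    mean_phase = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0
    return PeakResult(i_max=float(np.mean(peaks)), phase=float(mean_phase))


def detect_spikes(v, t=None, threshold: float = -10.0, refractory_ms: float = 2.0):
    """Spike times from upward threshold crossings with a refractory period.

    ``v`` in mV; ``t`` in seconds (defaults to sample indices). Returns an
    array of crossing times.
    """
    v = np.asarray(v, dtype=float)
    if t is None:
        t = np.arange(v.size, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    above = v >= threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = t[crossings]
    kept = [times[0]]
    refr = refractory_ms * 1e-3
    for ti in times[1:]:
        if ti - kept[-1] >= refr:
            kept.append(ti)
    return np.asarray(kept)


@dataclass
class BurstMetrics:
    """Per-cycle burst descriptors relative to the synaptic-conductance peak.

    Phases are in cycle units mod 1 and unwrapped so ``end >= onset`` within
    a cycle (a burst running past the next conductance peak has end > 1).
    ``f_inst`` are instantaneous spike frequencies (1/ISI, Hz) within each
    burst; cycles with no spikes have empty entries.
    """

    cycles: list
    onset_phase: list
    end_phase: list
    spike_count: list
    f_inst: list
    duty_cycle: list

    def mean_onset(self) -> float:
        vals = [p for p in self.onset_phase if p is not None]
        return float(np.mean(vals)) if vals else np.nan

    def mean_end(self) -> float:
        vals = [p for p in self.end_phase if p is not None]
        return float(np.mean(vals)) if vals else np.nan

    def mean_spikes(self) -> float:
        return float(np.mean(self.spike_count))


def burst_metrics(
    spike_times,
    syn: SynapseSpec,
    cycles: Sequence[int],
) -> BurstMetrics:
    """Assign spikes to cycles and reduce to burst metrics.

    Spikes are anchored to the synaptic-conductance peak of each cycle
    (cycle ``k`` spans the interval between peaks ``k`` and ``k+1``); onset
    and end phases are (spike - peak)/period, so they lie in [0, 1) for
    bursts contained in the cycle.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    period = syn.period
    out = BurstMetrics([], [], [], [], [], [])
    for c in cycles:
        anchor = c * period + syn.peak_time
        in_cycle = spikes[(spikes >= anchor) & (spikes < anchor + period)]
        out.cycles.append(int(c))
        if in_cycle.size == 0:
            out.onset_phase.append(None)
            out.end_phase.append(None)
            out.spike_count.append(0)
            out.f_inst.append(np.empty(0))
            out.duty_cycle.append(0.0)
            continue
        onset = (in_cycle[0] - anchor) / period
        end = (in_cycle[-1] - anchor) / period
        out.onset_phase.append(float(onset))
        out.end_phase.append(float(end))
        out.spike_count.append(int(in_cycle.size))
        isi = np.diff(in_cycle)
        out.f_inst.append(1.0 / isi if isi.size else np.empty(0))
        out.duty_cycle.append(float(end - onset))
    return out
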