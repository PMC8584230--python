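"""Synthetic two-condition voltage-clamp recordings with known ground truth.

Real recordings of modulator-activated currents are obtained by clamping the
same cell twice -- in control saline and with the modulator present -- and
subtracting. The generator emulates that structure: a background membrane
current (leak plus a generic, non-modulated delayed-rectifier-like outward
current) is present in both conditions; the modulator condition adds the
clamp-model currents; each condition gets its own additive Gaussian noise
draw and slow baseline drift. The injected modulator current and its
generating parameters ride along as ground truth, so every analysis stage is
testable by parameter recovery without any external data.

A ``modulator_cd`` condition emulates recording in a calcium-channel blocker:
the calcium-carried component of the modulator model is removed and the pool
frozen at rest, leaving the persistent current untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .clamp import ClampModel, ClampTrace, simulate_clamp, sweep_mean_current
from .config import clamp_model_from_config, load_packaged_config
from .gating import ChannelSpec, GateSpec, TauSpec
from .stimuli import VoltageCommand

__all__ = [
    "RecordingConfig",
    "RecordingPair",
    "surrogate_lp_waveform",
    "default_background",
    "generate_recording_pair",
    "cd_mode_check",
    "CdCheckResult",
]


def surrogate_lp_waveform(
    asymmetry: float = 0.6,
    plateau_fraction: float = 0.1,
    trough_fraction: float = 0.4,
):
    """Parametric one-cycle stand-in for a bursting neuron's slow wave.

    The shape (normalized phase, normalized amplitude pairs) has a trough
    plateau at amplitude 0 (the inhibited phase, ``trough_fraction`` of the
    cycle, split across phase 0), a linear rising limb, a depolarized
    plateau at amplitude 1 (``plateau_fraction``) and a falling limb back to
    the trough. ``asymmetry`` splits the remaining time between rise
    (fraction ``asymmetry``) and fall. The defaults mimic a follower neuron
    inhibited for nearly half its cycle with a gradual rebound
    depolarization and a brief burst plateau. Played at period P, the
    maximum depolarization rate scales exactly as 1/P.
    """
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must be in (0, 1)")
    if not 0.0 < trough_fraction < 0.9:
        raise ValueError("trough_fraction must be in (0, 0.9)")
    if not 0.0 < plateau_fraction < 1.0 - trough_fraction:
        raise ValueError("plateau_fraction too large for the trough")
    half_tr = trough_fraction / 2.0
    free = 1.0 - plateau_fraction - trough_fraction
    rise = asymmetry * free
    p0 = half_tr
    p1 = p0 + rise
    p2 = p1 + plateau_fraction
    p3 = 1.0 - half_tr
    return [(0.0, 0.0), (p0, 0.0), (p1, 1.0), (p2, 1.0), (p3, 0.0)]


def default_background() -> ClampModel:
    """Generic non-modulated background membrane: leak + delayed rectifier.

    Exact parameters are irrelevant to the pipeline (the two-condition
    subtraction removes them); they exist so the subtraction step is
    meaningfully exercised.
    """
    leak = ChannelSpec(name="I_leak", gbar=10.0, e_rev=-60.0, a=1, b=0)
    kdr = ChannelSpec(
        name="I_Kdr",
        gbar=50.0,
        e_rev=-80.0,
        a=4,
        b=0,
        m_gate=GateSpec(form="logistic", v_half=-20.0, k=10.0),
        m_tau=TauSpec(base=20.0),
    )
    return ClampModel(channels=[leak, kdr], mi_t_mode="ohmic")


@dataclass
class RecordingConfig:
    """Everything needed to generate one two-condition recording pair.

    ``noise_sd`` (nA) defaults to 2% of the peak ground-truth modulator
    current; ``drift_amp`` likewise defaults to 1% of it. The seed fully
    determines the output.
    """

    cmd: VoltageCommand
    modulator: Optional[ClampModel] = None
    background: Optional[ClampModel] = None
    noise_sd: Optional[float] = None
    drift_amp: Optional[float] = None
    drift_period_s: float = 30.0
    drift_linear: float = 0.0  # nA/s
    seed: int = 0
    condition: str = "modulator"

    def __post_init__(self) -> None:
        if self.condition not in ("control", "modulator", "modulator_cd"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class RecordingPair:
    """Control and condition traces plus ground truth."""

    t: np.ndarray
    v: np.ndarray
    control: np.ndarray  # nA
    condition: np.ndarray  # nA
    truth: np.ndarray  # noiseless modulator current, nA
    truth_trace: ClampTrace
    config: RecordingConfig
    noise_sd: float
    drift_amp: float

    @property
    def difference(self) -> np.ndarray:
        return self.condition - self.control


def _cd_model(model: ClampModel) -> ClampModel:
    """Remove the calcium-carried component and freeze the pool at rest."""
    chans = [ch for ch in model.channels if not (ch.ghk_mode or ch.ca_permeable)]
    return ClampModel(channels=chans, mi_t_mode="ohmic", pool=None)


def generate_recording_pair(config: RecordingConfig) -> RecordingPair:
    """Simulate the pair of recordings for ``config``.

    control   = background + noise_c + drift_c
    condition = background + modulator currents + noise_m + drift_m

    with independent noise draws and independent drift phases per condition
    (slow sinusoid plus optional linear trend). With noise and drift at zero
    the difference equals the ground-truth modulator current exactly.
    """
    cmd = config.cmd
    modulator = config.modulator
    if modulator is None:
        modulator = clamp_model_from_config(
            load_packaged_config("table2_clamp_model"), mi_t_mode="ghk_ca"
        )
    if config.condition == "modulator_cd":
        modulator = _cd_model(modulator)
    background = config.background or default_background()

    bg = simulate_clamp(cmd, background).i_total
    truth_trace = simulate_clamp(cmd, modulator)
    truth = truth_trace.i_total

    peak = float(np.max(np.abs(truth))) or 1.0
    noise_sd = config.noise_sd if config.noise_sd is not None else 0.02 * peak
    drift_amp = config.drift_amp if config.drift_amp is not None else 0.01 * peak

    rng = np.random.default_rng(config.seed)
    t = cmd.t

    def drift():
        phase = rng.uniform(0, 2 * np.pi)
        return (
            drift_amp * np.sin(2 * np.pi * t / config.drift_period_s + phase)
            + config.drift_linear * t
        )

    # draw order is fixed: control drift, control noise, condition drift,
    # condition noise -- regeneration with the same seed is bit-identical
    control = bg + drift() + rng.normal(0.0, noise_sd, t.size)
    condition = bg + truth + drift() + rng.normal(0.0, noise_sd, t.size)
    return RecordingPair(
        t=t,
        v=cmd.v,
        control=control,
        condition=condition,
        truth=truth,
        truth_trace=truth_trace,
        config=config,
        noise_sd=noise_sd,
        drift_amp=drift_amp,
    )


@dataclass
class CdCheckResult:
    """Comparison of normal-saline vs calcium-blocked synthetic recordings."""

    normal: RecordingPair
    cd: RecordingPair
    #: steady-state / initial-state sweep-mean ratio per condition
    decay_ratio_normal: float
    decay_ratio_cd: float


def cd_mode_check(config: RecordingConfig) -> CdCheckResult:
    """Generate paired recordings with and without the calcium component.

    Returns both pairs together with each condition's steady/initial
    sweep-mean ratio of the true modulator current (mean of the last five
    sweeps over the first sweep): ~1 in the calcium-blocked mode, < 1 when
    calcium accumulation inactivates the transient current.
    """
    normal = generate_recording_pair(replace(config, condition="modulator"))
    cd = generate_recording_pair(replace(config, condition="modulator_cd"))

    def ratio(pair: RecordingPair) -> float:
        means = sweep_mean_current(pair.truth_trace)
        if means.shape[0] < 6:
            raise ValueError("decay ratio needs at least 6 sweeps")
        return float(np.mean(means[-5:]) / means[0])

    return CdCheckResult(
        normal=normal,
        cd=cd,
        decay_ratio_normal=ratio(normal),
        decay_ratio_cd=ratio(cd),
    )
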