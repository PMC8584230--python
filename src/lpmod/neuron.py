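"""Two-compartment model of the bursting LP neuron under periodic inhibition.

The neuron is reduced to a soma/neurite compartment (leak, transient
potassium I_A, hyperpolarization-activated I_h, GHK calcium current I_Ca,
calcium-dependent potassium I_KCa, and the two modulator-activated currents
I_MI and I_MI-T) and an axon compartment (leak, I_Na, I_K), coupled by a
fixed conductance. The cell receives a symmetric triangular inhibitory
conductance (reversal -80 mV) whose active window opens at the start of each
cycle; it bursts on rebound from this inhibition.

Three modulator configurations are shipped for the frequency-dependence
comparison: the reference model (I_MI + calcium-permeable I_MI-T), an
I_MI-only model, and an I_MI-T-only model, with maximal conductances chosen
so all three fire the same number of spikes per burst at 1 Hz drive.

Numerics: voltages advance by a semi-implicit step (backward Euler on the
linear conductance/coupling/synaptic terms with gates frozen within the
step), gates by exponential Euler, at dt = 0.025 ms by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .clamp import IntegrationError, pack_channels
from .config import load_packaged_config, neuron_model_from_config
from .gating import CalciumPoolSpec, ChannelSpec

__all__ = [
    "CompartmentSpec",
    "SynapseSpec",
    "NeuronModel",
    "NeuronTrace",
    "synaptic_conductance",
    "simulate_neuron",
    "table3_neuron_model",
    "fig9_variants",
    "VARIANT_NAMES",
]

#: Modulator-configuration names, reference first.
VARIANT_NAMES = ("mi_plus_mit_ca", "mi_plus_mit_noca", "mi_only", "mit_ca_only")


@dataclass
class CompartmentSpec:
    """A cylindrical compartment; membrane area is the lateral surface only."""

    name: str
    diameter_um: float = 200.0
    length_um: float = 200.0
    cm_uf_per_cm2: float = 1.0
    channels: list[ChannelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError("compartment geometry must be positive")

    @property
    def area_mm2(self) -> float:
        """Lateral cylinder surface pi*d*L in mm^2 (no end caps)."""
        return math.pi * self.diameter_um * self.length_um * 1e-6

    @property
    def area_m2(self) -> float:
        return self.area_mm2 * 1e-6

    @property
    def capacitance_nf(self) -> float:
        # uF/cm^2 * cm^2 -> uF -> nF
        return self.cm_uf_per_cm2 * (self.area_mm2 * 1e-2) * 1e3


@dataclass(frozen=True)
class SynapseSpec:
    """Symmetric triangular inhibitory conductance waveform.

    The active window occupies the first ``duty`` fraction of each cycle;
    the conductance rises linearly from 0 to ``gmax`` (uS/mm^2) over the
    first half of the window and falls back over the second half, peaking at
    the window midpoint. Phase 0 for burst metrics is the conductance peak.
    """

    gmax: float = 1.0  # uS/mm^2
    e_rev: float = -80.0  # mV
    duty: float = 0.5
    period: float = 1.0  # s

    def __post_init__(self) -> None:
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must be in (0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def peak_time(self) -> float:
        """Time of the conductance peak within a cycle, seconds."""
        return self.duty * self.period / 2.0


def synaptic_conductance(t, spec: SynapseSpec):
    """Triangular synaptic conductance (uS/mm^2) at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    tc = np.mod(t, spec.period)
    half = spec.peak_time
    g = np.zeros_like(tc)
    rising = tc < half
    falling = (~rising) & (tc < 2 * half)
    g[rising] = spec.gmax * tc[rising] / half
    g[falling] = spec.gmax * (2.0 - tc[falling] / half)
    return g


@dataclass
class NeuronModel:
    """The coupled two-compartment cell."""

    soma: CompartmentSpec
    axon: CompartmentSpec
    coupling_us: float = 0.15
    pool: CalciumPoolSpec = field(default_factory=CalciumPoolSpec)
    variant: str = "base"
    v_init: float = -55.0
    synapse_defaults: Optional[SynapseSpec] = None

    def __post_init__(self) -> None:
        if self.coupling_us <= 0:
            raise ValueError("coupling conductance must be positive")

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.soma.channels + self.axon.channels]


@dataclass
class NeuronTrace:
    """Recorded model activity.

    Voltages in mV, calcium in mM, synaptic conductance in uS/mm^2;
    ``i_per_channel`` (nA, total per compartment membrane) is present only
    when requested at simulation time.
    """

    t: np.ndarray  # s
    v_soma: np.ndarray
    v_axon: np.ndarray
    ca: np.ndarray
    g_syn: np.ndarray
    channel_names: list[str]
    period: float
    dt: float  # recording interval, s
    i_per_channel: Optional[np.ndarray] = None

    def channel(self, name: str) -> np.ndarray:
        if self.i_per_channel is None:
            raise ValueError("per-channel currents were not recorded")
        return self.i_per_channel[self.channel_names.index(name)]


def simulate_neuron(
    model: NeuronModel,
    syn: SynapseSpec,
    n_cycles: int = 20,
    dt_ms: float = 0.025,
    record_stride: int = 1,
    record_currents: bool = False,
) -> NeuronTrace:
    """Drive the model with periodic inhibition for ``n_cycles`` cycles.

    The run starts from rest (both compartments at ``model.v_init``, gates at
    steady state, calcium at its resting value); the first cycles absorb the
    transient and analysis conventionally uses the last four.
    """
    if dt_ms <= 0 or dt_ms > 0.05:
        raise ValueError("dt_ms must be in (0, 0.05] for stable spikes")
    channels = model.soma.channels + model.axon.channels
    comp_index = {c.name: 0 for c in model.soma.channels}
    comp_index.update({c.name: 1 for c in model.axon.channels})
    P = pack_channels(channels, comp_index=comp_index)
    # per-area densities -> absolute conductances (uS); GHK areas are set in
    # the spec already (clamp-style area_um2 = compartment area)
    areas = np.array([model.soma.area_m2, model.axon.area_m2])
    for i, ch in enumerate(channels):
        if not ch.ghk_mode:
            P[i, K.AMP] = ch.gbar * (
                model.soma.area_mm2 if comp_index[ch.name] == 0 else model.axon.area_mm2
            )
    c_nf = np.array([model.soma.capacitance_nf, model.axon.capacitance_nf])
    period_ms = syn.period * 1e3
    n_steps = int(round(n_cycles * period_ms / dt_ms))
    pool = model.pool
    out = K.neuron_kernel(
        n_steps, dt_ms, P,
        c_nf, model.coupling_us, areas,
        syn.gmax * model.soma.area_mm2, syn.e_rev, period_ms, syn.duty,
        pool.ca_inf, pool.tau_ca_ms, pool.effective_flux_coeff, pool.floor,
        model.v_init, record_stride, record_currents,
    )
    t_tr, vs, va, ca, gsyn, cur, err = out
    if err >= 0:
        raise IntegrationError(
            f"non-finite state at step {err} (t={err * dt_ms:.3f} ms)"
        )
    return NeuronTrace(
        t=t_tr * 1e-3,
        v_soma=vs,
        v_axon=va,
        ca=ca,
        g_syn=gsyn / model.soma.area_mm2,
        channel_names=[c.name for c in channels],
        period=syn.period,
        dt=dt_ms * record_stride * 1e-3,
        i_per_channel=cur if record_currents else None,
    )


def table3_neuron_model(
    variant: Optional[str] = None,
    g_mi: Optional[float] = None,
    g_mit: Optional[float] = None,
) -> NeuronModel:
    """The shipped LP neuron model, optionally as a named variant."""
    doc = load_packaged_config("table3_neuron_model")
    return neuron_model_from_config(doc, variant=variant, g_mi=g_mi, g_mit=g_mit)


def fig9_variants() -> dict[str, NeuronModel]:
    """The three spike-matched modulator configurations.

    Reference (``mi_plus_mit_ca``): g_MI = 0.227, g_MI-T = 2.27 uS/mm^2 with
    calcium-permeable I_MI-T; ``mi_only``: g_MI = 0.995 alone;
    ``mit_ca_only``: g_MI-T = 3.63 alone.
    """
    return {
        name: table3_neuron_model(variant=name)
        for name in ("mi_plus_mit_ca", "mi_only", "mit_ca_only")
    }
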