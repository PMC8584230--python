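"""Kinetic core: gates, time constants, ohmic and GHK currents, calcium pool.

Every voltage-gated current is written as

    I = gbar * m^a * h^b * (V - E)            (ohmic channels)

with first-order gate relaxation ``dx/dt = (x_inf(V) - x) / tau_x(V)``,
integrated by exponential Euler (exact for frozen voltage, unconditionally
stable, keeps gates in [0, 1]).

Calcium-carried currents use the Goldman-Hodgkin-Katz constant-field flux

    i = P * pref * zeta * ([Ca]out e^{-zeta} - [Ca]in) / (e^{-zeta} - 1),
    zeta = z F V / (R T),

returned as a current *density* in A/m^2 with concentrations in mol/m^3
(numerically equal to mM) and permeability in m/s; this is the unit system in
which the microdomain calcium balance

    d[Ca]in/dt = ([Ca]inf - [Ca]in)/tau_Ca - P1/(z F vol P) * i

is dimensionally exact. ``pref`` is ``F`` (the printed form, default) or
``z*F`` (the conventional form), selectable per GhkSpec.

Gate parameterizations (half-voltages, scales, time-constant shapes) are data,
not code: the shipped configurations carry the full clamp-current and neuron
models, and any alternative reading of a published expression is a config
change only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import constants

__all__ = [
    "GateSpec",
    "TauSpec",
    "ChannelSpec",
    "GhkSpec",
    "CalciumPoolSpec",
    "CalciumState",
    "InvalidStateError",
    "logistic_gate",
    "tau_eval",
    "gate_step",
    "ohmic_current",
    "ghk_current",
    "ghk_reversal",
    "calcium_step",
    "ca_inactivation",
    "FARADAY",
    "GAS_CONSTANT",
]

FARADAY = constants.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = constants.R  # J/(mol K)

#: |zeta| below which the GHK flux is evaluated by series expansion.
GHK_ZETA_EPS = 1e-4


class InvalidStateError(ValueError):
    """A dynamical state violates its invariants (e.g. non-positive [Ca])."""


@dataclass(frozen=True)
class GateSpec:
    """Steady-state parameterization of one gating variable.

    ``form`` selects the functional family:

    * ``"logistic"`` -- S((x - v_half)/k) with S the logistic sigmoid; the
      sign of ``k`` encodes activation (k > 0) vs inactivation (k < 0).
    * ``"tanh_plus"`` -- positive part of tanh((x - v_half)/k); used for
      hyperpolarization-activated gates (k < 0).
    * ``"hill"`` -- 1 / (1 + (ca / ca_half)^hill), a decreasing Hill function
      of intracellular calcium.

    ``depends`` names the controlling variable (``"v"`` in mV or ``"ca"`` in
    mM). ``floor_offset`` subtracts a constant before rectifying at zero
    (rectified gates of the form [S(.) - r]+). ``ca_gain_kd``, if set, applies
    an additional multiplicative saturation factor ca/(ca + kd) (calcium-
    facilitated activation, e.g. the calcium-dependent potassium current).
    """

    form: str = "logistic"
    v_half: float = 0.0
    k: float = 1.0
    floor_offset: float = 0.0
    depends: str = "v"
    ca_half: float = 0.0
    hill: float = 1.0
    ca_gain_kd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "tanh_plus", "hill"):
            raise ValueError(f"unknown gate form {self.form!r}")
        if self.form != "hill" and self.k == 0:
            raise ValueError("gate scale k must be nonzero")
        if self.form == "hill" and self.ca_half <= 0:
            raise ValueError("hill gate requires ca_half > 0")

    def steady_state(self, v, ca=None):
        """Evaluate x_inf at voltage ``v`` (mV) and calcium ``ca`` (mM)."""
        if self.form == "hill":
            return ca_inactivation(ca, self)
        x = ca if self.depends == "ca" else v
        arg = (np.asarray(x, dtype=float) - self.v_half) / self.k
        if self.form == "logistic":
            out = _logistic(arg)
        else:  # tanh_plus
            out = np.maximum(np.tanh(arg), 0.0)
        if self.floor_offset:
            out = np.maximum(out - self.floor_offset, 0.0)
        if self.ca_gain_kd is not None:
            out = out * np.asarray(ca, dtype=float) / (
                np.asarray(ca, dtype=float) + self.ca_gain_kd
            )
        return out


def _logistic(x):
    # numerically saturating logistic
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    if scalar:
        return float(out[0])
    return out


@dataclass(frozen=True)
class TauSpec:
    """Voltage-dependent time constant, milliseconds.

    tau(v) = base + sech_amp * sech((v - sech_v0)/sech_scale)
                  + log_amp * S((v - log_v0)/log_scale)

    Constant, base+sech, base+logistic and base+sech+logistic forms are all
    expressed by zeroing the unused amplitudes. ``log_scale`` may be negative
    (falling logistic term).
    """

    base: float = 1.0
    sech_amp: float = 0.0
    sech_v0: float = 0.0
    sech_scale: float = 1.0
    log_amp: float = 0.0
    log_v0: float = 0.0
    log_scale: float = 1.0

    def __call__(self, v):
        return tau_eval(v, self)


def logistic_gate(v, spec: GateSpec):
    """Steady-state gate value in [0, 1] at voltage ``v`` (or calcium)."""
    return spec.steady_state(v, ca=None if spec.depends == "v" else v)


def tau_eval(v, spec: TauSpec):
    """Evaluate a TauSpec at voltage ``v`` (mV); strictly positive, ms."""
    v = np.asarray(v, dtype=float)
    tau = np.full_like(v, spec.base, dtype=float)
    if spec.sech_amp:
        with np.errstate(over="ignore"):  # cosh overflow -> sech term 0
            tau = tau + spec.sech_amp / np.cosh((v - spec.sech_v0) / spec.sech_scale)
    if spec.log_amp:
        tau = tau + spec.log_amp * _logistic((v - spec.log_v0) / spec.log_scale)
    if tau.ndim == 0:
        return float(tau)
    return tau


def gate_step(x, v, dt, gate: GateSpec, tau: TauSpec, ca=None):
    """One exponential-Euler gate update; exact for constant ``v``.

    x' = x_inf + (x - x_inf) * exp(-dt / tau(v)), with dt in ms.
    """
    x_inf = gate.steady_state(v, ca=ca)
    t = tau_eval(v, tau)
    return x_inf + (x - x_inf) * np.exp(-dt / t)


def ohmic_current(v, m, h, spec: "ChannelSpec"):
    """Signed ohmic channel current gbar * m^a * h^b * (v - e_rev).

    Negative values are inward by convention (v below the reversal with
    positive conductance gives a negative current).
    """
    g = spec.gbar * np.asarray(m, dtype=float) ** spec.a
    if spec.b:
        g = g * np.asarray(h, dtype=float) ** spec.b
    return g * (np.asarray(v, dtype=float) - spec.e_rev)


@dataclass(frozen=True)
class GhkSpec:
    """Constant-field calcium-flux parameters.

    ``p_ca`` is stored with an explicit unit tag and normalized to m/s by
    :meth:`p_mps`; accepted units are ``"cm/s"`` and ``"nm/ms"``.
    ``prefactor_mode`` selects the printed ``"f_zeta"`` form (default) or the
    conventional ``"zf_zeta"`` form. ``area_um2`` converts flux density to a
    total current for point (non-compartment) models.
    """

    p_ca: float = 0.014
    p_unit: str = "cm/s"
    z: int = 2
    temperature_k: float = 283.15
    ca_out: float = 13.0  # mM
    prefactor_mode: str = "f_zeta"
    area_um2: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")
        if self.ca_out <= 0:
            raise ValueError("ca_out must be positive")
        if self.p_unit not in ("cm/s", "nm/ms"):
            raise ValueError(f"unknown permeability unit {self.p_unit!r}")
        if self.prefactor_mode not in ("f_zeta", "zf_zeta"):
            raise ValueError(f"unknown prefactor mode {self.prefactor_mode!r}")

    @property
    def p_mps(self) -> float:
        """Permeability in m/s."""
        if self.p_unit == "cm/s":
            return self.p_ca * 1e-2
        return self.p_ca * 1e-6  # nm/ms

    @property
    def zeta_per_mv(self) -> float:
        """zeta per mV of membrane potential (dimensionless/mV)."""
        return self.z * FARADAY * 1e-3 / (GAS_CONSTANT * self.temperature_k)


def ghk_flux_density(v, ca_in, ghk: GhkSpec):
    """GHK current density (A/m^2) per unit gating at voltage ``v`` (mV).

    Concentrations in mM (== mol/m^3). The removable singularity at zeta = 0
    is evaluated by series expansion for |zeta| < 1e-4; the density is
    continuous and vanishes exactly at the Nernst potential.
    """
    scalar = np.ndim(v) == 0 and np.ndim(ca_in) == 0
    v = np.atleast_1d(np.asarray(v, dtype=float))
    ca_in = np.atleast_1d(np.asarray(ca_in, dtype=float))
    if np.any(ca_in <= 0):
        raise InvalidStateError("ca_in must be positive")
    zeta = ghk.zeta_per_mv * v
    pref = ghk.p_mps * FARADAY * (ghk.z if ghk.prefactor_mode == "zf_zeta" else 1.0)
    zb, cb = np.broadcast_arrays(zeta, ca_in)
    small = np.abs(zb) < GHK_ZETA_EPS
    out = np.empty(zb.shape, dtype=float)
    zs = zb[~small]
    # zeta/(1 - e^{-zeta}) * (ci - co e^{-zeta}); outward positive
    out[~small] = zs / (1.0 - np.exp(-zs)) * (cb[~small] - ghk.ca_out * np.exp(-zs))
    zt = zb[small]
    series = 1.0 + zt / 2.0 + zt * zt / 12.0  # zeta/(1-e^-zeta) expansion
    out[small] = series * (cb[small] - ghk.ca_out * np.exp(-zt))
    out = pref * out
    if scalar:
        return float(out[0])
    return out


def ghk_current(v, m, h, ca_in, ghk: GhkSpec, a: int = 3, b: int = 1):
    """Total GHK current in nA over the spec's effective area.

    ``I = m^a * h^b * density(v, ca_in) * area``; inward currents (external
    calcium entering) are negative for ``v`` below the Nernst potential.
    """
    dens = ghk_flux_density(v, ca_in, ghk)
    gating = np.asarray(m, dtype=float) ** a
    if b:
        gating = gating * np.asarray(h, dtype=float) ** b
    return gating * dens * ghk.area_um2 * 1e-12 * 1e9  # A/m^2 * m^2 -> nA


def ghk_reversal(ca_in, ghk: GhkSpec):
    """Nernst/GHK reversal potential in mV: (RT/zF) ln(ca_out/ca_in)."""
    ca_in = np.asarray(ca_in, dtype=float)
    return np.log(ghk.ca_out / ca_in) / ghk.zeta_per_mv


@dataclass(frozen=True)
class CalciumPoolSpec:
    """Microdomain calcium pool.

    d[Ca]/dt = ([Ca]inf - [Ca])/tau_ca - P1/(z F vol P) * i_ca

    with ``i_ca`` the calcium current *density* in A/m^2. ``p_total`` carries
    the same unit tag convention as GhkSpec. The flux coefficient
    ``P1/(z F vol P)`` has units mol/(C m), so the product with A/m^2 is
    mol/(m^3 s) = mM/s exactly.
    """

    ca_inf: float = 0.02  # mM
    tau_ca_ms: float = 12_000.0
    vol_um3: float = 6.49
    p1_um3_per_s: float = 1.1675
    p_total: float = 0.0369
    p_total_unit: str = "cm/s"
    z: int = 2
    floor: float = 1e-6  # mM
    #: dimensionless scaling of the flux coefficient (see methods note);
    #: resolves the unit ambiguity of the printed microdomain constants
    flux_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ca_inf <= 0 or self.tau_ca_ms <= 0 or self.vol_um3 <= 0:
            raise ValueError("pool parameters must be positive")
        if self.p_total_unit not in ("cm/s", "nm/ms"):
            raise ValueError(f"unknown permeability unit {self.p_total_unit!r}")

    @property
    def p_total_mps(self) -> float:
        if self.p_total_unit == "cm/s":
            return self.p_total * 1e-2
        return self.p_total * 1e-6

    @property
    def flux_coeff(self) -> float:
        """P1/(z F vol P) in mol/(C m) == (mM/s) per (A/m^2)."""
        p1 = self.p1_um3_per_s * 1e-18  # m^3/s
        vol = self.vol_um3 * 1e-18  # m^3
        return p1 / (self.z * FARADAY * vol * self.p_total_mps)

    @property
    def effective_flux_coeff(self) -> float:
        """Flux coefficient after the calibrated dimensionless scaling."""
        return self.flux_coeff * self.flux_scale


@dataclass
class CalciumState:
    """Intracellular calcium concentration, mM."""

    ca_in: float = 0.02

    def __post_init__(self) -> None:
        if self.ca_in <= 0:
            raise InvalidStateError("ca_in must be positive")


def calcium_step(
    state: CalciumState, i_ca_density: float, dt: float, pool: CalciumPoolSpec
) -> CalciumState:
    """Advance the calcium pool one step of ``dt`` ms.

    ``i_ca_density`` is the instantaneous calcium current density (A/m^2,
    negative = inward = calcium influx). The update is exponential Euler on
    the linear relaxation with the flux term folded into the target, exact
    for a frozen current. Concentrations driven to or below zero are clamped
    at ``pool.floor`` with a warning.
    """
    if state.ca_in <= 0:
        raise InvalidStateError("ca_in must be positive")
    # mM/ms influx from the current density
    influx = -pool.effective_flux_coeff * i_ca_density * 1e-3
    target = pool.ca_inf + pool.tau_ca_ms * influx
    ca = target + (state.ca_in - target) * np.exp(-dt / pool.tau_ca_ms)
    if ca <= pool.floor:
        warnings.warn(
            "calcium pool hit its floor; clamping at %.1e mM" % pool.floor,
            RuntimeWarning,
            stacklevel=2,
        )
        ca = pool.floor
    return replace(state, ca_in=float(ca))


def ca_inactivation(ca_in, spec: GateSpec):
    """Hill-type calcium-dependent inactivation in (0, 1].

    h_inf([Ca]) = 1 / (1 + ([Ca]/ca_half)^hill); decreasing in [Ca].
    """
    ca = np.asarray(ca_in, dtype=float)
    if np.any(ca < 0):
        raise InvalidStateError("ca_in must be nonnegative")
    out = 1.0 / (1.0 + (ca / spec.ca_half) ** spec.hill)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated membrane current.

    ``gbar`` is an absolute conductance (nS) for the clamp model and a
    per-area density (uS/mm^2) for the neuron model; the models do the
    area bookkeeping. For GHK-mode channels ``gbar`` is unused and the
    amplitude comes from the GhkSpec.
    """

    name: str
    gbar: float
    e_rev: float
    a: int = 1
    b: int = 0
    m_gate: Optional[GateSpec] = None
    m_tau: Optional[TauSpec] = None
    h_gate: Optional[GateSpec] = None
    h_tau: Optional[TauSpec] = None
    ghk_mode: bool = False
    ca_permeable: bool = False
    ca_inactivated: bool = False
    ghk: Optional[GhkSpec] = None
    #: instantaneous multiplicative calcium inactivation (GHK clamp variant)
    ca_h_gate: Optional[GateSpec] = None

    def __post_init__(self) -> None:
        if self.a < 1 or int(self.a) != self.a:
            raise ValueError("activation exponent a must be a positive integer")
        if self.b not in (0, 1):
            raise ValueError("inactivation exponent b must be 0 or 1")
        if self.b == 1 and self.h_gate is None:
            raise ValueError("b = 1 requires an h gate")
        if self.ghk_mode and self.ghk is None:
            raise ValueError("ghk_mode requires a GhkSpec")
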