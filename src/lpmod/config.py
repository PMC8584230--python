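"""YAML configuration schema: model, protocol and run documents.

All published model constants (gating parameterizations, conductances,
geometry, calcium-pool parameters, variant overrides) live in the shipped
YAML files under ``lpmod/configs``; code never hard-codes them. Documents are
validated strictly -- unknown keys are rejected with the offending path.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Optional

import yaml

from .gating import CalciumPoolSpec, ChannelSpec, GateSpec, GhkSpec, TauSpec

__all__ = [
    "ConfigError",
    "load_config",
    "load_packaged_config",
    "clamp_model_from_config",
    "neuron_model_from_config",
    "protocol_from_config",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration document violates the schema."""


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path}")


def load_config(path) -> dict:
    """Load a YAML config document from a file path."""
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return doc


def load_packaged_config(name: str) -> dict:
    """Load one of the shipped default configs (e.g. ``table2_clamp_model``)."""
    ref = resources.files("lpmod") / "configs" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def config_hash(doc: dict) -> str:
    """Deterministic hash of a config document (for run manifests)."""
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# -- gate / tau / channel builders -------------------------------------------

_GATE_KEYS = {"form", "v_half", "k", "floor_offset", "depends", "ca_half",
              "hill", "ca_gain_kd"}
_TAU_KEYS = {"base", "sech_amp", "sech_v0", "sech_scale", "log_amp", "log_v0",
             "log_scale"}


def _gate(d: Optional[dict], path: str) -> Optional[GateSpec]:
    if d is None:
        return None
    _check_keys(d, _GATE_KEYS, path)
    return GateSpec(**d)


def _tau(d: Optional[dict], path: str) -> Optional[TauSpec]:
    if d is None:
        return None
    _check_keys(d, _TAU_KEYS, path)
    return TauSpec(**d)


_GHK_KEYS = {"p_ca", "p_unit", "z", "temperature_k", "ca_out_mm", "prefactor",
             "area_um2", "ca_h_inf"}


def _ghk(d: dict, path: str, area_um2: Optional[float] = None) -> GhkSpec:
    _check_keys(d, _GHK_KEYS, path)
    return GhkSpec(
        p_ca=d["p_ca"],
        p_unit=d.get("p_unit", "cm/s"),
        z=d.get("z", 2),
        temperature_k=d.get("temperature_k", 283.15),
        ca_out=d.get("ca_out_mm", 13.0),
        prefactor_mode=d.get("prefactor", "f_zeta"),
        area_um2=area_um2 if area_um2 is not None else d.get("area_um2", 1.0),
    )


_POOL_KEYS = {"ca_inf_mm", "tau_ca_ms", "vol_um3", "p1_um3_per_s", "p_total",
              "p_total_unit", "floor_mm", "flux_scale"}


def _pool(d: dict, path: str) -> CalciumPoolSpec:
    _check_keys(d, _POOL_KEYS, path)
    return CalciumPoolSpec(
        ca_inf=d.get("ca_inf_mm", 0.02),
        tau_ca_ms=d.get("tau_ca_ms", 12000.0),
        vol_um3=d.get("vol_um3", 6.49),
        p1_um3_per_s=d.get("p1_um3_per_s", 1.1675),
        p_total=d.get("p_total", 0.0369),
        p_total_unit=d.get("p_total_unit", "cm/s"),
        floor=d.get("floor_mm", 1e-6),
        flux_scale=d.get("flux_scale", 1.0),
    )


_CLAMP_CH_KEYS = {"name", "gbar_ns", "e_rev_mv", "a", "b", "m_inf", "tau_m",
                  "h_inf", "tau_h"}


def clamp_model_from_config(doc: dict, mi_t_mode: Optional[str] = None):
    """Build a :class:`~lpmod.clamp.ClampModel` from a config document.

    ``mi_t_mode`` overrides the document's mode. In ``ghk_ca`` mode the
    transient channel (``I_MI_T``) is converted to a GHK calcium current with
    instantaneous calcium-dependent inactivation, fed into the pool.
    """
    from .clamp import ClampModel

    m = doc.get("model", doc)
    if m.get("kind") != "clamp":
        raise ConfigError("not a clamp model config")
    mode = mi_t_mode or m.get("mi_t_mode", "ohmic")
    channels = []
    for i, chd in enumerate(m["channels"]):
        path = f"model.channels[{i}]"
        _check_keys(chd, _CLAMP_CH_KEYS, path)
        ch = ChannelSpec(
            name=chd["name"],
            gbar=chd["gbar_ns"],
            e_rev=chd["e_rev_mv"],
            a=chd.get("a", 1),
            b=chd.get("b", 0),
            m_gate=_gate(chd.get("m_inf"), path + ".m_inf"),
            m_tau=_tau(chd.get("tau_m"), path + ".tau_m"),
            h_gate=_gate(chd.get("h_inf"), path + ".h_inf"),
            h_tau=_tau(chd.get("tau_h"), path + ".tau_h"),
        )
        if mode == "ghk_ca" and ch.name == "I_MI_T":
            gd = m["ghk"]
            ghk = _ghk(gd, "model.ghk")
            ca_h = gd.get("ca_h_inf")
            ch = ChannelSpec(
                name=ch.name,
                gbar=0.0,
                e_rev=0.0,
                a=ch.a,
                b=ch.b,
                m_gate=ch.m_gate,
                m_tau=ch.m_tau,
                h_gate=ch.h_gate,
                h_tau=ch.h_tau,
                ghk_mode=True,
                ca_permeable=True,
                ca_inactivated=ca_h is not None,
                ghk=ghk,
                ca_h_gate=GateSpec(form="hill", **ca_h) if ca_h else None,
            )
        channels.append(ch)
    pool = _pool(m["calcium_pool"], "model.calcium_pool") if "calcium_pool" in m else None
    return ClampModel(channels=channels, mi_t_mode=mode, pool=pool)


_NEURON_CH_KEYS = {"name", "compartment", "gbar_us_per_mm2", "e_rev_mv", "a",
                   "b", "m_inf", "tau_m", "h_inf", "tau_h", "ghk",
                   "ca_permeable"}


def neuron_model_from_config(
    doc: dict,
    variant: Optional[str] = None,
    g_mi: Optional[float] = None,
    g_mit: Optional[float] = None,
):
    """Build a :class:`~lpmod.neuron.NeuronModel` from a config document.

    ``variant`` selects one of the documented modulator configurations
    (overriding the base conductances and the calcium-permeability flag of
    the transient current); ``g_mi``/``g_mit`` override explicitly.
    """
    from .neuron import CompartmentSpec, NeuronModel, SynapseSpec

    m = doc.get("model", doc)
    if m.get("kind") != "neuron":
        raise ConfigError("not a neuron model config")

    var = None
    if variant is not None:
        variants = m.get("variants", {})
        if variant not in variants:
            raise ConfigError(f"unknown variant {variant!r}")
        var = variants[variant]

    soma_area_um2 = None
    comps = {}
    for cname, cd in m["compartments"].items():
        _check_keys(cd, {"diameter_um", "length_um", "cm_uf_per_cm2"},
                    f"model.compartments.{cname}")
        comps[cname] = dict(cd)
    import math

    soma_area_um2 = math.pi * comps["soma_neurite"]["diameter_um"] * \
        comps["soma_neurite"]["length_um"]

    mit_ca = var["mit_ca_permeable"] if var else True
    channels = {"soma_neurite": [], "axon": []}
    for i, chd in enumerate(m["channels"]):
        path = f"model.channels[{i}]"
        _check_keys(chd, _NEURON_CH_KEYS, path)
        name = chd["name"]
        gbar = chd["gbar_us_per_mm2"]
        if name == "I_MI":
            if var:
                gbar = var["g_mi"]
            if g_mi is not None:
                gbar = g_mi
        if name == "I_MI_T":
            if var:
                gbar = var["g_mit"]
            if g_mit is not None:
                gbar = g_mit
        is_ghk = bool(chd.get("ghk", False))
        ghk = _ghk(m["ghk"], "model.ghk", area_um2=soma_area_um2) if is_ghk else None
        ca_perm = bool(chd.get("ca_permeable", False))
        if name == "I_MI_T":
            ca_perm = mit_ca
        channels[chd.get("compartment", "soma_neurite")].append(
            ChannelSpec(
                name=name,
                gbar=gbar,
                e_rev=chd.get("e_rev_mv", 0.0),
                a=chd.get("a", 1),
                b=chd.get("b", 0),
                m_gate=_gate(chd.get("m_inf"), path + ".m_inf"),
                m_tau=_tau(chd.get("tau_m"), path + ".tau_m"),
                h_gate=_gate(chd.get("h_inf"), path + ".h_inf"),
                h_tau=_tau(chd.get("tau_h"), path + ".tau_h"),
                ghk_mode=is_ghk,
                ca_permeable=ca_perm,
                ghk=ghk,
            )
        )

    soma = CompartmentSpec(
        name="soma_neurite",
        diameter_um=comps["soma_neurite"]["diameter_um"],
        length_um=comps["soma_neurite"]["length_um"],
        cm_uf_per_cm2=comps["soma_neurite"]["cm_uf_per_cm2"],
        channels=channels["soma_neurite"],
    )
    axon = CompartmentSpec(
        name="axon",
        diameter_um=comps["axon"]["diameter_um"],
        length_um=comps["axon"]["length_um"],
        cm_uf_per_cm2=comps["axon"]["cm_uf_per_cm2"],
        channels=channels["axon"],
    )
    syn = m.get("synapse", {})
    _check_keys(syn, {"gmax_us_per_mm2", "e_rev_mv", "duty"}, "model.synapse")
    return NeuronModel(
        soma=soma,
        axon=axon,
        coupling_us=m.get("coupling_us", 0.15),
        pool=_pool(m["calcium_pool"], "model.calcium_pool"),
        variant=variant or "base",
        v_init=m.get("v_init_mv", -55.0),
        synapse_defaults=SynapseSpec(
            gmax=syn.get("gmax_us_per_mm2", 1.0),
            e_rev=syn.get("e_rev_mv", -80.0),
            duty=syn.get("duty", 0.5),
            period=1.0,
        ),
    )


_PROTO_KEYS = {
    "ramp": {"kind", "v_start_mv", "v_peak_mv", "slope_mv_per_s", "n_sweeps",
             "inter_sweep_hold_s", "hold_v_mv", "dt_s"},
    "ramp_hold": {"kind", "v_low_mv", "v_high_mv", "slope_mv_per_s",
                  "n_cycles", "dt_s"},
    "wave": {"kind", "period_s", "v_trough_mv", "v_peak_mv", "n_cycles",
             "dt_s", "asymmetry", "plateau_fraction"},
}


def protocol_from_config(doc: dict):
    """Build a VoltageCommand from a protocol config section."""
    from .stimuli import (
        DEFAULT_DT,
        PeriodicWaveSpec,
        RampHoldSpec,
        RampSpec,
        make_periodic_waveform,
        make_ramp_and_hold,
        make_triangular_ramp,
    )
    from .synth import surrogate_lp_waveform

    p = doc.get("protocol", doc)
    kind = p.get("kind")
    if kind not in _PROTO_KEYS:
        raise ConfigError(f"unknown protocol kind {kind!r}")
    _check_keys(p, _PROTO_KEYS[kind], "protocol")
    dt = p.get("dt_s", DEFAULT_DT)
    if kind == "ramp":
        spec = RampSpec(
            v_start=p.get("v_start_mv", -80.0),
            v_peak=p.get("v_peak_mv", 20.0),
            slope=p["slope_mv_per_s"],
            n_sweeps=p.get("n_sweeps", 5),
            inter_sweep_hold=p.get("inter_sweep_hold_s", 5.0),
            hold_v=p.get("hold_v_mv", p.get("v_start_mv", -80.0)),
        )
        return make_triangular_ramp(spec, dt)
    if kind == "ramp_hold":
        spec = RampHoldSpec(
            v_low=p.get("v_low_mv", -80.0),
            v_high=p.get("v_high_mv", 20.0),
            slope=p["slope_mv_per_s"],
            n_cycles=p.get("n_cycles", 30),
        )
        return make_ramp_and_hold(spec, dt)
    shape = surrogate_lp_waveform(
        asymmetry=p.get("asymmetry", 0.6),
        plateau_fraction=p.get("plateau_fraction", 0.1),
    )
    spec = PeriodicWaveSpec(
        unitary_shape=shape,
        period=p["period_s"],
        v_trough=p.get("v_trough_mv", -60.0),
        v_peak=p.get("v_peak_mv", -20.0),
        n_cycles=p.get("n_cycles", 20),
    )
    return make_periodic_waveform(spec, dt)
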