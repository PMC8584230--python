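"""Shipped acceptance checks (fast subset for the command line).

The full behavioral suite lives in the package's test suite; this module
collects the quick analytic checks the ``lpmod run-acceptance`` command
prints: the inactivation time-constant bound, GHK/Nernst reversal agreement,
exact gate relaxation, and the ramp-slope dependence of the transient
current.
"""

from __future__ import annotations

import numpy as np

from .clamp import iv_points, simulate_clamp
from .config import clamp_model_from_config, load_packaged_config
from .gating import GateSpec, GhkSpec, TauSpec, gate_step, ghk_current, ghk_reversal, tau_eval
from .stimuli import RampSpec, make_triangular_ramp

__all__ = ["tau_h_mit_max", "run_fast_checks"]


def tau_h_mit_max(grid_mv: float = 0.01, v_range=(-80.0, 20.0)) -> float:
    """Maximum of the clamp-model transient-current inactivation time
    constant over the ramp voltage range, in ms (dense-grid evaluation)."""
    doc = load_packaged_config("table2_clamp_model")
    mit = next(c for c in doc["model"]["channels"] if c["name"] == "I_MI_T")
    tau = TauSpec(**mit["tau_h"])
    v = np.arange(v_range[0], v_range[1] + grid_mv / 2, grid_mv)
    return float(np.max(tau_eval(v, tau)))


def run_fast_checks(seed: int = 0):
    """Run the quick checks; returns (name, passed, detail) tuples."""
    results = []

    tmax = tau_h_mit_max()
    results.append((
        "tau_h(MI-T) max <= 800 ms over [-80, 20] mV",
        tmax <= 800.0,
        f"max = {tmax:.1f} ms",
    ))

    ghk = GhkSpec()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(50):
        ci = rng.uniform(1e-4, 1.0)
        vrev = ghk_reversal(ci, ghk)
        i = ghk_current(vrev, 1.0, 1.0, ci, ghk, a=1, b=0)
        di = ghk_current(vrev - 1.0, 1.0, 1.0, ci, ghk, a=1, b=0)
        # invert the local slope to express the residual in mV
        worst = max(worst, abs(i / (i - di)))
    results.append((
        "GHK reversal matches Nernst to < 0.01 mV",
        worst < 0.01,
        f"worst residual = {worst:.2e} mV",
    ))

    gate = GateSpec(form="logistic", v_half=-30.0, k=6.0)
    tau = TauSpec(base=2.0)
    x = gate_step(0.0, -30.0, 2.0, gate, tau)
    expected = 0.5 * (1.0 - np.exp(-1.0))
    err = abs(x - expected)
    results.append((
        "gate update matches closed-form relaxation",
        err < 1e-12,
        f"|error| = {err:.1e}",
    ))

    model = clamp_model_from_config(load_packaged_config("table2_clamp_model"))
    peaks = []
    for slope in (50.0, 100.0, 200.0, 400.0):
        cmd = make_triangular_ramp(RampSpec(slope=slope, n_sweeps=1,
                                            inter_sweep_hold=0.5))
        v, i = iv_points(simulate_clamp(cmd, model), "pos_ramp", 0)
        peaks.append(i.min())
    mono = all(peaks[j] > peaks[j + 1] for j in range(len(peaks) - 1))
    results.append((
        "positive-ramp peak current increases with slope",
        mono,
        "peaks (nA): " + ", ".join(f"{p:.2f}" for p in peaks),
    ))
    return results
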