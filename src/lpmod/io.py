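"""Trace-file reading and writing.

Traces are plain tabular text: '#'-prefixed metadata lines (``key=value``),
then a CSV header and data. The first column is ``time_s`` (strictly
increasing, uniform); remaining columns are named signals (``v_mV``,
``i_nA``, ``g_syn_uS_per_mm2``, ``ca_mM``, ...) plus an optional integer
``sweep`` column. Round-trips are lossless at full float precision.
"""

from __future__ import annotations

import io as _io
import json
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["TraceFileError", "write_trace", "read_trace", "write_manifest"]

_DT_TOL = 1e-9


class TraceFileError(ValueError):
    """A trace file violates the format contract."""


def write_trace(path, df: pd.DataFrame, meta: Optional[dict] = None) -> None:
    """Write a trace DataFrame with metadata comment lines."""
    if "time_s" not in df.columns:
        raise TraceFileError("trace must have a time_s column")
    meta = dict(meta or {})
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        meta.setdefault("dt", repr(float(t[1] - t[0])))
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trace(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a trace file; returns (data, metadata)."""
    meta: dict = {}
    lines = []
    with open(path, "r") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), float_precision="round_trip")
    if "time_s" not in df.columns:
        raise TraceFileError("missing declared column 'time_s'")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise TraceFileError(f"missing value in column {col!r} at row {row}")
    t = df["time_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TraceFileError(f"time_s not strictly increasing at row {int(bad[0]) + 1}")
    if "dt" in meta and len(t) > 1:
        dt = float(meta["dt"])
        if np.max(np.abs(np.diff(t) - dt)) > _DT_TOL:
            raise TraceFileError("time grid does not match declared dt")
    return df, meta


def write_manifest(path, config: dict, seed: Optional[int], extra=None) -> None:
    """Write a reproducibility manifest (config hash, version, seed)."""
    from . import __version__
    from .config import config_hash

    doc = {
        "package": "lpmod",
        "version": __version__,
        "config_sha256_16": config_hash(config),
        "seed": seed,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
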