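"""File formats: trace CSVs with JSON metadata sidecars, fit-result JSON.

A measured trace is a CSV with header exactly ``time_s,stage_um,cantilever_um``
plus a sidecar ``<stem>.json`` carrying at least ``d_um`` and
``k_clv_nN_per_um``. Simulation traces use the extended eight-column header.
Floats are written with full ``repr`` precision so write/read round-trips are
exact. Every structured output embeds the schema version, package version and
a config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import ExperimentTrace, FitResult

TRACE_COLUMNS = ["time_s", "stage_um", "cantilever_um"]
SIM_COLUMNS = [
    "time_s",
    "stage_um",
    "cantilever_um",
    "e_um",
    "force_nN",
    "delta_um",
    "tension_nN",
    "tmaxwell_nN",
]
SCHEMA_VERSION = "1"

__all__ = [
    "TRACE_COLUMNS",
    "SIM_COLUMNS",
    "SCHEMA_VERSION",
    "SchemaError",
    "read_trace",
    "write_trace",
    "write_sim_trace",
    "sidecar_path",
    "fit_result_to_dict",
    "save_fit_result",
    "config_hash",
    "to_jsonable",
]


class SchemaError(ValueError):
    """A file does not match the declared trace/sidecar schema."""


def _write_float_csv(path: Path, columns, data: np.ndarray):
    """CSV with shortest-round-trip float formatting (exact read-back)."""
    np.savetxt(path, data, fmt="%.17g", delimiter=",",
               header=",".join(columns), comments="")


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy objects to JSON-safe values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def config_hash(obj) -> str:
    """Stable sha256 over the canonical JSON encoding of a config object."""
    payload = json.dumps(to_jsonable(obj), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: ExperimentTrace, csv_path, sidecar: Path | None = None) -> Path:
    """Write the measured channels + metadata sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    _write_float_csv(
        csv_path,
        TRACE_COLUMNS,
        np.column_stack([trace.t, trace.delta_s, trace.delta_clv]),
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "d_um": trace.d,
        "k_clv_nN_per_um": trace.k_clv,
        "condition": trace.condition,
        "provenance": to_jsonable(trace.provenance),
        "package_version": __version__,
    }
    (sidecar or sidecar_path(csv_path)).write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trace(csv_path, sidecar: Path | None = None) -> ExperimentTrace:
    """Read and validate a trace CSV + sidecar into an ExperimentTrace."""
    csv_path = Path(csv_path)
    side = sidecar or sidecar_path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not side.exists():
        raise SchemaError(f"missing metadata sidecar {side}")
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # empty / unparseable file
        raise SchemaError(f"{csv_path}: not a parseable CSV ({exc})") from exc
    if list(df.columns) != TRACE_COLUMNS:
        offending = [c for c in df.columns if c not in TRACE_COLUMNS] or list(df.columns)
        raise SchemaError(
            f"{csv_path}: header must be exactly {','.join(TRACE_COLUMNS)}; "
            f"offending columns: {offending}"
        )
    meta = json.loads(side.read_text())
    for key in ("d_um", "k_clv_nN_per_um"):
        if key not in meta:
            raise SchemaError(f"{side}: missing required sidecar field '{key}'")
    d = float(meta["d_um"])
    k_clv = float(meta["k_clv_nN_per_um"])
    if d <= 0:
        raise SchemaError(f"{side}: d_um must be positive, got {d}")
    if k_clv <= 0:
        raise SchemaError(f"{side}: k_clv_nN_per_um must be positive, got {k_clv}")
    return ExperimentTrace(
        t=df["time_s"].to_numpy(),
        delta_s=df["stage_um"].to_numpy(),
        delta_clv=df["cantilever_um"].to_numpy(),
        d=d,
        k_clv=k_clv,
        condition=str(meta.get("condition", "")),
        provenance=meta.get("provenance", {}),
    )


def write_sim_trace(sim, csv_path) -> Path:
    """Write the full eight-column simulator output + sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    _write_float_csv(csv_path, SIM_COLUMNS, sim.to_frame().to_numpy())
    meta = {
        "schema_version": SCHEMA_VERSION,
        "d_um": sim.geometry.d,
        "k_clv_nN_per_um": sim.probe.k_clv,
        "params": to_jsonable(sim.params),
        "protocol": to_jsonable(sim.protocol),
        "solver": to_jsonable(sim.solver),
        "package_version": __version__,
    }
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))
    return csv_path


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def fit_result_to_dict(result: FitResult) -> dict:
    cfg = result.config
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "params": {
            "T0_nN": result.params.T0,
            "k1_nN_per_um": result.params.k1,
            "k2_nN_per_um": result.params.k2,
            "eta_nN_s_per_um": result.params.eta,
        },
        "relaxation": to_jsonable(result.relaxation),
        "pretension": to_jsonable(result.pretension),
        "halt": to_jsonable(result.halt),
        "error": result.error,
        "grid": to_jsonable(result.grid),
        "config": to_jsonable(cfg),
    }


def save_fit_result(result: FitResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(to_jsonable(fit_result_to_dict(result)), indent=1))
    return path
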