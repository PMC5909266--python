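"""Reading and writing scan traces and fitted models.

Scan CSV schema (one row per sample, UTF-8, decimal point)::

    time_s,marker1_ap_mm,marker2_ap_mm,marker3_ap_mm,target_lr_mm,target_si_mm,target_ap_mm

with a sidecar YAML next to it (``<stem>.yaml``) carrying ``scan_id``,
``acquired_at`` (ISO-8601 or null) and ``dt_s``.  Models serialize to
YAML with a ``kind`` tag.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DIRECTIONS,
    MARKER_IDS,
    InvalidInputError,
    Scan,
    SurrogateTrace,
    TargetTrace,
)
from .model import PhaseLinearModel, QuadraticModel, fit_phase_linear

__all__ = ["SCAN_COLUMNS", "read_scan", "write_scan", "save_model", "load_model"]

SCAN_COLUMNS = [
    "time_s",
    "marker1_ap_mm",
    "marker2_ap_mm",
    "marker3_ap_mm",
    "target_lr_mm",
    "target_si_mm",
    "target_ap_mm",
]

DT_TOLERANCE_S = 1e-6


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_scan(scan: Scan, path) -> Path:
    """Write a scan CSV (6 decimal places) plus its metadata sidecar."""
    path = Path(path)
    n = scan.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) * scan.dt,
            "marker1_ap_mm": scan.surrogate(1).positions,
            "marker2_ap_mm": scan.surrogate(2).positions,
            "marker3_ap_mm": scan.surrogate(3).positions,
            "target_lr_mm": scan.target.positions[:, 0],
            "target_si_mm": scan.target.positions[:, 1],
            "target_ap_mm": scan.target.positions[:, 2],
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "scan_id": scan.scan_id,
        "acquired_at": scan.acquired_at.isoformat() if scan.acquired_at else None,
        "dt_s": float(scan.dt),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_scan(path, metadata_path=None) -> Scan:
    """Read a scan CSV, validating schema, finiteness and uniform sampling."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path.name}: missing columns {missing}")
    if len(df) < 2:
        raise InvalidInputError(f"{path.name}: need at least 2 samples")
    for col in SCAN_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise InvalidInputError(
                f"{path.name}: non-finite value in column '{col}' at data row {bad[0]}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    if np.any(np.abs(steps - steps[0]) > DT_TOLERANCE_S):
        row = int(np.argmax(np.abs(steps - steps[0]) > DT_TOLERANCE_S)) + 1
        raise InvalidInputError(f"{path.name}: non-uniform time step at data row {row}")

    meta_path = Path(metadata_path) if metadata_path else _sidecar(path)
    meta = {}
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
    dt = float(meta.get("dt_s", steps[0]))
    if abs(dt - steps[0]) > DT_TOLERANCE_S:
        raise InvalidInputError(
            f"{path.name}: metadata dt_s={dt} disagrees with time column step {steps[0]}"
        )
    acquired_at = meta.get("acquired_at")
    acquired = datetime.fromisoformat(acquired_at) if acquired_at else None
    scan_id = str(meta.get("scan_id", path.stem))
    surrogates = tuple(
        SurrogateTrace(m, df[f"marker{m}_ap_mm"].to_numpy(dtype=float), dt)
        for m in MARKER_IDS
    )
    target = TargetTrace(
        np.column_stack(
            [df["target_lr_mm"], df["target_si_mm"], df["target_ap_mm"]]
        ).astype(float),
        dt,
    )
    return Scan(scan_id, surrogates, target, acquired)


def save_model(model: QuadraticModel | PhaseLinearModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, QuadraticModel):
        doc = {
            "kind": "quadratic",
            "t_m_s": float(model.t_m),
            "source_scan_id": model.source_scan_id,
            "coefficients": {
                f"marker{m}": {
                    d.value: [float(x) for x in model.coeffs[i, g]]
                    for g, d in enumerate(DIRECTIONS)
                }
                for i, m in enumerate(MARKER_IDS)
            },
        }
    elif isinstance(model, PhaseLinearModel):
        doc = {
            "kind": "phase_linear",
            "source_scan_id": model.source_scan_id,
            "w_ave_mm": [float(x) for x in model.w_ave],
            "p_phase_mm": [[float(x) for x in row] for row in model.p_phase],
            "slopes": [[float(x) for x in row] for row in model.slopes],
            "intercepts_mm": [[float(x) for x in row] for row in model.intercepts],
        }
    else:
        raise InvalidInputError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_model(path) -> QuadraticModel | PhaseLinearModel:
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "quadratic":
        coeffs = np.array(
            [
                [doc["coefficients"][f"marker{m}"][d.value] for d in DIRECTIONS]
                for m in MARKER_IDS
            ],
            dtype=float,
        )
        return QuadraticModel(
            coeffs=coeffs, t_m=float(doc["t_m_s"]), source_scan_id=doc.get("source_scan_id", "")
        )
    if kind == "phase_linear":
        return fit_phase_linear(
            np.asarray(doc["w_ave_mm"], dtype=float),
            np.asarray(doc["p_phase_mm"], dtype=float),
            source_scan_id=doc.get("source_scan_id", ""),
        )
    raise InvalidInputError(f"unknown model kind {kind!r} in {path}")
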