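"""RMSE metrics and intra-/inter-scan validation workflows.

The validation unit is one scan split into modeling and validating
halves.  *Intra-scan*: train and validate on the same scan.  *Inter-scan*:
train on scan A, validate on scan B's second half, optionally after
baseline-drift correction.  A grid sweep runs all ordered pairs of a
cohort over the modeling-period (T_M) x correction-period (T_C) grid and
summarises the 3D RMSE distribution per cell with Tukey boxplot
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InvalidInputError, Scan, split_sessions
from .drift import apply_corrected, compute_correction
from .model import (
    QuadraticModel,
    average_over_markers,
    fit_phase_linear,
    fit_quadratic_model,
    predict_phase_linear,
    predict_quadratic,
)

__all__ = [
    "rmse",
    "rmse_per_direction",
    "rmse_3d",
    "RmseReport",
    "BoxSummary",
    "box_summary",
    "intra_scan",
    "inter_scan",
    "grid_sweep",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("quadratic", "phase_linear")
PHASE_LINEAR_LABEL = "4D-CBCT"


def rmse(estimated: np.ndarray, actual: np.ndarray) -> float:
    """Root-mean-square error of two equal-length 1-D traces (mm)."""
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    if est.shape != act.shape or est.size < 1:
        raise InvalidInputError("traces must be non-empty and equal-length")
    return float(np.sqrt(np.mean((est - act) ** 2)))


def rmse_per_direction(estimated: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-direction RMSEs for (n, 3) estimated/actual arrays."""
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    if est.shape != act.shape or est.ndim != 2 or est.shape[1] != 3:
        raise InvalidInputError("arrays must be equal-shape (n, 3)")
    return np.sqrt(np.mean((est - act) ** 2, axis=0))


def rmse_3d(estimated: np.ndarray, actual: np.ndarray) -> float:
    """RMS of the per-sample 3D Euclidean error.

    Algebraically identical to sqrt(sum over directions of rmse_γ²).
    """
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    if est.shape != act.shape or est.ndim != 2 or est.shape[1] != 3:
        raise InvalidInputError("arrays must be equal-shape (n, 3)")
    return float(np.sqrt(np.mean(np.sum((est - act) ** 2, axis=1))))


@dataclass(frozen=True)
class RmseReport:
    """Per-direction and 3D RMSE of one estimation run."""

    rmse: np.ndarray  # (3,) LR, SI, AP in mm
    rmse_3d: float
    scenario: str  # "intra" | "inter"
    model_kind: str
    t_m: float | None  # None for the phase-linear comparator
    t_c: float | None
    corrected: bool
    anchor: str | None
    scan_a_id: str
    scan_b_id: str
    elapsed_min: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rmse, dtype=float)
        object.__setattr__(self, "rmse", r)
        if r.shape != (3,):
            raise InvalidInputError("per-direction rmse must hold 3 values")
        total = float(np.sqrt(np.sum(r**2)))
        if not np.isclose(self.rmse_3d, total, rtol=1e-9, atol=1e-12):
            raise InvalidInputError(
                f"rmse_3d {self.rmse_3d} violates the decomposition identity ({total})"
            )

    @property
    def t_m_label(self) -> str:
        return PHASE_LINEAR_LABEL if self.t_m is None else f"{self.t_m:g} s"

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "model_kind": self.model_kind,
            "t_m_s": np.nan if self.t_m is None else float(self.t_m),
            "t_c_s": np.nan if self.t_c is None else float(self.t_c),
            "corrected": self.corrected,
            "anchor": self.anchor if self.anchor else "",
            "scan_a": self.scan_a_id,
            "scan_b": self.scan_b_id,
            "rmse_lr_mm": float(self.rmse[0]),
            "rmse_si_mm": float(self.rmse[1]),
            "rmse_ap_mm": float(self.rmse[2]),
            "rmse_3d_mm": float(self.rmse_3d),
            "elapsed_min": np.nan if self.elapsed_min is None else float(self.elapsed_min),
        }


def _report(est, act, **meta) -> RmseReport:
    per_dir = rmse_per_direction(est, act)
    return RmseReport(rmse=per_dir, rmse_3d=rmse_3d(est, act), **meta)


def _fit(scan: Scan, model_kind: str, t_m: float | None, invert_breathing_sign: bool):
    if model_kind == "quadratic":
        if t_m is None:
            raise InvalidInputError("the quadratic model needs a modeling period T_M")
        return fit_quadratic_model(scan, t_m)
    if model_kind == "phase_linear":
        from .simulate import simulate_phase_averages

        w_ave, p_phase = simulate_phase_averages(scan)
        return fit_phase_linear(w_ave, p_phase, source_scan_id=scan.scan_id)
    raise InvalidInputError(f"model_kind must be one of {MODEL_KINDS}")


def _predict(model, scan: Scan, indices: np.ndarray, invert_breathing_sign: bool):
    if isinstance(model, QuadraticModel):
        return average_over_markers(predict_quadratic(model, scan.surrogates, indices))
    w_mean = scan.mean_surrogate()
    w = w_mean[indices]
    v = (w_mean[indices] - w_mean[indices - 1]) / scan.dt
    return predict_phase_linear(model, w, v, invert_breathing_sign=invert_breathing_sign)


def intra_scan(
    scan: Scan,
    model_kind: str = "quadratic",
    t_m: float | None = 10.0,
    *,
    invert_breathing_sign: bool = False,
) -> RmseReport:
    """Train on the modeling half, validate on the validating half.

    A ``t_m`` spanning the whole scan (the 70-s comparator) deliberately
    trains on the validating session too, mirroring how that comparator
    is defined.
    """
    split = split_sessions(scan)
    val_idx = np.arange(split.validating.start, split.validating.stop)
    if model_kind == "phase_linear":
        t_m = None
    model = _fit(scan, model_kind, t_m, invert_breathing_sign)
    est = _predict(model, scan, val_idx, invert_breathing_sign)
    act = scan.target.positions[val_idx]
    return _report(
        est,
        act,
        scenario="intra",
        model_kind=model_kind,
        t_m=t_m,
        t_c=None,
        corrected=False,
        anchor=None,
        scan_a_id=scan.scan_id,
        scan_b_id=scan.scan_id,
        elapsed_min=0.0,
    )


def _elapsed_minutes(scan_a: Scan, scan_b: Scan) -> float | None:
    if scan_a.acquired_at is None or scan_b.acquired_at is None:
        return None
    return abs((scan_b.acquired_at - scan_a.acquired_at).total_seconds()) / 60.0


def inter_scan(
    scan_a: Scan,
    scan_b: Scan,
    model_kind: str = "quadratic",
    t_m: float | None = 10.0,
    t_c: float | None = None,
    corrected: bool = False,
    anchor: str = "scan_a",
    *,
    per_marker_target_drift: bool = False,
    invert_breathing_sign: bool = False,
) -> RmseReport:
    """Train on scan A's modeling half, validate on scan B's second half.

    With ``corrected`` the surrogate and target baselines are drift-
    corrected using windows of length ``t_c`` (required, and ``t_c <= t_m``
    for the quadratic model).
    """
    if corrected and t_c is None:
        raise InvalidInputError("corrected estimation requires a correction period T_C")
    if model_kind == "phase_linear":
        t_m = None
    model = _fit(scan_a, model_kind, t_m, invert_breathing_sign)
    split_b = split_sessions(scan_b)
    val_idx = np.arange(split_b.validating.start, split_b.validating.stop)
    if corrected:
        correction = compute_correction(
            model,
            scan_a,
            scan_b,
            t_c,
            anchor,
            per_marker_target_drift=per_marker_target_drift,
            invert_breathing_sign=invert_breathing_sign,
        )
        est = apply_corrected(
            model, scan_b, correction, val_idx, invert_breathing_sign=invert_breathing_sign
        )
    else:
        est = _predict(model, scan_b, val_idx, invert_breathing_sign)
    act = scan_b.target.positions[val_idx]
    return _report(
        est,
        act,
        scenario="inter",
        model_kind=model_kind,
        t_m=t_m,
        t_c=t_c if corrected else None,
        corrected=corrected,
        anchor=anchor if corrected else None,
        scan_a_id=scan_a.scan_id,
        scan_b_id=scan_b.scan_id,
        elapsed_min=_elapsed_minutes(scan_a, scan_b),
    )


@dataclass(frozen=True)
class BoxSummary:
    """Tukey boxplot statistics of one grid cell."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def box_summary(values) -> BoxSummary:
    """Median, quartiles (linear interpolation), 1.5*IQR whiskers, outliers."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidInputError("box_summary needs at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(x[(x < lo_fence) | (x > hi_fence)]))
    return BoxSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(x.size),
    )


def grid_sweep(
    pairs,
    t_m_set=(5.0, 10.0, 15.0, 25.0, 35.0),
    t_c_set=(5.0, 10.0, 15.0),
    model_kinds=("quadratic",),
    anchor: str = "scan_a",
    *,
    per_marker_target_drift: bool = False,
    invert_breathing_sign: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Evaluate every ordered pair over the full (T_M, T_C, corrected) grid.

    Each unordered pair is used in both directions (A->B and B->A).
    Infeasible cells (T_C > T_M) are skipped; failing cells (degenerate
    fits on pathological scans) are logged and counted, not fatal.
    Returns ``(long_results, cell_summary, n_failures)``.
    """
    pairs = list(pairs)
    if not pairs or not list(t_m_set) or not list(model_kinds):
        raise InvalidInputError("pairs, t_m_set and model_kinds must be non-empty")
    rows: list[dict] = []
    n_failures = 0

    def run(scan_a, scan_b, kind, t_m, t_c, corrected):
        nonlocal n_failures
        try:
            report = inter_scan(
                scan_a,
                scan_b,
                model_kind=kind,
                t_m=t_m,
                t_c=t_c,
                corrected=corrected,
                anchor=anchor,
                per_marker_target_drift=per_marker_target_drift,
                invert_breathing_sign=invert_breathing_sign,
            )
            rows.append(report.to_row())
        except Exception as exc:  # noqa: BLE001 - per-cell robustness is the contract
            n_failures += 1
            logger.warning(
                "grid cell failed (%s->%s kind=%s T_M=%s T_C=%s corrected=%s): %s",
                scan_a.scan_id, scan_b.scan_id, kind, t_m, t_c, corrected, exc,
            )

    for scan_a, scan_b in pairs:
        for src, dst in ((scan_a, scan_b), (scan_b, scan_a)):
            for kind in model_kinds:
                t_ms = [None] if kind == "phase_linear" else list(t_m_set)
                for t_m in t_ms:
                    run(src, dst, kind, t_m, None, corrected=False)
                    for t_c in t_c_set:
                        if t_m is not None and t_c > t_m:
                            continue  # infeasible cell, skipped by the grid constraint
                        run(src, dst, kind, t_m, t_c, corrected=True)

    long_df = pd.DataFrame(rows)
    summaries = []
    if not long_df.empty:
        grouped = long_df.groupby(
            ["model_kind", "t_m_s", "t_c_s", "corrected"], dropna=False
        )
        for (kind, t_m, t_c, corrected), sub in grouped:
            box = box_summary(sub["rmse_3d_mm"].to_numpy())
            summaries.append(
                {
                    "model_kind": kind,
                    "t_m_s": t_m,
                    "t_c_s": t_c,
                    "corrected": corrected,
                    "median_mm": box.median,
                    "q25_mm": box.q25,
                    "q75_mm": box.q75,
                    "whisker_low_mm": box.whisker_low,
                    "whisker_high_mm": box.whisker_high,
                    "outlier_count": len(box.outliers),
                    "n": box.n,
                }
            )
    summary_df = pd.DataFrame(summaries)
    return long_df, summary_df, n_failures


def export_boxplot(long_df: pd.DataFrame, path, corrected: bool | None = None) -> None:
    """Basic boxplot of 3D RMSE per (T_M, T_C) cell (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = long_df
    if corrected is not None:
        df = df[df["corrected"] == corrected]
    labels, groups = [], []
    for (t_m, t_c, corr), sub in df.groupby(["t_m_s", "t_c_s", "corrected"], dropna=False):
        tm = "4D-CBCT" if pd.isna(t_m) else f"{t_m:g}"
        tc = "-" if pd.isna(t_c) else f"{t_c:g}"
        labels.append(f"TM={tm}\nTC={tc}\n{'cor' if corr else 'unc'}")
        groups.append(sub["rmse_3d_mm"].to_numpy())
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(groups)), 4))
    ax.boxplot(groups, tick_labels=labels, whis=1.5)
    ax.set_ylabel("3D RMSE (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
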