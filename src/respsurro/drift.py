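"""Inter-scan baseline-drift correction.

Between two scans minutes apart, the resting positions of both the
abdominal surrogate and the internal target drift.  The correction
estimates each baseline as the *median* position over a correction window
of length ``T_C`` at the end of the modeling session (immediately prior
to the validating session), then

1. shifts scan B's surrogate by the surrogate baseline difference
   ``BD_IR`` before evaluating the model, and
2. subtracts from the resulting estimates a per-direction target offset
   ``BD_Target`` — the median of the shifted-surrogate estimates over
   scan B's window minus an anchor term.

Anchor conventions: ``scan_a`` uses the median of scan A's *actual*
target over scan A's window (referencing the training scan); ``scan_b`` uses
the median of scan B's actual target over scan B's window, which is the
variant that removes a genuine target baseline shift.  For the
phase-linear comparator the anchor term is always the centroid of scan
A's eight phase-averaged target positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MARKER_IDS,
    InvalidInputError,
    Scan,
    SurrogateTrace,
    split_sessions,
    tail_window,
)
from .model import (
    PhaseLinearModel,
    QuadraticModel,
    average_over_markers,
    predict_phase_linear,
    predict_quadratic,
)

__all__ = [
    "DriftCorrection",
    "correction_window",
    "surrogate_drift",
    "correct_surrogate",
    "target_drift",
    "compute_correction",
    "apply_corrected",
]

ANCHORS = ("scan_a", "scan_b")


def correction_window(scan: Scan, t_c: float) -> np.ndarray:
    """Last ``T_C/dt`` modeling-session indices of ``scan``."""
    return tail_window(split_sessions(scan), t_c, scan.dt)


def surrogate_drift(scan_a: Scan, scan_b: Scan, marker_id: int, t_c: float) -> float:
    """BD_IR: scan B's surrogate baseline minus scan A's, in mm.

    Baselines are window medians; even-length windows use the mean of the
    two central order statistics.
    """
    wa = correction_window(scan_a, t_c)
    wb = correction_window(scan_b, t_c)
    med_b = float(np.median(scan_b.surrogate(marker_id).positions[wb]))
    med_a = float(np.median(scan_a.surrogate(marker_id).positions[wa]))
    return med_b - med_a


def correct_surrogate(trace: SurrogateTrace, bd_ir: float) -> SurrogateTrace:
    """Shift every surrogate sample by −bd_ir (velocities unchanged)."""
    return trace.shifted(-bd_ir)


@dataclass(frozen=True)
class DriftCorrection:
    """Computed offsets for one (model, scan A -> scan B, T_C) combination."""

    bd_ir: np.ndarray  # (3,) per marker, mm
    bd_target: np.ndarray  # (3,) per direction, mm
    t_c: float
    anchor: str
    model_kind: str  # "quadratic" | "phase_linear"
    t_m: float | None
    scan_a_id: str
    scan_b_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bd_ir", np.asarray(self.bd_ir, dtype=float))
        object.__setattr__(self, "bd_target", np.asarray(self.bd_target, dtype=float))
        if self.bd_ir.shape != (3,) or self.bd_target.shape != (3,):
            raise InvalidInputError("bd_ir and bd_target must each hold 3 values")
        if self.anchor not in ANCHORS:
            raise InvalidInputError(f"anchor must be one of {ANCHORS}")

    def to_dict(self) -> dict:
        return {
            "bd_ir_mm": {f"marker{m}": float(v) for m, v in zip(MARKER_IDS, self.bd_ir)},
            "bd_target_mm": {
                d: float(v) for d, v in zip(("LR", "SI", "AP"), self.bd_target)
            },
            "t_c_s": float(self.t_c),
            "anchor": self.anchor,
            "model_kind": self.model_kind,
            "t_m_s": None if self.t_m is None else float(self.t_m),
            "scan_a_id": self.scan_a_id,
            "scan_b_id": self.scan_b_id,
        }


def _corrected_traces(scan_b: Scan, bd_ir: np.ndarray) -> tuple[SurrogateTrace, ...]:
    return tuple(
        correct_surrogate(scan_b.surrogate(m), bd_ir[i]) for i, m in enumerate(MARKER_IDS)
    )


def _per_marker_estimates(
    model: QuadraticModel | PhaseLinearModel,
    surrogates: tuple[SurrogateTrace, ...],
    indices: np.ndarray,
    *,
    invert_breathing_sign: bool = False,
) -> np.ndarray:
    """Per-marker estimates, (3, n, 3).

    The phase-linear model is a single marker-averaged model; it is
    evaluated on the marker-averaged surrogate and the result replicated
    so the downstream marker averaging is a no-op.
    """
    indices = np.asarray(indices, dtype=int)
    if isinstance(model, QuadraticModel):
        return predict_quadratic(model, surrogates, indices)
    w_mean = np.mean([s.positions for s in surrogates], axis=0)
    dt = surrogates[0].dt
    if indices.min() < 1:
        raise InvalidInputError("velocity needs a predecessor; index 0 not allowed")
    w = w_mean[indices]
    v = (w_mean[indices] - w_mean[indices - 1]) / dt
    est = predict_phase_linear(model, w, v, invert_breathing_sign=invert_breathing_sign)
    return np.broadcast_to(est, (3,) + est.shape).copy()


def target_drift(
    model: QuadraticModel | PhaseLinearModel,
    scan_a: Scan,
    scan_b: Scan,
    t_c: float,
    anchor: str = "scan_a",
    *,
    per_marker_target_drift: bool = False,
    invert_breathing_sign: bool = False,
) -> np.ndarray:
    """BD_Target per direction (mm) for a model trained on scan A.

    First term: median, over scan B's correction window, of the model
    evaluated on scan B's *surrogate-corrected* traces (marker-averaged;
    with ``per_marker_target_drift`` the per-marker medians are averaged
    instead).  Second term: the anchor baseline (see module docstring).
    """
    if anchor not in ANCHORS:
        raise InvalidInputError(f"anchor must be one of {ANCHORS}")
    wb = correction_window(scan_b, t_c)
    bd_ir = np.array(
        [surrogate_drift(scan_a, scan_b, m, t_c) for m in MARKER_IDS]
    )
    per_marker = _per_marker_estimates(
        model,
        _corrected_traces(scan_b, bd_ir),
        wb,
        invert_breathing_sign=invert_breathing_sign,
    )
    if per_marker_target_drift:
        first = np.median(per_marker, axis=1).mean(axis=0)
    else:
        first = np.median(average_over_markers(per_marker), axis=0)

    if isinstance(model, PhaseLinearModel):
        second = model.centroid
    elif anchor == "scan_a":
        wa = correction_window(scan_a, t_c)
        second = np.median(scan_a.target.positions[wa], axis=0)
    else:
        second = np.median(scan_b.target.positions[wb], axis=0)
    return first - second


def compute_correction(
    model: QuadraticModel | PhaseLinearModel,
    scan_a: Scan,
    scan_b: Scan,
    t_c: float,
    anchor: str = "scan_a",
    *,
    per_marker_target_drift: bool = False,
    invert_breathing_sign: bool = False,
) -> DriftCorrection:
    """Assemble the full drift correction (BD_IR per marker + BD_Target)."""
    if isinstance(model, QuadraticModel) and t_c > model.t_m + 1e-12:
        raise InvalidInputError(
            f"correction period T_C={t_c} s exceeds modeling period T_M={model.t_m} s"
        )
    bd_ir = np.array([surrogate_drift(scan_a, scan_b, m, t_c) for m in MARKER_IDS])
    bd_target = target_drift(
        model,
        scan_a,
        scan_b,
        t_c,
        anchor,
        per_marker_target_drift=per_marker_target_drift,
        invert_breathing_sign=invert_breathing_sign,
    )
    return DriftCorrection(
        bd_ir=bd_ir,
        bd_target=bd_target,
        t_c=t_c,
        anchor=anchor,
        model_kind="quadratic" if isinstance(model, QuadraticModel) else "phase_linear",
        t_m=model.t_m if isinstance(model, QuadraticModel) else None,
        scan_a_id=scan_a.scan_id,
        scan_b_id=scan_b.scan_id,
    )


def apply_corrected(
    model: QuadraticModel | PhaseLinearModel,
    scan_b: Scan,
    correction: DriftCorrection,
    indices: np.ndarray,
    *,
    invert_breathing_sign: bool = False,
) -> np.ndarray:
    """Drift-corrected marker-averaged estimates at ``indices`` -> (n, 3)."""
    kind = "quadratic" if isinstance(model, QuadraticModel) else "phase_linear"
    if correction.model_kind != kind:
        raise InvalidInputError("correction was computed for a different model kind")
    if isinstance(model, QuadraticModel) and correction.t_m != model.t_m:
        raise InvalidInputError("correction was computed for a different T_M")
    if correction.scan_b_id != scan_b.scan_id:
        raise InvalidInputError("correction was computed for a different scan B")
    per_marker = _per_marker_estimates(
        model,
        _corrected_traces(scan_b, correction.bd_ir),
        indices,
        invert_breathing_sign=invert_breathing_sign,
    )
    return average_over_markers(per_marker) - correction.bd_target
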