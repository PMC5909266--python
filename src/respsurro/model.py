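"""Surrogate-to-target estimation models.

Two model families are implemented:

* the quadratic position+velocity model — per IR marker ``i`` and
  direction ``γ``::

      P(t_k) = a w² + b w + c + d v² + e v,   v = Δw/Δt,

  fitted by unweighted least squares over a training window of length
  ``T_M`` at the end of the modeling session, with the final estimate
  being the unweighted mean over the three markers; and

* a piecewise-linear comparator built from eight phase-averaged surrogate
  and target positions (the kind of data a respiration-sorted cone-beam
  CT provides), with one line per adjacent phase pair and the breathing
  limb selected by the sign of the surrogate velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DIRECTIONS,
    MARKER_IDS,
    ConditioningWarning,
    DegenerateBranchError,
    DegenerateFitError,
    Direction,
    InvalidInputError,
    Scan,
    SurrogateTrace,
    split_sessions,
    tail_window,
)

__all__ = [
    "FEATURE_NAMES",
    "feature_vector",
    "design_matrix",
    "fit_quadratic",
    "fit_quadratic_model",
    "QuadraticModel",
    "predict_quadratic",
    "average_over_markers",
    "PhaseLinearModel",
    "fit_phase_linear",
    "predict_phase_linear",
    "N_PHASES",
]

FEATURE_NAMES = ("w2", "w", "1", "v2", "v")
N_COEFFS = 5
N_PHASES = 8

#: branches walked during inhalation (end-exhalation 0 -> end-inhalation 4)
INHALATION_BRANCHES = (0, 1, 2, 3)
#: branches walked during exhalation (end-inhalation 4 -> end-exhalation 0)
EXHALATION_BRANCHES = (4, 5, 6, 7)

COND_WARN_THRESHOLD = 1e8


def feature_vector(w_k: float, w_km1: float, dt: float) -> np.ndarray:
    """Feature vector W(t_k) = (w², w, 1, v², v) with v = (w_k − w_{k−1})/dt."""
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    v = (w_k - w_km1) / dt
    return np.array([w_k * w_k, w_k, 1.0, v * v, v], dtype=float)


def design_matrix(positions: np.ndarray, dt: float, indices: np.ndarray) -> np.ndarray:
    """Stack feature vectors for ``indices`` (each must have a predecessor)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise InvalidInputError("empty index set")
    if indices.min() < 1:
        raise InvalidInputError("velocity needs a predecessor; index 0 not allowed")
    w = positions[indices]
    v = (positions[indices] - positions[indices - 1]) / dt
    return np.column_stack([w * w, w, np.ones_like(w), v * v, v])


def _training_indices(scan: Scan, t_m: float) -> np.ndarray:
    """Training rows for a modeling period ``t_m``.

    ``t_m`` covering the whole scan (the 70-s comparator) trains on every
    sample, validating session included.  Index 0 is always dropped: the
    backward velocity difference is undefined there.
    """
    n_full = int(round(scan.duration / scan.dt))
    if int(round(t_m / scan.dt)) >= n_full:
        return np.arange(1, scan.n_samples)
    split = split_sessions(scan)
    idx = tail_window(split, t_m, scan.dt, need_predecessor=False)
    return idx[idx >= 1]


def fit_quadratic(
    scan: Scan,
    marker_id: int,
    direction: Direction,
    t_m: float,
    *,
    cond_warn: float = COND_WARN_THRESHOLD,
) -> np.ndarray:
    """Least-squares coefficients (a, b, c, d, e) for one marker/direction.

    The minimum-norm solution is returned (SVD-based); a
    :class:`ConditioningWarning` is emitted when the design matrix
    condition number exceeds ``cond_warn``, and a
    :class:`DegenerateFitError` is raised when the numerical rank is
    below 2 (e.g. a constant surrogate).
    """
    indices = _training_indices(scan, t_m)
    X = design_matrix(scan.surrogate(marker_id).positions, scan.dt, indices)
    y = scan.target.component(direction)[indices]
    coeffs, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise DegenerateFitError(
            f"design matrix rank {rank} < 2 for marker {marker_id}, {direction}"
        )
    cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
    if cond > cond_warn:
        warnings.warn(
            f"design matrix condition number {cond:.3g} exceeds {cond_warn:.1g}",
            ConditioningWarning,
            stacklevel=2,
        )
    return coeffs


@dataclass(frozen=True)
class QuadraticModel:
    """Fitted coefficients for all 3 markers x 3 directions.

    ``coeffs[i, g]`` holds (a, b, c, d, e) for marker ``MARKER_IDS[i]``
    and direction ``DIRECTIONS[g]``.
    """

    coeffs: np.ndarray  # (3, 3, 5)
    t_m: float
    source_scan_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (3, 3, N_COEFFS) or not np.all(np.isfinite(c)):
            raise InvalidInputError("coeffs must be a finite (3, 3, 5) array")
        object.__setattr__(self, "coeffs", c)

    def coefficients(self, marker_id: int, direction: Direction) -> np.ndarray:
        i = MARKER_IDS.index(marker_id)
        g = DIRECTIONS.index(Direction(direction))
        return self.coeffs[i, g]


def fit_quadratic_model(scan: Scan, t_m: float, **kwargs) -> QuadraticModel:
    """Fit all nine coefficient sets of the quadratic model on one scan."""
    coeffs = np.empty((3, 3, N_COEFFS))
    for i, marker_id in enumerate(MARKER_IDS):
        for g, direction in enumerate(DIRECTIONS):
            coeffs[i, g] = fit_quadratic(scan, marker_id, direction, t_m, **kwargs)
    return QuadraticModel(coeffs=coeffs, t_m=t_m, source_scan_id=scan.scan_id)


def predict_quadratic(
    model: QuadraticModel,
    surrogates: tuple[SurrogateTrace, SurrogateTrace, SurrogateTrace],
    indices: np.ndarray,
) -> np.ndarray:
    """Per-marker 3D estimates, shape (3 markers, len(indices), 3 directions)."""
    surrogates = tuple(sorted(surrogates, key=lambda s: s.marker_id))
    if tuple(s.marker_id for s in surrogates) != MARKER_IDS:
        raise InvalidInputError("need surrogate traces for markers {1, 2, 3}")
    indices = np.asarray(indices, dtype=int)
    out = np.empty((3, indices.size, 3))
    for i, trace in enumerate(surrogates):
        X = design_matrix(trace.positions, trace.dt, indices)
        out[i] = X @ model.coeffs[i].T
    return out


def average_over_markers(per_marker: np.ndarray) -> np.ndarray:
    """Unweighted mean of the three per-marker estimates -> (n, 3)."""
    per_marker = np.asarray(per_marker, dtype=float)
    if per_marker.shape[0] != 3:
        raise InvalidInputError("expected estimates from exactly 3 markers")
    return per_marker.mean(axis=0)


@dataclass(frozen=True)
class PhaseLinearModel:
    """Piecewise-linear model from 8 phase-averaged positions.

    Phase 0 is end-exhalation, phase 4 end-inhalation.  Branch ``α`` joins
    phases ``α`` and ``(α+1) % 8`` with per-direction slope/intercept;
    ``centroid`` (mean of the 8 target positions per direction) serves as
    the model's target baseline for inter-scan drift correction.
    """

    w_ave: np.ndarray  # (8,)
    p_phase: np.ndarray  # (8, 3)
    slopes: np.ndarray  # (8, 3)
    intercepts: np.ndarray  # (8, 3)
    source_scan_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.w_ave, dtype=float)
        p = np.asarray(self.p_phase, dtype=float)
        s = np.asarray(self.slopes, dtype=float)
        b = np.asarray(self.intercepts, dtype=float)
        if w.shape != (N_PHASES,) or p.shape != (N_PHASES, 3):
            raise InvalidInputError("phase model needs 8 phases (w_ave 8, p_phase 8x3)")
        if s.shape != (N_PHASES, 3) or b.shape != (N_PHASES, 3):
            raise InvalidInputError("phase model needs 8 branches of slopes/intercepts")
        for arr, name in ((w, "w_ave"), (p, "p_phase"), (s, "slopes"), (b, "intercepts")):
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
        object.__setattr__(self, "w_ave", w)
        object.__setattr__(self, "p_phase", p)
        object.__setattr__(self, "slopes", s)
        object.__setattr__(self, "intercepts", b)

    @property
    def centroid(self) -> np.ndarray:
        return self.p_phase.mean(axis=0)


def fit_phase_linear(
    w_ave: np.ndarray, p_phase: np.ndarray, source_scan_id: str = ""
) -> PhaseLinearModel:
    """Build the branch lines joining each adjacent phase pair."""
    w = np.asarray(w_ave, dtype=float)
    p = np.asarray(p_phase, dtype=float)
    if w.shape != (N_PHASES,) or p.shape != (N_PHASES, 3):
        raise InvalidInputError("need 8 phase-averaged surrogate and 8x3 target positions")
    slopes = np.empty((N_PHASES, 3))
    intercepts = np.empty((N_PHASES, 3))
    for alpha in range(N_PHASES):
        beta = (alpha + 1) % N_PHASES
        dw = w[beta] - w[alpha]
        if dw == 0.0:
            raise DegenerateBranchError(
                f"phase averages {alpha} and {beta} coincide (w_ave = {w[alpha]})"
            )
        slopes[alpha] = (p[beta] - p[alpha]) / dw
        intercepts[alpha] = p[alpha] - slopes[alpha] * w[alpha]
    return PhaseLinearModel(w, p, slopes, intercepts, source_scan_id)


def _select_branch(model: PhaseLinearModel, w: float, limb: tuple[int, ...]) -> int:
    """Branch of ``limb`` whose w_ave interval contains ``w``; else nearest.

    Membership uses [min, max] of the two endpoint phase averages (the
    descending limb reverses their order); out-of-range surrogate
    positions clamp to the nearest branch of the limb and extrapolate
    its line.
    """
    best, best_dist = limb[0], np.inf
    for alpha in limb:
        beta = (alpha + 1) % N_PHASES
        lo = min(model.w_ave[alpha], model.w_ave[beta])
        hi = max(model.w_ave[alpha], model.w_ave[beta])
        if lo <= w <= hi:
            return alpha
        dist = lo - w if w < lo else w - hi
        if dist < best_dist:
            best, best_dist = alpha, dist
    return best


def predict_phase_linear(
    model: PhaseLinearModel,
    w: np.ndarray,
    v: np.ndarray,
    *,
    invert_breathing_sign: bool = False,
) -> np.ndarray:
    """Evaluate the phase-linear model at surrogate positions/velocities.

    The default limb convention maps positive surrogate velocity to
    mid-exhalation (branches 4..7) and negative to mid-inhalation
    (branches 0..3); zero velocity falls on the exhalation limb.  Whether
    that matches a given setup depends on the AP axis orientation, hence
    ``invert_breathing_sign``.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if w.shape != v.shape:
        raise InvalidInputError("w and v must have the same shape")
    out = np.empty((w.size, 3))
    for j, (wj, vj) in enumerate(zip(w, v)):
        exhaling = vj >= 0.0
        if invert_breathing_sign:
            exhaling = not exhaling
        limb = EXHALATION_BRANCHES if exhaling else INHALATION_BRANCHES
        alpha = _select_branch(model, wj, limb)
        out[j] = model.slopes[alpha] * wj + model.intercepts[alpha]
    return out
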