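"""Domain types and index/time conventions shared by the whole pipeline.

A *scan* is the atomic validation unit: three abdominal infrared (IR)
marker traces recorded along the anterior-posterior (AP) axis, plus the
triangulated 3D target trace (LR/SI/AP), uniformly sampled at ``dt``
(nominally 0.2 s over 70 s, i.e. 351 samples).  Every scan is split into a
*modeling* first half and a *validating* second half; training and
drift-correction windows are always suffixes of the modeling half.

Index convention: samples are 0-based, ``t_k = k * dt``.  All windows end
at the last modeling-session index so that model fitting never touches
validating data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
import numpy as np

__all__ = [
    "Direction",
    "DIRECTIONS",
    "InvalidInputError",
    "DegenerateFitError",
    "DegenerateBranchError",
    "InsufficientCyclesError",
    "UndefinedCorrelationError",
    "ConditioningWarning",
    "SurrogateTrace",
    "TargetTrace",
    "Scan",
    "SessionSplit",
    "split_sessions",
    "sample_count",
    "tail_window",
]

NOMINAL_DT = 0.2  # s
NOMINAL_DURATION = 70.0  # s
MARKER_IDS = (1, 2, 3)


class Direction(str, Enum):
    """Patient axis along which a target coordinate is expressed."""

    LR = "LR"  # left-right
    SI = "SI"  # superior-inferior
    AP = "AP"  # anterior-posterior


DIRECTIONS: tuple[Direction, Direction, Direction] = (
    Direction.LR,
    Direction.SI,
    Direction.AP,
)


class InvalidInputError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateFitError(RuntimeError):
    """Design matrix numerically rank-deficient below the usable minimum."""


class DegenerateBranchError(RuntimeError):
    """Two adjacent phase averages coincide; the branch line is undefined."""


class InsufficientCyclesError(RuntimeError):
    """Too few breathing cycles for the requested respiratory descriptor."""


class UndefinedCorrelationError(RuntimeError):
    """Pearson correlation undefined (zero variance on one side)."""


class ConditioningWarning(UserWarning):
    """Design matrix condition number exceeds the warning threshold."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SurrogateTrace:
    """AP positions (mm) of one abdominal IR marker, uniformly sampled."""

    marker_id: int
    positions: np.ndarray
    dt: float = NOMINAL_DT

    def __post_init__(self) -> None:
        if self.marker_id not in MARKER_IDS:
            raise InvalidInputError(f"marker_id must be in {MARKER_IDS}, got {self.marker_id}")
        pos = _as_float_array(self.positions, "surrogate positions")
        if pos.ndim != 1 or pos.size < 2:
            raise InvalidInputError("surrogate trace needs >= 2 samples")
        if not self.dt > 0:
            raise InvalidInputError("dt must be positive")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.size

    def shifted(self, offset_mm: float) -> "SurrogateTrace":
        """Return a copy with every sample shifted by ``offset_mm``."""
        return SurrogateTrace(self.marker_id, self.positions + offset_mm, self.dt)


@dataclass(frozen=True)
class TargetTrace:
    """3D target positions (mm) as an (n, 3) array ordered LR, SI, AP."""

    positions: np.ndarray
    dt: float = NOMINAL_DT

    def __post_init__(self) -> None:
        pos = _as_float_array(self.positions, "target positions")
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise InvalidInputError("target trace must be (n >= 2, 3)")
        if not self.dt > 0:
            raise InvalidInputError("dt must be positive")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def component(self, direction: Direction) -> np.ndarray:
        return self.positions[:, DIRECTIONS.index(Direction(direction))]


@dataclass(frozen=True)
class Scan:
    """One 4D-CBCT-style acquisition: three surrogate traces + target trace.

    ``acquired_at`` is metadata only (used for elapsed-time reporting
    between scans); no computation depends on it.
    """

    scan_id: str
    surrogates: tuple[SurrogateTrace, SurrogateTrace, SurrogateTrace]
    target: TargetTrace
    acquired_at: datetime | None = None

    def __post_init__(self) -> None:
        surrogates = tuple(self.surrogates)
        if tuple(sorted(s.marker_id for s in surrogates)) != MARKER_IDS:
            raise InvalidInputError("scan needs surrogate markers exactly {1, 2, 3}")
        surrogates = tuple(sorted(surrogates, key=lambda s: s.marker_id))
        n = len(self.target)
        dt = self.target.dt
        for s in surrogates:
            if len(s) != n:
                raise InvalidInputError("all traces in a scan must share the sample count")
            if not math.isclose(s.dt, dt, rel_tol=0, abs_tol=1e-9):
                raise InvalidInputError("all traces in a scan must share dt")
        object.__setattr__(self, "surrogates", surrogates)

    @property
    def n_samples(self) -> int:
        return len(self.target)

    @property
    def dt(self) -> float:
        return self.target.dt

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) * self.dt

    def surrogate(self, marker_id: int) -> SurrogateTrace:
        for s in self.surrogates:
            if s.marker_id == marker_id:
                return s
        raise InvalidInputError(f"no marker {marker_id} in scan {self.scan_id}")

    def mean_surrogate(self) -> np.ndarray:
        """Marker-averaged surrogate positions (mm)."""
        return np.mean([s.positions for s in self.surrogates], axis=0)


@dataclass(frozen=True)
class SessionSplit:
    """Contiguous modeling/validating index ranges covering one scan."""

    modeling: range
    validating: range

    def __post_init__(self) -> None:
        m, v = self.modeling, self.validating
        if m.step != 1 or v.step != 1:
            raise InvalidInputError("session ranges must be contiguous")
        if m.stop != v.start or m.start != 0:
            raise InvalidInputError("modeling must start at 0 and abut validating")
        if len(m) < 2 or len(v) < 2:
            raise InvalidInputError("each session needs >= 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.modeling) + len(self.validating)


def split_sessions(scan: Scan | int) -> SessionSplit:
    """Split a scan into modeling (first half) and validating (second half).

    The modeling session takes the first ``floor(n/2)`` samples; the
    validating session takes the rest, so an odd-length scan gives the
    extra sample to validation (351 -> 175/176).
    """
    n = scan if isinstance(scan, int) else scan.n_samples
    if n < 4:
        raise InvalidInputError(f"scan too short to split: n={n}")
    half = n // 2
    return SessionSplit(modeling=range(0, half), validating=range(half, n))


def sample_count(duration_s: float, dt: float) -> int:
    """Number of uniform samples covering ``duration_s`` inclusive of t=0.

    (70, 0.2) -> 351.
    """
    if duration_s <= 0 or dt <= 0:
        raise InvalidInputError("duration and dt must be positive")
    ratio = duration_s / dt
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise InvalidInputError(f"duration {duration_s} s is not a multiple of dt {dt} s")
    return int(round(ratio)) + 1


def tail_window(
    split: SessionSplit,
    T: float,
    dt: float,
    need_predecessor: bool = False,
) -> np.ndarray:
    """Indices of the last ``T/dt`` samples of the modeling session.

    This is the common window used both for model training (T = T_M) and
    for baseline medians (T = T_C).  With ``need_predecessor`` the window
    must leave at least one earlier sample available for the backward
    velocity difference.
    """
    if T <= 0 or dt <= 0:
        raise InvalidInputError("T and dt must be positive")
    ratio = T / dt
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise InvalidInputError(f"T={T} s is not a multiple of dt={dt} s")
    n_w = int(round(ratio))
    m = len(split.modeling)
    if n_w > m:
        raise InvalidInputError(f"window of {n_w} samples exceeds modeling session of {m}")
    start = split.modeling.stop - n_w
    if need_predecessor and start < 1:
        raise InvalidInputError("window leaves no predecessor sample for the velocity")
    return np.arange(start, split.modeling.stop)
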