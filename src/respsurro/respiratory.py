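"""Respiratory descriptors of a breathing trace.

Period = mean interval between consecutive end-inhalations; amplitude =
mean |end-exhalation minus end-inhalation position| within a cycle; plus
the Euclidean 3D amplitude and the Pearson correlation between the AP
surrogate and each target direction.  Extremum detection is prominence-
based; maxima are taken as end-inhalation (abdomen most anterior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (
    InsufficientCyclesError,
    InvalidInputError,
    UndefinedCorrelationError,
)

__all__ = [
    "BreathCycleSet",
    "detect_extrema",
    "respiratory_period",
    "respiratory_amplitude",
    "amplitude_3d",
    "surrogate_target_correlation",
]

DEFAULT_MIN_SEPARATION_S = 1.0
DEFAULT_PROMINENCE_IQR_FRAC = 0.2


@dataclass(frozen=True)
class BreathCycleSet:
    """Detected breathing extrema of one trace.

    ``end_inhalation_indices`` are the trace maxima, ``end_exhalation_indices``
    the minima; they strictly alternate.  ``dt`` converts indices to time.
    """

    end_inhalation_indices: np.ndarray
    end_exhalation_indices: np.ndarray
    positions: np.ndarray
    dt: float

    @property
    def periods(self) -> np.ndarray:
        """Per-cycle periods (s): successive end-inhalation intervals."""
        return np.diff(self.end_inhalation_indices) * self.dt

    @property
    def amplitudes(self) -> np.ndarray:
        """Per-cycle amplitudes (mm).

        Each end-inhalation is paired with the immediately preceding
        end-exhalation (a cycle runs exhale-trough -> inhale-peak).
        """
        amps = []
        for k in self.end_inhalation_indices:
            prior = self.end_exhalation_indices[self.end_exhalation_indices < k]
            if prior.size:
                amps.append(abs(self.positions[k] - self.positions[prior[-1]]))
        return np.asarray(amps, dtype=float)


def _alternating(idx_max, idx_min, prom_max, prom_min):
    """Merge extrema; among same-type neighbours keep the more prominent."""
    events = sorted(
        [(int(i), +1, p) for i, p in zip(idx_max, prom_max)]
        + [(int(i), -1, p) for i, p in zip(idx_min, prom_min)]
    )
    kept: list[tuple[int, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    maxima = np.array([i for i, s, _ in kept if s > 0], dtype=int)
    minima = np.array([i for i, s, _ in kept if s < 0], dtype=int)
    return maxima, minima


def detect_extrema(
    positions: np.ndarray,
    dt: float,
    min_prominence: float | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    smooth_window_s: float = 0.0,
) -> BreathCycleSet:
    """Detect alternating breathing extrema of a 1-D trace.

    ``min_prominence`` defaults to 20% of the trace interquartile range,
    which rejects sub-millimetre ripple at 5 Hz sampling; ``min_separation``
    (s) suppresses double detections within a cycle limb.  An optional
    moving-average of width ``smooth_window_s`` is applied before
    detection (indices still refer to the raw trace sampling grid).
    """
    x = np.asarray(positions, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InvalidInputError("trace must be 1-D with >= 3 samples")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if smooth_window_s > 0:
        width = max(1, int(round(smooth_window_s / dt)))
        kernel = np.ones(width) / width
        x_det = np.convolve(x, kernel, mode="same")
    else:
        x_det = x
    if min_prominence is None:
        q75, q25 = np.percentile(x_det, [75, 25])
        min_prominence = DEFAULT_PROMINENCE_IQR_FRAC * (q75 - q25)
    distance = max(1, int(round(min_separation / dt)))
    kw = dict(prominence=max(min_prominence, 1e-12), distance=distance)
    idx_max, props_max = find_peaks(x_det, **kw)
    idx_min, props_min = find_peaks(-x_det, **kw)
    maxima, minima = _alternating(
        idx_max, idx_min, props_max["prominences"], props_min["prominences"]
    )
    return BreathCycleSet(
        end_inhalation_indices=maxima,
        end_exhalation_indices=minima,
        positions=x,
        dt=dt,
    )


def respiratory_period(cycles: BreathCycleSet) -> float:
    """Mean interval (s) between consecutive end-inhalations."""
    if cycles.end_inhalation_indices.size < 2:
        raise InsufficientCyclesError("need >= 2 end-inhalations for a period")
    return float(cycles.periods.mean())


def respiratory_amplitude(cycles: BreathCycleSet) -> float:
    """Mean |end-exhalation − end-inhalation| position difference (mm)."""
    amps = cycles.amplitudes
    if amps.size < 1:
        raise InsufficientCyclesError("need >= 1 complete cycle for an amplitude")
    return float(amps.mean())


def amplitude_3d(amplitudes) -> float:
    """Euclidean norm of the per-direction amplitudes (mm).

    How per-direction amplitudes combine into a single 3D motion figure
    is a convention; the Euclidean norm of (A_LR, A_SI, A_AP) is used
    here.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)) or np.any(a < 0):
        raise InvalidInputError("need three finite non-negative amplitudes")
    return float(np.linalg.norm(a))


def surrogate_target_correlation(surrogate: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation between an AP surrogate trace and one target axis."""
    x = np.asarray(surrogate, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("traces must be equal-length 1-D with >= 3 samples")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance on one side")
    return float(np.corrcoef(x, y)[0, 1])
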