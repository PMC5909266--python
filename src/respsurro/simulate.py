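"""Synthetic respiratory-motion generator.

Real validation data for this method are paired traces of abdominal IR
markers and a triangulated internal target recorded during 70-s cone-beam
CT scans.  This module generates scans with the same statistical
structure: quasi-periodic breathing with per-cycle period/amplitude
jitter, a known ground-truth quadratic surrogate-to-target coupling
(including velocity terms, i.e. hysteresis), measurement noise,
inter-scan baseline drift of both surrogate and target, and irregular
breathing events (apnea, hypopnea, hyperpnea, correlation changes).

The waveform is the classic ``cos^(2n)`` breathing profile: within one
cycle of period ``τ`` starting at end-exhalation,

    w(t) = baseline + A · (1 − cos^(2n)(π (t − t0) / τ)),

so the trace rests at the baseline (end-exhalation) at cycle boundaries,
dwells longest there, and peaks at end-inhalation mid-cycle, with ``A``
the peak-to-peak amplitude.  Amplitude-type irregularity events scale the
oscillation, so an apnea (magnitude 0) is a breath hold at the
end-exhalation resting level.

Drift semantics for a scan pair: by default the surrogate and target
baselines drift *additively and independently* — scan B's measured
surrogate is the breathing signal plus ``surrogate_shift``, while its
target is the coupling truth applied to the unshifted breathing signal
plus ``target_shift``.  This is the situation the baseline-drift
correction is designed for (the oscillatory coupling persists; each
resting position wanders on its own).  With ``drift_in_coupling=True``
the target instead follows the *measured* (shifted) surrogate through
the coupling plus ``target_shift``, a variant in which an uncorrected
model stays wrong by exactly the target shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .core import (
    DIRECTIONS,
    MARKER_IDS,
    InsufficientCyclesError,
    InvalidInputError,
    Scan,
    SurrogateTrace,
    TargetTrace,
    sample_count,
)
from .model import N_PHASES
from .respiratory import detect_extrema

__all__ = [
    "BreathingParams",
    "CouplingTruth",
    "IrregularityEvent",
    "CohortMember",
    "DEFAULT_COHORT_RANGES",
    "simulate_surrogate",
    "simulate_target",
    "simulate_scan",
    "simulate_scan_pair",
    "simulate_phase_averages",
    "simulate_cohort",
]

_EPOCH = datetime(2021, 6, 1, 9, 0, 0)

EVENT_KINDS = ("apnea", "hypopnea", "hyperpnea", "correlation_change")


@dataclass(frozen=True)
class BreathingParams:
    """Generator settings for one virtual patient's breathing.

    ``marker_amplitudes`` are peak-to-peak AP excursions (mm) of the three
    abdominal markers; ``waveform_exponent`` is ``n`` in the cos^(2n)
    profile (n=2 gives the typical extended end-exhalation dwell);
    ``drift_rate`` adds a slow within-scan linear trend (mm/min), off by
    default because inter-scan drift is modelled as a constant offset.
    """

    mean_period: float = 4.0
    period_sd: float = 0.2
    marker_amplitudes: tuple[float, float, float] = (8.0, 7.0, 6.0)
    amplitude_sd_frac: float = 0.05
    waveform_exponent: int = 2
    surrogate_noise_sd: float = 0.1
    drift_rate: float = 0.0
    baselines: tuple[float, float, float] = (10.0, 12.0, 14.0)

    def __post_init__(self) -> None:
        if self.mean_period <= 1.0:
            raise InvalidInputError("mean_period must exceed 1 s")
        if self.period_sd < 0 or self.amplitude_sd_frac < 0:
            raise InvalidInputError("jitter parameters must be non-negative")
        if any(a < 0 for a in self.marker_amplitudes):
            raise InvalidInputError("marker amplitudes must be non-negative")
        if self.waveform_exponent < 1:
            raise InvalidInputError("waveform_exponent must be >= 1")
        if self.surrogate_noise_sd < 0:
            raise InvalidInputError("surrogate_noise_sd must be non-negative")


@dataclass(frozen=True)
class IrregularityEvent:
    """Breathing irregularity over ``[start, start + duration]`` seconds.

    ``magnitude`` multiplies the oscillation amplitude (apnea ~ 0,
    hypopnea < 1, hyperpnea > 1) or, for ``correlation_change``, the
    coupled part of the target motion.
    """

    kind: str
    start: float
    duration: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidInputError(f"event kind must be one of {EVENT_KINDS}")
        if self.start < 0 or self.duration <= 0:
            raise InvalidInputError("event must have start >= 0 and duration > 0")
        if self.magnitude < 0:
            raise InvalidInputError("event magnitude must be non-negative")

    def active(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start) & (t <= self.start + self.duration)


@dataclass(frozen=True)
class CouplingTruth:
    """Ground-truth coefficients of the surrogate-to-target coupling.

    ``coeffs[i, g]`` = (a, b, c, d, e) for marker i, direction g; the
    generated target is the mean of the three per-marker couplings plus
    Gaussian noise, so the estimator's marker averaging is correctly
    specified under the truth.  Nonzero d/e terms produce hysteresis
    (target leading/lagging the surrogate).
    """

    coeffs: np.ndarray
    target_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (3, 3, 5) or not np.all(np.isfinite(c)):
            raise InvalidInputError("coeffs must be a finite (3, 3, 5) array")
        if self.target_noise_sd < 0:
            raise InvalidInputError("target_noise_sd must be non-negative")
        object.__setattr__(self, "coeffs", c)

    @classmethod
    def uniform(
        cls,
        a=(0.0, 0.0, 0.0),
        b=(0.2, 1.5, 0.8),
        c=(0.0, 0.0, 0.0),
        d=(0.0, 0.0, 0.0),
        e=(0.0, 0.0, 0.0),
        target_noise_sd: float = 0.0,
    ) -> "CouplingTruth":
        """Truth with identical coefficients for all three markers."""
        per_dir = np.column_stack([a, b, c, d, e])  # (3 directions, 5)
        return cls(np.broadcast_to(per_dir, (3, 3, 5)).copy(), target_noise_sd)


def _draw_cycles(
    params: BreathingParams, duration: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """(start_s, period_s, amplitude_factor) per cycle covering the scan."""
    cycles = []
    t = 0.0
    while t <= duration:
        tau = params.mean_period + params.period_sd * rng.standard_normal()
        tau = max(1.0, tau)
        f = max(0.05, 1.0 + params.amplitude_sd_frac * rng.standard_normal())
        cycles.append((t, tau, f))
        t += tau
    return cycles


def _amplitude_envelope(t: np.ndarray, events) -> np.ndarray:
    env = np.ones_like(t)
    for ev in events:
        if ev.kind in ("apnea", "hypopnea", "hyperpnea"):
            env[ev.active(t)] = ev.magnitude
    return env


def _oscillation(
    t: np.ndarray, cycles, exponent: int
) -> np.ndarray:
    """Unit-amplitude breathing profile in [0, 1] (trough at cycle starts)."""
    osc = np.empty_like(t)
    starts = np.array([c[0] for c in cycles])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(cycles) - 1)
    for j, (t0, tau, f) in enumerate(cycles):
        mask = idx == j
        u = (t[mask] - t0) / tau
        osc[mask] = f * (1.0 - np.cos(np.pi * u) ** (2 * exponent))
    return osc


def simulate_surrogate(
    params: BreathingParams,
    duration: float = 70.0,
    dt: float = 0.2,
    events=(),
    rng: np.random.Generator | None = None,
    cycles=None,
) -> tuple[SurrogateTrace, SurrogateTrace, SurrogateTrace]:
    """Generate the three IR-marker traces of one scan.

    All markers share the cycle schedule (they ride the same breathing)
    but have their own peak-to-peak amplitude, baseline and noise.
    Passing ``cycles`` (from a previous call's schedule) reproduces the
    breathing phase exactly, which is how paired scans share breathing.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = sample_count(duration, dt)
    t = np.arange(n) * dt
    if cycles is None:
        cycles = _draw_cycles(params, duration, rng)
    osc = _oscillation(t, cycles, params.waveform_exponent)
    env = _amplitude_envelope(t, events)
    traces = []
    for marker_id, amp, base in zip(MARKER_IDS, params.marker_amplitudes, params.baselines):
        noise = params.surrogate_noise_sd * rng.standard_normal(n)
        w = base + params.drift_rate * t / 60.0 + env * amp * osc + noise
        traces.append(SurrogateTrace(marker_id, w, dt))
    return tuple(traces)


def simulate_target(
    surrogates,
    truth: CouplingTruth,
    dt: float,
    rng: np.random.Generator | None = None,
    events=(),
) -> TargetTrace:
    """Target trace generated from the coupling truth.

    Velocities use the backward difference; the first sample falls back
    to a forward difference (it is unusable for fitting and is excluded
    from training windows anyway).  ``correlation_change`` events scale
    the coupled (non-constant) part of the motion by their magnitude over
    their span.
    """
    rng = np.random.default_rng() if rng is None else rng
    surrogates = tuple(sorted(surrogates, key=lambda s: s.marker_id))
    n = len(surrogates[0])
    t = np.arange(n) * dt
    coupling_scale = np.ones(n)
    for ev in events:
        if ev.kind == "correlation_change":
            coupling_scale[ev.active(t)] = ev.magnitude
    total = np.zeros((n, 3))
    for i, trace in enumerate(surrogates):
        w = trace.positions
        v = np.empty(n)
        v[1:] = (w[1:] - w[:-1]) / dt
        v[0] = (w[1] - w[0]) / dt
        X = np.column_stack([w * w, w, np.ones(n), v * v, v])
        g = X @ truth.coeffs[i].T  # (n, 3)
        const = truth.coeffs[i, :, 2]  # the c terms
        total += const + coupling_scale[:, None] * (g - const)
    positions = total / 3.0
    if truth.target_noise_sd > 0:
        positions = positions + truth.target_noise_sd * rng.standard_normal((n, 3))
    return TargetTrace(positions, dt)


def simulate_scan(
    scan_id: str,
    params: BreathingParams,
    truth: CouplingTruth,
    duration: float = 70.0,
    dt: float = 0.2,
    events=(),
    rng: np.random.Generator | None = None,
    acquired_at: datetime | None = None,
    surrogate_shift: float = 0.0,
    target_shift=(0.0, 0.0, 0.0),
    cycles=None,
    drift_in_coupling: bool = False,
) -> Scan:
    """One complete scan; shifts model inter-scan baseline drift."""
    rng = np.random.default_rng() if rng is None else rng
    traces = simulate_surrogate(params, duration, dt, events, rng, cycles)
    if surrogate_shift != 0.0 and drift_in_coupling:
        traces = tuple(tr.shifted(surrogate_shift) for tr in traces)
    target = simulate_target(traces, truth, dt, rng, events)
    if surrogate_shift != 0.0 and not drift_in_coupling:
        traces = tuple(tr.shifted(surrogate_shift) for tr in traces)
    shift = np.asarray(target_shift, dtype=float)
    if shift.shape != (3,):
        raise InvalidInputError("target_shift must have one value per direction")
    if np.any(shift != 0.0):
        target = TargetTrace(target.positions + shift, dt)
    return Scan(scan_id, traces, target, acquired_at)


def simulate_scan_pair(
    params: BreathingParams,
    truth: CouplingTruth,
    elapsed_min: float = 10.0,
    surrogate_shift: float = 0.0,
    target_shift=(0.0, 0.0, 0.0),
    events_a=(),
    events_b=(),
    duration: float = 70.0,
    dt: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    share_breathing: bool = False,
    scan_id_prefix: str = "sim",
    drift_in_coupling: bool = False,
) -> tuple[Scan, Scan]:
    """Two scans of the same virtual patient, ``elapsed_min`` apart.

    Scan B re-uses the same truth but its measured surrogate baseline is
    shifted by ``surrogate_shift`` and its target baseline by
    ``target_shift`` (see the module docstring for ``drift_in_coupling``);
    noise is drawn independently.  With ``share_breathing`` scan B reuses
    scan A's exact cycle schedule (otherwise only the statistics are
    shared).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    cycles_a = _draw_cycles(params, duration, rng)
    cycles_b = cycles_a if share_breathing else _draw_cycles(params, duration, rng)
    scan_a = simulate_scan(
        f"{scan_id_prefix}_a", params, truth, duration, dt, events_a, rng,
        acquired_at=_EPOCH, cycles=cycles_a,
    )
    scan_b = simulate_scan(
        f"{scan_id_prefix}_b", params, truth, duration, dt, events_b, rng,
        acquired_at=_EPOCH + timedelta(minutes=elapsed_min),
        surrogate_shift=surrogate_shift, target_shift=target_shift, cycles=cycles_b,
        drift_in_coupling=drift_in_coupling,
    )
    return scan_a, scan_b


def simulate_phase_averages(
    scan: Scan, n_phases: int = N_PHASES, **extrema_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-averaged surrogate and target positions, as a respiration-
    sorted cone-beam CT would provide.

    Samples between consecutive end-exhalations are binned by elapsed
    cycle-time fraction: bin ``l = floor(n_phases * fraction)``, so bin 0
    is centred at end-exhalation and bin ``n_phases/2`` near
    end-inhalation.  Returns ``(w_ave (n_phases,), p_phase (n_phases, 3))``.
    """
    w_mean = scan.mean_surrogate()
    cycles = detect_extrema(w_mean, scan.dt, **extrema_kwargs)
    ee = cycles.end_exhalation_indices
    if ee.size < 3:
        raise InsufficientCyclesError("need >= 2 complete cycles for phase averaging")
    bins = np.full(scan.n_samples, -1)
    for j in range(ee.size - 1):
        k0, k1 = ee[j], ee[j + 1]
        frac = (np.arange(k0, k1) - k0) / (k1 - k0)
        bins[k0:k1] = np.minimum((n_phases * frac).astype(int), n_phases - 1)
    w_ave = np.empty(n_phases)
    p_phase = np.empty((n_phases, 3))
    for l in range(n_phases):
        mask = bins == l
        if not np.any(mask):
            raise InsufficientCyclesError(f"phase bin {l} is empty")
        w_ave[l] = w_mean[mask].mean()
        p_phase[l] = scan.target.positions[mask].mean(axis=0)
    return w_ave, p_phase


#: population spans the cohort draws from by default (per-patient uniform)
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "mean_period_s": (2.4, 13.0),
    "marker_amplitude_mm": (1.7, 14.6),
    "target_amplitude_3d_mm": (2.8, 34.2),
    "elapsed_min": (1.7, 15.0),
    "surrogate_shift_mm": (0.1, 5.0),
    "target_shift_mm": (0.1, 3.0),
    "surrogate_noise_sd_mm": (0.05, 0.2),
    "target_noise_sd_mm": (0.1, 0.4),
    "period_jitter_frac": (0.02, 0.08),
    "amplitude_jitter_frac": (0.02, 0.10),
    "curvature_frac": (0.0, 0.15),
    "velocity_frac": (0.0, 0.15),
}

#: probability that scan B of a cohort member contains one irregular event
DEFAULT_EVENT_PROBABILITY = 0.2


@dataclass(frozen=True)
class CohortMember:
    """One virtual patient: a scan pair plus its generative ground truth."""

    patient_id: str
    scan_a: Scan
    scan_b: Scan
    params: BreathingParams
    truth: CouplingTruth
    elapsed_min: float
    surrogate_shift: float
    target_shift: np.ndarray
    events_b: tuple = ()

    @property
    def pair(self) -> tuple[Scan, Scan]:
        return (self.scan_a, self.scan_b)


def _draw_truth(
    rng: np.random.Generator,
    ranges: dict,
    a3d: float,
    marker_amps: np.ndarray,
    baselines: np.ndarray,
    mean_period: float,
) -> CouplingTruth:
    """Random but physiologically shaped coupling for one patient.

    SI carries the largest share of the drawn 3D amplitude (that axis
    correlates most strongly with abdominal motion); LR/AP signs are
    random.  The quadratic term is parameterised around each marker's
    breathing working point (baseline − amp/2), so ``curvature_frac``
    bounds the nonlinear contribution relative to the per-direction
    amplitude instead of being leveraged by the absolute baseline offset;
    velocity terms (d, e) add a bounded hysteresis fraction.
    """
    weights = np.array(
        [rng.uniform(0.05, 0.5), rng.uniform(0.7, 1.0), rng.uniform(0.2, 0.8)]
    )
    a_dir = a3d * weights / np.linalg.norm(weights)
    signs = np.array([rng.choice((-1.0, 1.0)), 1.0, rng.choice((-1.0, 1.0))])
    kappa = rng.uniform(*ranges["curvature_frac"])
    nu = rng.uniform(*ranges["velocity_frac"])
    v_scale = np.pi * marker_amps.mean() / mean_period  # typical |dw/dt|
    coeffs = np.zeros((3, 3, 5))
    for i, (amp, base) in enumerate(zip(marker_amps, baselines)):
        slope = signs * a_dir / amp
        a = kappa * slope / amp
        w_center = base - amp / 2.0
        coeffs[i, :, 0] = a
        coeffs[i, :, 1] = slope - 2.0 * a * w_center
        coeffs[i, :, 2] = rng.uniform(-30.0, 30.0, size=3)
        coeffs[i, :, 3] = 0.2 * nu * signs * a_dir / v_scale**2
        coeffs[i, :, 4] = nu * signs * a_dir / v_scale
    noise = float(rng.uniform(*ranges["target_noise_sd_mm"]))
    return CouplingTruth(coeffs, target_noise_sd=noise)


def _maybe_event(rng: np.random.Generator, duration: float, prob: float):
    if rng.uniform() >= prob:
        return ()
    kind = str(rng.choice(("apnea", "hypopnea", "hyperpnea")))
    magnitude = {
        "apnea": rng.uniform(0.0, 0.1),
        "hypopnea": rng.uniform(0.3, 0.7),
        "hyperpnea": rng.uniform(1.3, 1.8),
    }[kind]
    start = rng.uniform(5.0, duration - 20.0)
    return (
        IrregularityEvent(
            kind, float(start), float(rng.uniform(5.0, 15.0)), float(magnitude)
        ),
    )


def simulate_cohort(
    n_patients: int,
    param_ranges: dict | None = None,
    seed: int = 0,
    duration: float = 70.0,
    dt: float = 0.2,
    event_probability: float = DEFAULT_EVENT_PROBABILITY,
) -> list[CohortMember]:
    """Virtual-patient cohort of scan pairs for grid-sweep evaluation.

    Per-patient parameters are drawn uniformly from
    :data:`DEFAULT_COHORT_RANGES` (overridable per key); everything is
    deterministic for a given ``seed``.
    """
    if n_patients < 1:
        raise InvalidInputError("n_patients must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    members = []
    for p in range(n_patients):
        # periods cluster around ~4 s with a long right tail; the range
        # bounds clip the extremes rather than defining a uniform draw
        period = float(
            np.clip(rng.lognormal(np.log(4.2), 0.35), *ranges["mean_period_s"])
        )
        # abdominal excursion tracks target amplitude across patients
        # (large tumour motion comes with large abdominal motion)
        a3d = rng.uniform(*ranges["target_amplitude_3d_mm"])
        amp_lo, amp_hi = ranges["marker_amplitude_mm"]
        base_amp = np.clip(a3d / rng.uniform(1.5, 3.5), amp_lo, amp_hi)
        amps = base_amp * rng.uniform(0.85, 1.15, size=3)
        baselines = rng.uniform(5.0, 20.0, size=3)
        params = BreathingParams(
            mean_period=period,
            period_sd=float(rng.uniform(*ranges["period_jitter_frac"])) * period,
            marker_amplitudes=tuple(float(a) for a in amps),
            amplitude_sd_frac=float(rng.uniform(*ranges["amplitude_jitter_frac"])),
            surrogate_noise_sd=float(rng.uniform(*ranges["surrogate_noise_sd_mm"])),
            baselines=tuple(float(b) for b in baselines),
        )
        truth = _draw_truth(rng, ranges, a3d, amps, baselines, period)
        lo, hi = ranges["surrogate_shift_mm"]
        surrogate_shift = rng.choice((-1.0, 1.0)) * rng.uniform(lo, hi)
        lo, hi = ranges["target_shift_mm"]
        target_shift = rng.choice((-1.0, 1.0), size=3) * rng.uniform(lo, hi, size=3)
        events_b = _maybe_event(rng, duration, event_probability)
        scan_a, scan_b = simulate_scan_pair(
            params,
            truth,
            elapsed_min=rng.uniform(*ranges["elapsed_min"]),
            surrogate_shift=float(surrogate_shift),
            target_shift=target_shift,
            events_b=events_b,
            duration=duration,
            dt=dt,
            rng=rng,
            scan_id_prefix=f"p{p:02d}",
        )
        members.append(
            CohortMember(
                patient_id=f"p{p:02d}",
                scan_a=scan_a,
                scan_b=scan_b,
                params=params,
                truth=truth,
                elapsed_min=(scan_b.acquired_at - scan_a.acquired_at).total_seconds() / 60.0,
                surrogate_shift=float(surrogate_shift),
                target_shift=target_shift,
                events_b=events_b,
            )
        )
    return members
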