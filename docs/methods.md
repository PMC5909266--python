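# Methods

## The estimation model

The core assumption is that over a span of minutes, the 3D position of an
internal target is a smooth, memory-one function of a single external
breathing signal: each direction γ of the target is modelled per IR marker
i as

    P_{i,γ}(t_k) = a w² + b w + c + d v² + e v,   v = (w(t_k) − w(t_{k−1}))/Δt,

and the reported estimate is the unweighted mean of the three per-marker
estimates. The quadratic position terms capture mild nonlinearity of the
abdominal-to-internal transfer; the velocity terms capture hysteresis
(different internal position during inhalation and exhalation at the same
abdominal position). Units: w, P in mm, v in mm/s, so a is mm⁻¹, b
dimensionless, c mm, d s²·mm⁻¹, e s.

Coefficients are fitted by unweighted least squares over the last `T_M`
seconds of the *modeling session* (the first half of a scan). The solver is
SVD-based (`numpy.linalg.lstsq`): minimum-norm on rank-deficient windows, a
`ConditioningWarning` above condition number 1e8, and a `DegenerateFitError`
when the numerical rank falls below 2 (e.g. a constant surrogate). The
backward velocity difference is undefined at the first sample of a scan, so
index 0 is excluded from any training window that reaches it (relevant only
for `T_M = 35` s, which spans the whole modeling session, and the 70-s
whole-scan comparator); for every shorter window the sample immediately
before the window supplies the first velocity.

### Index and window conventions

Samples are 0-based with t_k = k·Δt, Δt = 0.2 s; a 70-s scan has 351
samples. The modeling session is the first ⌊n/2⌋ samples (175 for n = 351),
the validating session the remainder (176). Every training and correction
window is a suffix of the modeling session ending at its **last** index, so
model construction never touches validating data. (A window running literally
up to sample index 35/Δt would include the first validating sample; we
keep the strict session separation and accept the one-sample shift.)

The `T_M = 70 s` comparator deliberately trains on the entire scan,
validating session included — it is a lower-bound reference, not a
deployable model, and is labelled as such.

## Baseline-drift correction

Scans minutes apart show baseline drift of both surrogate and target. The
baseline of a scan is defined as the **median** position over the last
`T_C` seconds of its modeling session (even-length windows: mean of the two
central order statistics). Correction proceeds in two steps for a model
trained on scan A and applied to scan B:

1. **Surrogate**: BD_IR = median{w_B window} − median{w_A window}, per
   marker; scan B's surrogate is shifted by −BD_IR before the model is
   evaluated (velocities are unaffected by a constant shift).
2. **Target**: BD_Target = median{shifted-surrogate estimates over scan B's
   window} − anchor, per direction, subtracted from the estimates.

Two anchors are implemented and never silently conflated:

- `scan_a` (target baseline referenced to the training scan): the anchor is the median of scan A's
  *actual* target over scan A's window. Corrected estimates are thereby
  pinned to scan A's target baseline; a genuine target baseline shift
  between the scans is *not* removed, and the residual floor is the target
  shift magnitude. The window-median identity — median of corrected
  estimates over scan B's window equals scan A's actual window median —
  holds exactly by construction.
- `scan_b`: the anchor is the median of scan B's actual target over scan
  B's own window. This variant removes a genuine target baseline shift
  (exactly, on noiseless pure-shift pairs) and uses both medians over the
  *same* window, so partial-cycle phase coverage cancels. It requires
  scan B's actual target over the correction window, which is available in
  the intended workflow (the correction window precedes the validating
  session).

For the phase-linear comparator the anchor is always the centroid of scan
A's eight phase-averaged target positions.

The grid constraint `T_C ≤ T_M` is enforced when a correction is computed
for a quadratic model; the grid sweep skips infeasible cells rather than
failing.

## Phase-linear comparator

Eight phase-averaged surrogate positions w_ave(l) and target positions
P(l), l = 0..7 (phase 0 = end-exhalation, phase 4 = end-inhalation), define
one line per adjacent phase pair (α, β) ∈ {(0,1), …, (7,0)}. At prediction
time the breathing limb is chosen by the velocity sign — positive →
exhalation branches (4,5)…(7,0), negative → inhalation branches (0,1)…(3,4),
zero ties to exhalation — and within the limb the branch whose [min, max]
of endpoint phase averages contains w is evaluated. Which physical limb a
velocity sign corresponds to depends on the AP axis orientation of the
tracking system, so `invert_breathing_sign` flips the convention.
Membership uses [min, max] of the endpoints because the literal inequality
w_ave(α) ≤ w ≤ w_ave(β) is unsatisfiable on the descending limb.
Out-of-range surrogate positions clamp to the nearest branch of the limb
and extrapolate its line (holding at the extreme phase value would create
flat segments the data do not show). Phase binning of a scan assigns each
sample the bin ⌊8 · (elapsed cycle-time fraction since end-exhalation)⌋;
this time-fraction sorting is this package's stand-in for scanner-side
respiratory sorting, whose exact algorithm is vendor-specific.

## Metrics

RMSE is computed per direction and as the RMS of the per-sample 3D
Euclidean error; the two are linked by the identity
rmse_3d² = Σ_γ rmse_γ², asserted at report construction to 1e-9 relative.
Grid-sweep distributions are summarised with type-7 (linear interpolation)
quartiles and Tukey 1.5·IQR whiskers; points beyond the whiskers are listed
as outliers. Per-cell failures (degenerate fits on pathological inputs) are
counted and excluded rather than aborting a sweep. Statistical hypothesis
testing across grid cells is intentionally out of scope; the long-format
per-cell distributions are exported for downstream analysis.

## The simulator

The generator emulates the statistical structure the method assumes rather
than any imaging chain:

- **Waveform**: per cycle of period τ drawn from N(mean_period, period_sd)
  (truncated above 1 s), w(t) = baseline + A·(1 − cos^{2n}(π(t−t₀)/τ)) + ε,
  with n = 2 by default — the classic breathing profile with an extended
  end-exhalation dwell; A is the peak-to-peak amplitude with per-cycle
  jitter, ε is white Gaussian measurement noise. The baseline is the
  end-exhalation resting level, so an apnea event (amplitude factor ≈ 0) is
  a breath hold at end-exhalation.
- **Coupling**: the target is the mean of the three per-marker quadratic
  couplings plus Gaussian noise, so the estimator is correctly specified
  under the truth; a first-sample forward velocity difference is used only
  there (it is excluded from fitting). `correlation_change` events scale
  the coupled (non-constant) part of the motion over their span, emulating
  the sudden internal/external decorrelations seen clinically.
- **Inter-scan drift**: constant offsets, applied between the scans of a
  pair. Default semantics are *additive and independent* — the measured
  surrogate gains the shift while the target stays coupled to the
  underlying breathing signal plus its own offset; this is the situation
  the median correction is designed for. The `drift_in_coupling=True`
  variant couples the target to the measured (shifted) surrogate instead,
  which makes the uncorrected error equal the target shift exactly and is
  used by the exact-recovery tests. A within-scan linear drift term exists
  for stress tests and is off by default.
- **Cohort**: per-patient parameters are drawn once per seed. Periods
  follow a lognormal with median 4.2 s and σ = 0.35, clipped to
  [2.4, 13.0] s — breathing periods cluster near 4 s with a long right
  tail; a uniform draw over the full range would make long-period patients
  the majority and starve sub-cycle correction windows. The target 3D
  amplitude is uniform on [2.8, 34.2] mm, split across directions with SI
  dominant (the axis that tracks abdominal motion most strongly) and random
  LR/AP signs; marker amplitudes are the target amplitude divided by a
  gain drawn from U(1.5, 3.5), clipped to [1.7, 14.6] mm, with ±15%
  marker-to-marker spread — amplitudes of the two motions are correlated
  across patients, and uncorrelated draws would create implausible gain
  levers. Curvature and hysteresis fractions are each up to 15% of the
  per-direction amplitude, parameterised around the breathing working
  point so the bound actually holds. Noise: 0.05–0.2 mm (surrogate),
  0.1–0.4 mm (target). Elapsed time 1.7–15.0 min; surrogate baseline
  shifts 0.1–5 mm and target shifts 0.1–3 mm per direction, random signs.
  Each scan B carries one irregular event with probability 0.2.

What the simulator does **not** emulate: cardiac motion, slow intra-scan
amplitude trends, non-Gaussian spike noise, imaging/triangulation errors,
and genuinely nonstationary couplings beyond the step-type events. Passing
tests therefore demonstrate correctness of the estimation and correction
machinery under the method's own assumptions, not clinical accuracy; the
published clinical error levels cannot be reproduced without the patient
traces.

## Problem sizes and numerical choices

Validation suites use 70-s scans (351 samples), 20-seed replications for
noise-floor and sub-cycle statistics, and 20-virtual-patient cohorts over
3 seeds for grid sweeps — large enough for stable medians while keeping a
full run in seconds. Exactness tolerances: 1e-6 relative for noiseless
coefficient recovery, 1e-9 for algebraic identities, 1e-12 for median
book-keeping identities. Extremum detection defaults: prominence ≥ 20% of
the trace interquartile range and ≥ 1 s separation, which rejects
sub-millimetre ripple at 5 Hz sampling without smoothing; an optional
moving-average width is exposed. Zero surrogate velocity at prediction
time ties to the exhalation limb. Timestamps are metadata used only for
elapsed-time reporting.

## Known limitations

- The scan-A anchor leaves any true target baseline
  shift uncorrected by construction; on simulated pure-shift pairs the
  scan-B anchor is strictly better. Real data may behave differently if
  target and surrogate drifts are strongly coupled.
- Median baselines assume the correction window covers at least about one
  breathing cycle; for slow breathers (> 10 s) with T_C = 5–10 s the
  baseline estimate carries partial-cycle bias (the scan-B anchor cancels
  it; the scan-A anchor does not).
- The marker-averaged estimate responds to a common surrogate shift with
  the average of per-marker amplitude ratios; with strongly unequal marker
  amplitudes this leaves a small constant residual that the target-drift
  step absorbs only when correction is enabled.
- No model updating during irradiation and no regularised/robust fitting
  variants — the method is deliberately train-once.
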