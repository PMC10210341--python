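# Methods

This note records the model, the procedures, the numerical conventions and
the deliberately made design choices behind `reacheval`.

## Kinematic features

Each trial is a sampled planar path (t, x, y) with target distance *A* and
width *W*; positions are in cm, sample time in s, movement time in ms,
average speed in m/s.  Per trial:

* **Movement time T_M.**  The robot-recorded value is used when present
  (the recording device is authoritative; whether it includes dwell or
  reaction segments is device-specific and is preserved verbatim).
  Otherwise T_M is the span between the first and last samples whose
  tangential speed reaches `onset_fraction` (default 0.02) of the peak
  speed.  For a single minimum-jerk pulse the threshold crossings solve
  30 (τ(1−τ))² = 0.02 · 1.875, i.e. τ = 0.0367 and 0.9633, so the measured
  span is 92.66% of the pulse duration; tests freeze this value.
* **Tangential speed.**  The recorded speed channel verbatim when present,
  otherwise centered finite differences (one-sided at the endpoints).
* **Average speed AS** = path length / T_M and **curvature index CI** =
  path length / straight start-to-end distance, both over a configurable
  window: `threshold` (the onset/offset window above, the default for real
  recordings, which include dwell) or `full` (the whole sampled trial, the
  natural choice for synthetic sessions whose samples span exactly the
  movement).  CI ≥ 1 by construction; a path whose chord is < 1e−9 of its
  length is reported as a degenerate (closed-path) trial.
* **Submovement count NS.**  The speed profile is decomposed into
  minimum-jerk speed pulses v(τ) = (s/D)·(30τ² − 60τ³ + 30τ⁴).  "Optimal"
  is operationalized as the *smallest* pulse count M whose best nonlinear
  least-squares fit reaches RMSE ≤ 5% of peak speed (so corrective counts
  are not exaggerated by over-segmentation), with multi-start
  initialization from the M largest local speed maxima and a cap of 10
  pulses (NS means in practice are ≈ 2.5–4).  Loosening the tolerance can
  only lower the count, by construction.

Before model fitting, trials whose CI lies beyond two interquartile ranges
outside [Q1, Q3] (Tukey-style fences at Q1 − 2·IQR and Q3 + 2·IQR,
quartiles by linear interpolation) are rejected: an extreme CI indicates a
reach-by-mistake rather than a normal reach.  The lower fence is normally
inert since CI ≥ 1.  The rule needs at least 5 trials.

## Movement-time models

Fitts' law is fitted by OLS of T_M [ms] on ID = log₂(2A/W).  The power
laws are fitted by OLS of ln T_M on the family's log regressors, with A in
meters, AS in m/s and T_M in seconds; the intercept k absorbs the unit
choice, which is recorded in the serialized model file.  The response is
the movement time: the models predict T_M from task and behaviour
variables.  R² and AIC are computed in each family's fitted space (ms for
Fitts, log for the power laws), so AIC is typically positive for Fitts and
negative for the power laws; cross-space values are reported as-is, not
converted.  AIC = n·ln(2π·RSS/n) + n + 2(p+1), counting the error variance
as a parameter; a perfect fit returns −∞ with a warning.  Residuals are
back-transformed to milliseconds for cross-family comparison and are
paired with each trial's NS and CI for residual-vs-error-parameter
analysis.

**A structural identity worth knowing.**  For features extracted from one
common window, AS ≡ CI·A/T_M *by definition* (AS = path/T_M and CI =
path/A).  Hence ln T_M = ln CI + ln A − ln AS holds exactly, and the
simplified Almanji family — whose regressor set spans exactly these terms —
always admits a perfect tautological fit (k, α, β, d, f) = (0, 1, −1, 0, 1)
on kinematically consistent data.  Two consequences: (i) its near-unity R²
on real or consistent synthetic sessions carries no information about
reaching normality, which is precisely why it cannot serve as the normal
model; (ii) the law's parameters (d, f) are only identifiable from data in
which AS carries information beyond CI·A/T_M — in the synthetic erroneous
mode this is the latent speed trait (below).  The proposed family omits
ln CI, so no tautology is available to it and its fit quality genuinely
reflects whether reaching follows the normal law.

## Evaluation index and map

e_n = (T_M,a − T_M,e)/T_M,e, with T_M,e predicted by the less-affected
arm's proposed model at each affected trial's own (A, AS).  e_n is
computed per trial and then averaged per target (not e_n of averaged
times; the two differ and the trial-wise order is the implemented one).
e_n is scale-free — multiplying both times by a constant leaves it
unchanged — so it is comparable across target distances, unlike raw
movement time.  Targets with no successful trial are marked unreachable
and masked in the map.  The map's display ceiling is the 95th percentile
(linear interpolation) of the per-target means — the plotted quantities —
and the floor is their minimum; cell values are stored unclipped, clipping
affects display only.  Rendering draws the discrete polar cells
(`pcolormesh`); all quantitative output comes from the unsmoothed grid CSV
written alongside the PNG/SVG.

## Synthetic sessions

The generator is **feature-first**: the feature tuple is drawn from the
generative law, then a trajectory consistent with it is realized.  This
makes (k, α, β, d, f) exactly recoverable by regression and sidesteps the
endogeneity that trajectory-first sampling would create through
AS = CI·A/T_M.

* **Normal mode** (less-affected / healthy): AS ~ lognormal (median
  0.045 m/s, log-sd 0.3); T_M = e^k A^α AS^β · e^(σz) with σ = 0.07;
  path length L = AS·T_M on a circular arc of chord A (the one-parameter
  family with exact chord and arc-length control), traversed by NS
  overlapping minimum-jerk pulses whose durations sum to T_M (NS ~
  support {2,3,4}, mean ≈ 2.9; normal reaches contain a few submovements,
  they just do not enter the time law).  When a draw yields L < A
  (≈ 2% of trials at the defaults) AS is re-solved from AS·T_M(AS) = A, so
  the trial reaches the target with CI = 1 while the (AS, T_M) pair stays
  exactly on the law.  Extracted (T_M, AS, CI) match the ground truth to
  within one sample period, 1% and 2·10⁻³ respectively (discretization
  and window clipping only).
* **Erroneous mode** (affected): NS ~ weighted support {2,…,6} (mean 3.8),
  CI = 1 + Gamma(1.0, 0.5) truncated at 3, AS a *latent* lognormal speed
  trait, and T_M = e^k A^α AS^β (NS+1)^d CI^f · e^(σz) with defaults
  d = 0.15, f = 0.8.  The trajectory realizes the sampled CI exactly
  (arc of chord A, length CI·A) and the sampled T_M exactly (recorded
  movement time); geometry then pins the *extracted* average speed to
  CI·A/T_M, so the latent AS is recorded in the ground-truth table and is
  the quantity the law is identified from (see the identity above —
  demanding extracted-AS consistency would make d and f unidentifiable).
* A **patient** is a normal-law less-affected session plus an
  erroneous-law affected session sharing subject, grid and (k, α, β);
  optionally some targets are marked unreachable.  Every random quantity
  draws from its own child generator of the seed, so identical configs
  are bit-reproducible and degenerate laws (NS ≡ 1, CI ≡ 1, d = f = 0)
  collapse the erroneous mode onto the normal time law on the same
  streams.

Defaults were sized by an a-priori variance budget so that the synthetic
study reproduces the method's qualitative behaviour at realistic
magnitudes: movement times ≈ 1.6–5 s, AS ≈ 0.02–0.08 m/s, normal CI ≈
1.0–1.4, erroneous CI up to ≈ 3, proposed-model R² ≈ 0.93–0.97 on normal
sessions and ≈ 0.65–0.75 on erroneous ones (a gap of ≥ 0.2), with the
Almanji law near-perfect on both.  The asymmetric split d ≪ f reflects
that ln(NS+1) has a large mean relative to its spread — a large d inflates
all movement times without adding the dispersion that separates the
models — whereas ln CI contributes dispersion at little inflation.

What the generator does *not* emulate: biomechanical arm dynamics, muscle
or sensorimotor noise processes, learning or fatigue within a session,
direction-dependent impairment structure, measurement noise on positions,
or 3-D movement.  Passing tests therefore demonstrate the correctness and
discriminative behaviour of the *method* under its own assumptions, not
clinical validity on real recordings.

## Numerical conventions and edge cases

* Quartiles/percentiles: linear interpolation between order statistics
  throughout (outlier fences, map clipping).
* OLS solutions agree with explicit normal-equations solutions to 1e−8
  relative on well-conditioned designs; rank-deficient designs (e.g. one
  distance level for Fitts, or constant NS for the Almanji family) raise a
  singular-design error naming the family.
* Stationary trials, zero-path and closed-path trials raise degenerate-
  trial errors; session-level extraction reports them as skipped instead
  of failing, mirroring protocols in which unreachable targets are
  skipped.
* Trial tables are CSV with ≥ 10 significant digits; sessions round-trip
  to 1e−9 relative.  Model files and session metadata are JSON with the
  seed and input hashes embedded.
* CLI exit codes: 0 success, 2 validation/config, 3 I/O, 4 numeric.

## Problem sizes

The test-suite and acceptance studies use the two protocol sizes the
package models: 8 × 5 × 3 = 120-trial sessions for model validation
studies (fit-oracle agreement at n = 120 over 20 random sets; parameter
recovery over 100 seeds for the normal law and 50 for the erroneous law;
discrimination over 50 patient pairs) and the condensed 8 × 3 grid with
24 less-affected + 48 affected trials for end-to-end pipeline runs.
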