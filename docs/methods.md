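# Methods

This note documents the models, transforms, numerical choices and the
synthetic-data generator behind `tapcog`, and what the test suite does and
does not establish.

## Trial logs and integrity screening

A trial log is one JSON object per test-stage administration: ordered
attempts, each an ordered stream of tap events `{t, action, target,
correct}` with integer millisecond timestamps from trial start
(`src/tapcog/schema/trial_log.schema.json` is the published schema).
Integer milliseconds avoid float drift in stored logs; all derived
intervals are reported in seconds. Structural invariants are enforced at
parse time (non-decreasing timestamps, deselect only after an open select
of the same target, 10 cue records per verbal attempt, 4–8 corner-adjacent
pattern cells, at most five spatial attempts with non-decreasing levels and
failed levels retried at the same level).

Integrity screening is a verdict, not an exception, and operates at trial
level only — no subject-level imputation anywhere. Defaults: per-interval
floor 150 ms (anticipatory tapping), per-interval ceiling 300 s
(mid-trial abandonment), total duration ≤ 30 min. These thresholds are
configuration (`IntegrityConfig`); the criteria are standard for
unsupervised reaction-time data but the exact values are conventions of
this package.

Two interval-stream decisions deserve flagging. First, **all** tap events —
selections and deselections — enter the inter-tap interval stream, since
every tap is logged and the minimum is meant to capture the fastest
response of any kind. Second, the stream starts at the first tap: the
latency from stimulus onset to the first tap mixes encoding and reading
time and is excluded. Both choices are stated interface contracts rather
than inferences about the source app.

## The fourteen biomarkers

* `iSMPT` per trial = minimum inter-tap interval, pooled across the trial's
  attempts. Computed per stage per session; never pooled across sessions.
* Adjusted latency `RLa` = mean interval − iSMPT. The mean (rather than the
  sum) makes trials of different lengths comparable; it equals the mean of
  per-interval excesses over the floor, is ≥ 0 by construction, and is
  invariant under pure motor slowing (a constant added to every interval
  moves iSMPT by that constant and RLa not at all) — the decomposition that
  motivates subtracting iSMPT in the first place.
* `VRI` uses the **first** attempt of a verbal trial (repeat attempts exist
  only after errors and would dilute the accuracy estimate):
  `VRI = log10(100 − pct_correct + 1)`.
* Spatial partial credit: passed levels earn their square count (×2 in the
  dynamic stage); the highest level failed and never passed earns
  `weight·level − weight·mean(incorrect taps per attempt at that level)`,
  floored at 0. Static maximum 30 = 4+5+6+7+8; dynamic maximum 60 with 2×
  weights (8+10+12+14+16). `SRI = log10(max − raw + 1)`.
* `SRM = log10(k + 1)` where k counts incorrect selections later deselected
  within the same attempt. Note the two "mistake" notions are deliberately
  distinct: partial credit counts *incorrect taps*; SRM counts only
  *self-corrected* ones.

The `+1` inside every log₁₀ is a deliberate convention: the raw transforms
are undefined at perfect scores, and a monotone shift changes no rank-based
downstream statistic while anchoring flawless performance at exactly 0.

Quadrant stratification of the (iSMPT-S, SRLa) plane median-splits each
axis within the supplied table; ties go to the "low" side. Q1 = high/high
(combined physical + cognitive impairment), Q2 = low iSMPT & high latency
(cognitive only), Q3 = low/low, Q4 = high iSMPT & low latency (physical
only).

## Cohort protocol and the ordinal composite

MS subjects (RR-MS, SP-MS, PP-MS) are split 2/3 train : 1/3 validation
within SDMT-quartile strata (`ceil(2/3·n)` per stratum to training;
deterministic given a seed). Healthy donors are model anchors used in both
roles; other groups (NIND, OIND, RIS, CIS) are score-only. Training tables
keep up to each subject's first ten sessions; validation keeps exactly the
first.

The composite is a proportional-odds model over HD < RR-MS < P-MS
(P-MS pools the two progressive phenotypes), fitted by maximum likelihood
(BFGS) on z-scored features — standardization makes coefficients
comparable across biomarkers with different units. Classification accuracy
is reported from stratified 10-fold cross-validation with per-fold refits;
the package fits the proportional-odds model directly rather than running
a learner search, since the cross-validated accuracy is a report, not a
selection criterion, in this design. The composite score is the
threshold-free linear predictor `x'β` on standardized features. Two open
choices were resolved as follows: the score is the linear predictor (not a
class probability — it is the quantity the thresholds cut, and it
preserves the within-class ordering); and its orientation is fixed
empirically so that the training mean for P-MS exceeds that for HD (the
cumulative-logit parameterisation already makes this the identity in
practice, but the check guards against feature sets with inverted
conventions). Odds ratios are `exp(β)` per feature SD with Wald 95 % CIs
`exp(β ± 1.96·SE)`. Group contrasts use Wilcoxon rank-sum (unpaired) or
signed-rank (paired) tests and report raw p-values with no multiplicity
adjustment.

Four composite variants are first-class configurations (`FEATURE_SETS`):
verbal (4 features), spatial (6), spatial+iSMPT-S (8), and global
(verbal+spatial, 10).

## SDMT prediction and the QC envelope

All eight spatial biomarkers are OLS candidates; the reduced model is a
bidirectional stepwise search minimizing AIC, starting from the full model
(mirroring the classical stepAIC default), so each accepted step strictly
lowers AIC and the intercept-only model is admissible. A known property of
AIC selection worth stating: each pure-noise candidate survives with
probability ≈ P(χ²₁ > 2) ≈ 0.157 regardless of sample size, so "the reduced
model equals the true support" happens in roughly 84 %^(#nulls) of
replicates even under strong signal; the tests assert exactly that
behaviour.

Prediction intervals are exact t intervals for a new observation,
`x'b ± t_{df} · s·sqrt(1 + x'(X'X)⁻¹x)` — residual variance *and* leverage —
rather than the ±1.96·RMSE approximation; the difference matters at small
n and away from the training feature means. A trial is `discordant` iff
its observed SDMT lies outside the interval; queries outside the training
feature hull still receive verdicts but carry an extrapolation warning.
Serialized models store the design summary (`(X'X)⁻¹`, residual variance,
df), so a reloaded model predicts byte-identically.

Agreement statistics: Spearman Rho (average-rank ties; NaN sentinel for
constant input), R², and Lin's CCC with population (n-denominator)
moments, the convention of Lin's original estimator. Confidence intervals
for these use a participant-level nonparametric bootstrap: subjects are
resampled with replacement and all their rows travel together (2,000
replicates by default, percentile method — the minimal faithful reading of
"nonparametric bootstrap"; BCa was not used).

## Reliability battery

ICC comes from a random-intercept linear mixed model fitted by REML:
`ICC = σ²_b / (σ²_b + σ²_w)`; bands: 0.50–0.75 moderate, 0.75–0.90 good,
≥ 0.90 excellent. Unequal visit counts are handled by the mixed-model
likelihood itself. The 95 % CI is a parametric bootstrap of the fitted
model (500 seeded replicates by default): simulate from the estimated
variance components on the observed subject/visit structure, refit, take
percentiles. Degenerate inputs short-circuit: exact repeats give ICC 1;
zero between-subject variance gives ICC 0 with a degenerate-CI note.
Optimizer fallbacks (lbfgs → powell → cg) cover near-boundary fits where a
single method's profiled information matrix is singular.

Age norms: reference (healthy) trajectories are reduced to per-subject
yearly medians (calendar years from first trial), a linear score~age model
is fitted, and a two-sided 90 % new-observation band is drawn; queries are
flagged only when **above** the upper bound — the impaired side, since
higher composite = more impaired — so 5 % of healthy observations are
expected above the band by construction.

Averaging uses non-overlapping blocks of n consecutive trials (not running
means), so block means are independent under iid noise and the expected
within-subject variance reduction is exactly 1 − 1/n (75 % at n = 4).
Real series with slow trends reduce less — the trend survives averaging —
which is the desired behaviour: averaging suppresses short-term
non-cognitive fluctuation while preserving trajectories.

## Synthetic cohort generator

Each subject carries a latent profile: `motor_floor` (s), `motor_jitter`
(rate of shifted-exponential interval noise, 1/s), `cog_latency_scale`
(s per unit cognitive demand), `memory_capacity` (logistic location on the
4–8 level axis, also linked to verbal accuracy), `lapse_rate`, and
`self_correct_prob`. Observed intervals are
`motor_floor + cog_latency_scale·demand + Exp(jitter)`; 30 % of taps are
cognitively trivial (demand 0 — immediate confirmations and reflexive
responses), which is what makes the per-trial minimum converge to the
motor floor and gives iSMPT its meaning inside the generator. Spatial
patterns grow by corner-adjacent accretion (each new cell within Chebyshev
distance 1 of the pattern); that is one valid reading of "adjacent by at
least a corner" — the source app's exact algorithm is not public. Pass/fail
per level is logistic in (capacity − level); failed attempts draw
1 + Poisson mistakes scaled by the capacity shortfall; the dynamic stage
doubles per-tap demand. The simulated SDMT is
`78 − 22·cog_latency_scale − 40·motor_floor + N(0, 7²)`, truncated to
[0, 110] — chosen so that spatial-biomarker prediction of SDMT lands at a
moderate R² (≈0.4–0.65 across seeds), the regime in which an envelope QC
is actually informative.

Default group presets encode the ordered impairment gradient
HD < RR-MS < P-MS on motor floor (0.30/0.42/0.58 s), cognitive latency
(0.55/0.85/1.25 s), capacity (7.0/6.0/5.0) and lapse rate
(0.03/0.06/0.10), with NIND/OIND between HD and RR-MS; between-subject SDs
(e.g. 0.07 s floor, 0.22 s latency, 0.9 capacity) produce heavy group
overlap at the individual level, as in real cohorts. Effect sizes of this
magnitude — roughly 0.5–1.5 SD between adjacent groups — are what
moderate-size MS studies report for processing-speed measures; they were
fixed once as the generator's study conditions. Session-to-session change
is iid Gaussian jitter on `cog_latency_scale` (SD 0.08 s), enough for ICC
and averaging analyses without claiming any real temporal structure.

Determinism: one root `SeedSequence` spawns per-group, per-subject and
per-session generators; (config, seed) fixes every byte of the emitted
logs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real demographic structure (age/diagnosis joint
distributions, trial-count imbalance), practice effects, device and
time-of-day effects, non-stationary drift, verbal-item semantics
(cues are opaque ids), and the true difficulty–accuracy link (the logistic
form is the generator's assumption). Consequently the published
real-cohort effect sizes (validation R² = 0.53, Rho = 0.74, CCC = 0.66,
ICC = 0.813/0.713, the 79.5 % median variance reduction) are not numeric
targets here; the suite verifies the *mechanisms* — floor recovery,
coefficient recovery, interval calibration, the 1 − 1/n law — at
desk-scale problem sizes (e.g. 1,000 simulated sessions, 200
train/validation draws of n = 500, 50 ICC seeds at 100×4) chosen to make
Monte-Carlo error small relative to the assertion tolerances.

## Known limitations

* The ordinal model assumes proportional odds; no test of that assumption
  is provided (the composite is used as a score, not for inference on
  thresholds).
* The QC envelope is the new-observation interval of the SDMT-on-biomarkers
  fit itself, not of an observed-on-predicted recalibration; with
  errors-in-predictors its real-data coverage will be approximate.
* `bootstrap_ci` resamples subjects only; it does not implement nested
  (subject × session) resampling.
* The stepwise search refits OLS per candidate step — fine for 8
  predictors, quadratic cost in larger feature sets.
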