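# Methods

This note documents the models, conventions and design choices behind
`noctglu`: what is computed, under which assumptions, and what the
synthetic-data experiments do and do not demonstrate.

## Night window, QC and episode definitions

- The nocturnal window is the half-open interval [00:00, 06:00) local
  time. At the 15-min sensor cadence this holds exactly the 24 expected
  readings (00:00 … 05:45); a reading stamped exactly 06:00 belongs to
  the day. Timestamps are naive local time — single-site wearable data,
  no timezone or DST arithmetic.
- Nights with fewer than 20 in-window readings fail QC and are excluded
  from all analyses (exclusions are logged, never silent).
- Hypoglycemia is *strictly* below threshold (< 3.9, < 3.0 mmol/L); a
  reading exactly 3.9 is in range. TIR bounds are inclusive on both ends
  ([3.9, 10.0] mmol/L), following the consensus convention, so
  %time < 3.9 + TIR + %time > 10.0 partitions every night exactly.
- Each reading represents the 15-min interval starting at its
  timestamp: a maximal run of k consecutive below-threshold readings is
  one episode of 15k min, and a single below-threshold reading already
  meets the ≥ 15 min definition. "Consecutive" requires nominal cadence
  adjacency — a missing expected reading breaks the run, because
  interpolating across a gap would invent unobserved hypoglycemia.
  Runs are never re-joined across an above-threshold reading.
- An episode truncated by the window boundary still counts if at least
  one in-window reading is below threshold.
- Denominators for mean/TIR/%CV are the observed readings (not the
  expected 24); %CV uses the sample SD (n−1). AUC is the literal sum of
  (threshold − g) × 15 min over below-threshold readings, in
  mmol/L·min.
- A night is level 2 if any reading is < 3.0 mmol/L, level-1-only if it
  has NH < 3.9 but nothing below 3.0. Duration quartile bins are fixed
  at 0 / 1–45 / 46–90 / 91–150 / > 150 min.
- The sleep score reported on morning D is paired with the window
  [00:00, 06:00) of D: "How well did you sleep last night?" refers to
  the night ending that morning.

## The mixed ordinal model

For participant i, night t, sleep score Y ∈ {1..5}:

    P(Y_it ≤ k | x_it, u_i) = logistic(κ_k − x_itᵀβ − u_i),   u_i ~ N(0, σ_u²)

- Sign convention: exp(β) < 1 means lower odds of a *higher* score, so
  a harmful exposure has OR < 1.
- One glycemic exposure per model plus age (years, uncentered) and sex
  (female = 1); exposure ORs are invariant to this coding. Duration
  exposures enter in 15-min steps so the OR reads "per 15 min".
- Estimation maximizes the marginal likelihood
  Π_i ∫ Π_t P(y_it | x_it, u) φ(u; 0, σ_u²) du with adaptive
  Gauss–Hermite quadrature: per group, the integrand's mode and
  curvature are found by Newton iterations and the nodes are centered
  and scaled there. Default 15 nodes; 1 node is the Laplace
  approximation. On the test fixtures, doubling nodes changes the
  log-likelihood by < 1e-6 relative, which is why the replicate studies
  (below) run at 7 nodes.
- Identifiability: no free intercept — the K−1 cutpoints absorb it.
  The optimizer works on (β, κ_1, log cutpoint increments, log σ_u)
  with L-BFGS-B (log σ_u bounded in [−6, 2]); the analytic gradient
  holds the adaptive centering fixed, which is exact to quadrature
  accuracy because the integral is stationary in its centering.
- Standard errors come from the observed information: a
  central-difference Hessian of the negative log-likelihood at the
  optimum, pushed through the reparameterization jacobian. CIs are Wald
  (±1.96 SE) on the log-odds scale; no profile likelihood.
- Non-convergence is flagged on the fitted object and warned, never
  silent; OR extraction refuses unconverged fits. A constant exposure
  column (e.g. no NH nights in a cohort) is a precondition error, and
  the pipeline skips such exposures with an explicit note.
- Cross-checks: no established mixed-ordinal implementation is
  available as a dependency, so `cross_check` validates the fixed-effects
  machinery against statsmodels' `OrderedModel` (same cumulative-logit
  parameterization), the integration against dense trapezoid
  quadrature at the fitted parameters, and the stationarity of the
  stored optimum via the numerical score. The test suite additionally
  verifies the saturated intercept-only case against closed-form
  empirical cumulative logits.

## Descriptive comparisons

Continuous metrics across level-1-only vs level-2 nights use an
independent-samples t test when every stratum passes Shapiro–Wilk at
α = 0.05, otherwise Kruskal–Wallis; the gate decision is recorded on
each result. Episode-frequency proportions (1 vs ≥ 2 per night) use the
chi-squared test without continuity correction. Gold score vs NH
parameters uses Spearman's rank correlation across nights; constant
inputs are reported as undefined rather than dropped. No
multiple-testing correction is applied; two-sided p < 0.05 is the
nominal convention. Strata with n < 2 are skipped with a warning.

## LOWESS and inflection detection

The smoother is the standard single-pass locally weighted running line:
at each observed x, a degree-1 WLS fit over the nearest ⌈frac·n⌉
neighbours with tricube weights, evaluated pointwise (it matches
statsmodels' `lowess(..., it=0)` to machine precision, which the tests
assert). Default frac = 0.8; no robustness iterations. Local-linear
fits are exact on lines, so a linear signal is reproduced to rounding.

Inflections are local extrema of the fitted curve — sign changes of the
successive first-difference slopes. Two suppressions make this robust:
a curve whose slope never reaches the noise floor (default 1e-3 score
units per mmol/L) is treated as flat, and each extremum must have a
topographic prominence of at least 2% of the fitted range (a
pointwise-evaluated smoother wiggles slightly near a flat crest even on
noiseless data; the prominence filter merges that cluster into the one
underlying turn). Both tolerances are configurable.

## Sensor accuracy

- Each capillary reading pairs with its nearest-in-time sensor reading;
  pairs more than 3 min apart are discarded; a sensor reading may serve
  several capillary readings; exact time ties go to the earlier sensor
  reading. Only device-downloaded capillary readings should enter (the
  file format carries no manual entries).
- MARD = mean |capillary − sensor| / capillary × 100 — asymmetric by
  construction, the capillary value is the reference.
- Grids work in mg/dL via the fixed factor 18.016 (molar mass of
  glucose). Clarke zones follow the canonical published rules in the
  order A, E, C, D, else B, with zone A's 20% boundaries inclusive so
  boundary points take the favorable zone. The Parkes type-1 grid is a
  point-in-polygon test (shapely) against the published consensus
  boundary coordinates, with zones nested A ⊂ B ⊂ C ⊂ D ⊂ E over the
  0–550 mg/dL square and polygon boundaries belonging to the inner
  (better) zone; values beyond 550 mg/dL are clamped to the grid edge.

## The synthetic cohort generator

The generator emulates the four study inputs with known ground truth;
its defaults are the documented study-scale conditions:

- **Cohort**: 27 participants × 28 nights. Ages ~ N(30.6, 8.7²) rounded
  and clipped to 18–65; two-thirds female; Gold ~ N(2.1, 0.9²) clipped
  to 1–7; ~70% DAFNE 1 / 30% DAFNE 2; pump vs MDI roughly even.
- **Glucose**: participant baseline ~ N(8.3, 1.0²) mmol/L; within a
  night, AR(1) noise (ρ = 0.7, innovation SD 0.55) around the baseline;
  values clipped to the sensor span [1.1, 27.8]. Sensor quantization to
  0.1 mmol/L is not emulated.
- **Hypoglycemia injection**: a night is selected with probability
  0.24. A selected night gets a flat-bottomed excursion: half-cosine
  entry/exit ramps around a plateau held within 0.2 mmol/L of the drawn
  nadir. Plateau length ~ round(LogNormal(log 6.5, 0.65)) steps clipped
  to [1, 20]; nadir ~ N(3.2, 0.45²) truncated to [2.0, 3.8] mmol/L.
  With 8% probability a second, shorter excursion is placed with a
  ≥ 2-step recovery gap. These choices put the realized NH night rate
  at ~24%, the level-2 share of NH nights near 35–40%, measured
  duration quartiles near 60/105/160 min, and ~8% two-episode nights.
  Nadir and duration are drawn independently, so the generator does not
  reproduce a depth–duration correlation.
- **Sleep scores**: drawn from the same proportional-odds model the
  analysis fits. Night covariates are computed by calling the metrics
  module on the generated night — generator and analyzer share one set
  of definitions by construction. Defaults: presence effect
  log(0.49), age −0.02/yr, female +0.2, cutpoints
  (−3.7, −2.4, −0.7, 1.45) (no-NH mean score ≈ 3.5), σ_u = 0.8.
- **Capillary pairs**: 518 sensor readings sampled without replacement;
  capillary = sensor / (1 + e) with e ~ N(0, s), s = (MARD%/100)/√(2/π)
  so E|e| equals the 13.6% target exactly (|capillary − sensor| /
  capillary = |e|); timestamps offset uniformly within ±3 min.
- **Determinism**: one integer seed; participants, glucose, sleep and
  capillary streams are independent named substreams, so redrawing
  sleep scores under a different effect vector reuses bit-identical
  glucose.

What the generator does *not* emulate: daytime glucose, meal/insulin
physiology, missing diary entries or sensor dropout (both available as
QC paths but off by default), depth–duration dependence, and the
behavioral confounders (alcohol, exercise, weekday effects) that the
design cannot measure. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated generative
model, not robustness to real-data artifacts.

## Replicate studies and problem sizes

- **OR recovery**: for each reported exposure (presence, episodes,
  duration per 15 min of NH < 3.9; nocturnal mean glucose), 200 cohorts
  at 27 × 28 are generated with the published adjusted OR as the
  generative effect and refitted with exposure + age + sex. The mean
  recovered OR sits within a few thousandths of the generative value
  (e.g. 0.497 vs 0.49 for presence at seed 1). Fits use 7-node adaptive
  quadrature — indistinguishable from 15 nodes at these data sizes (see
  above) — and skip SE computation where only point estimates are
  needed.
- **Null calibration**: with all sleep effects zero, the 95% Wald CI
  for the presence OR covers 1.0 in 90–99% of 200 replicates.
- Convergence tolerances: L-BFGS-B with relative loglik change ≤ 1e-10
  and projected gradient ≤ 1e-5; mode-finding Newton to |score| < 1e-10
  with step clipping at ±4.

## Known limitations

- The random intercept is the only random effect: no random slopes,
  no non-proportional odds, no Bayesian alternative.
- Wald intervals can undercover for σ_u near zero (boundary); the
  exposure ORs, which the analysis reports, are insensitive to this.
- The Clarke C/D/E boundary segments follow the canonical inequality
  directions rather than a strict better-zone tie rule (the zone
  predicates overlap in the published definition; see the `clarke_zone`
  docstring).
- LOWESS inflection x-positions are grid-limited: an extremum is
  located at an observed x value, so precision is one grid step.
- The episode definition is cadence-bound (15-min Libre-style
  exports); other sensors would need the cadence constant adjusted.
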