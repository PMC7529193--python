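# Methods

## Measure-valued records

A sample measurement is a finitely supported probability measure on the
real line (`DiscreteMeasure`): strictly increasing support, positive
probabilities summing to one. Zero-probability atoms are dropped at
construction, so every measure is canonical and `Ber(1)` *is* the point
mass at 1; probabilities whose sum is within 1e-9 of one are renormalized
(tolerant of hand-entered decimals), anything further off is rejected.
Support values are compared exactly after float parsing — there is no
fuzzy merging of nearby support points. Bare numerals in data files parse
as point masses, so any classical numeric dataset is a valid measure-valued
dataset unchanged; this mirrors the framework's reduction to ordinary
likelihood-based inference when every record is a point mass.

Information content of a measure at the true value is −log μ({y}) in nats
(the KL divergence from the measure to the point mass at the truth); a
measure assigning zero mass to the truth raises an infinite-divergence
error, since such a protocol has excluded the actual outcome.

A `ProtocolSample` treats its records as mutually independent
measurements. That independence is a modelling contract — nothing in the
data can verify it — and everything downstream (the count convolution, the
completion weights) relies on it. Support-within-range is validated only
when a range for Y is declared, since real datasets rarely declare one.

## Success-count measure and the conjugate posterior

For Bernoulli-valued records with confidences θ₁…θₙ, the success count W
has the Poisson-binomial distribution, computed by O(n²) iterative
convolution. This is exact to floating precision and entirely adequate at
desk scale (n ≲ 10⁴, where a full convolution takes milliseconds); beyond
that a characteristic-function method would be the natural swap, which is
why the routine is isolated behind `success_count_distribution`. Records
with mass outside {0, 1} are rejected rather than coerced: a binary trait
cannot charge other outcomes.

The posterior for the population proportion under a Beta(α, β) prior is
the ν-weighted Beta mixture. Its mean uses the closed form
(α + E_ν W)/(α + β + n); its variance uses the law of total variance over
the *exact* pmf of W,

    Var = E_ν[(α+W)(β+n−W)] / ((α+β+n)²(α+β+n+1)) + Var_ν(W)/(α+β+n)²,

rather than any further algebraic simplification — the decomposition is
unambiguous, and an independent mixture-moment code path
(`mixture_mean`/`mixture_var`) must agree with it to 1e-12 in the tests.
Equal-tailed credible intervals invert the mixture CDF (a weighted sum of
regularized incomplete Beta functions) by bisection to below 1e-10.
The default prior is Beta(1, 1); the worked survey uses Beta(15, 15)
explicitly wherever it appears.

## Calibration diagnostics

Records are grouped by exact measure equality (keys rounded at 1e-12).
Exact equality is the definitionally correct grouping; for sparse real
data an optional bin width merges near-identical Bernoulli confidences
(the group's reference measure is then the bin-average confidence), and
reports produced that way are flagged `binned`. Each group's discrepancy
is |measure expectation − mean of truths|; binary groups get an exact
two-sided binomial test, with Holm-adjusted p-values reported alongside
the raw ones. The library deliberately makes no accept/reject decision:
no finite-sample threshold for "calibrated" is hard-coded, because none is
canonical — the report is the deliverable.

## Regression by posterior mixing over completions

A completion replaces every measure cell (response, and covariate cells if
any are measures) with one of its support points; its weight is the
product of the chosen atoms' probabilities. The generalized posterior is
the weight-averaged collection of complete-data posteriors, and pooling is
by draw concatenation — the mixture *is* the posterior, so no
moment-matching or Rubin-style combining rules are used.

- Exact mode enumerates completions (feasibility cap 4,096) and allocates
  the kept-draw budget across completions by largest-remainder rounding of
  the weights.
- MC mode draws K completions from the product measure, merges duplicates,
  and allocates by empirical frequency; merging makes K in the thousands
  cheap when only a handful of distinct completions exist.

Each completion is fit with a self-contained adaptive random-walk
Metropolis sampler: proposals are centred with a BFGS mode-finding step and
scaled by the inverse Hessian, the global step size adapts toward ~30%
acceptance during warmup, and split-Rhat is computed per parameter (a
floor of 400 kept draws per chain keeps the diagnostic meaningful even for
small allocations). Defaults are 4 chains × 2,500 kept after 2,500 warmup;
completions exceeding Rhat 1.05 are flagged and warned about, never
silently dropped or repaired. A `sampler` hook accepts any callable with
the same signature, so an external sampler can be plugged in.

Priors default to Normal(0, 10) on the intercept, Normal(0, 2.5) on
slopes, and — for the linear family, where a residual scale is needed and
no standard choice is implied by the binary-trait development — a weakly
informative half-Normal(0, 10) on σ, sampled on the log scale with the
Jacobian included. Logistic responses realized from Bernoulli measure
cells are the response itself; measure-valued covariates are completed
identically (a documented extension beyond the response-only case the
worked examples exercise).

## Synthetic data

`generate_birds` emulates the banding survey: 76% adults; 50% of adults
and 75% of juveniles female; two-thirds of juveniles only partially
sexable. Its partial mechanism draws the confidence first (Beta with mean
equal to the stratum female probability) and the true sex from that
confidence, which makes the protocol calibrated *by construction* — the
calibration tests on generator output therefore validate the diagnostic
machinery, not the generator. The Beta concentration defaults to 5, giving
a realistic confidence spread (roughly 0.2–1.0) comparable to the fixed
survey's printed confidences. Weight and wing-chord strata are Normal with
the second parameter read as a **standard deviation** (the convention of
the R ecosystem the survey's analysis came from): adult females N(50, 5) g,
adult males N(60, 5); definitively sexed juveniles N(30, 5) (F) / N(40, 5)
(M); partially sexed juveniles N(20, 5) (F) / N(30, 5) (M) — underweight
juveniles are harder to sex, which is the confounding the regression
examples exploit; wing chord N(11, 1) cm except juvenile males at N(8, 1).

`paper_bird_fixture` is the fixed 50-bird survey: all marginal counts, the
eight partial confidences, and their true sexes are canonical, as are the
weights and wing chords of the 17 published rows; the remaining 33 adult
rows' weights and wing chords are synthetic fills from the stratum
distributions under a fixed internal seed (they affect only the regression
illustrations, never the proportion-female results).

`generate_ratings` emulates per-item categorical confidence vectors for a
17-item, 0–4 rating scale: a patient-level latent severity in (0, 1) sets
a modal category per item (Binomial(4, severity)) and the confidence
vector is Dirichlet around that mode; infinite concentration recovers the
classical single-score protocol exactly. The published eight-patient
item-1 table ships verbatim as `hamd_item1_fixture`. What the generators
do **not** emulate: assessor-to-assessor heterogeneity, item correlation
beyond the shared severity, miscalibrated experts (available only through
the explicit `miscalibration` shift in the study harness), and
non-independent measurement protocols — so passing tests say nothing about
data violating those assumptions.

## Simulation studies and problem sizes

The weak-law study verifies vanishing bias of the generalized mean and of
the conjugate estimator on calibrated protocols across n ∈ {50, 200, 800}
(200 replications; Monte-Carlo error bars as sd/√reps, assertions at 3–4
standard errors), and detects the bias ≈ shift × nontrivial-fraction
introduced by a constructed miscalibration. The consistency study compares
m₂ = ⌈√m₁⌉ against m₂ = m₁ over m₁ ∈ {100, 400, 1600} (60 replications).
GLM checks run at n = 60–150 with 2 chains × 600 kept draws, against a
dense-grid quadrature oracle for the two-parameter logistic case; these
sizes give comfortable margins for every assertion while keeping the whole
suite under a minute.

One theoretical point surfaced by the consistency study deserves record:
for an *independent* protocol, Var_ν(W) = Σθᵢ(1−θᵢ) ≤ n/4 grows at most
linearly, so both posterior-variance terms are O(1/n) and the posterior sd
vanishes like 1/√n even when uncertain records grow proportionally with
maximum-entropy confidences (measured: mean sd 0.0429 → 0.0216 → 0.0108
across the grid above). A genuinely non-vanishing posterior spread
requires a count variance of order n², attainable only by dependent
(non-product) joint measurement measures, which this package deliberately
does not model. What independence does preserve — and the tests assert —
is that the mixed protocol's posterior sd strictly exceeds the all-trivial
posterior sd at matched n: partial information always costs precision,
even though it no longer blocks concentration.

## Known limitations

- Discrete, finitely supported measures only; continuous-support
  measurements are out of scope.
- Independent measurement protocols only; no dependent joint measures, and
  hence (see above) no inconsistency regime.
- No recalibration of miscalibrated protocols and no hierarchical
  assessor models; the calibration module diagnoses, it does not repair.
- Conjugate machinery covers the Bernoulli case; other families go through
  the completion-pooled GLM path with its MCMC cost.
- The categorical (multi-category count) generalization of ν is not
  implemented.
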