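# Methods

## Estimands and point estimation

For a cohort 2×2 table (TP=a, FP=b, FN=c, TN=d) the post-test
probabilities are PPV = a/(a+b) and NPV = d/(c+d). In a nested
case–control sample all cases are retained and a random subset of the
controls receives the index test (b₁ test-positive, d₁ test-negative
sampled controls, sampling fraction sf = (b₁+d₁)/(b+d)). The corrected
estimators

PPV = a/(a + b₁/sf),  NPV = (d₁/sf)/(c + d₁/sf)

are exact algebraic rearrangements of the Bayes expressions in
(Se, Sp, p) with Se = a/(a+c), Sp = d₁/(b₁+d₁) and p the cohort
prevalence; the package computes both targets through a single code path
(swap a↔d₁, b₁↔c, inflate the control cell by 1/sf) so the two formulas
cannot drift apart. Counts are validated as non-negative integers;
weighted intermediates are real-valued. Degenerate denominators raise a
typed error; an opt-in Haldane–Anscombe correction adds 0.5 to the four
nested counts while keeping sf at its design value (sf is a property of
the sampling design, not of the realized counts).

## The six interval constructions

With z the normal quantile for the chosen level (never hard-coded):

1. **Naive Wald.** SE = √(p̂(1−p̂)/n) with the *uncorrected* observed
   proportion p̂ (a/(a+b₁) for the PPV) and observed denominator n. The
   interval is centred on the corrected point estimate: the point estimate
   is common to all approaches by construction, and only the SE uses the
   uncorrected proportion.
2. **Corrected Wald.** Same n, but the corrected value in the variance
   numerator.
3. **Stratified percentile bootstrap.** Cases are resampled with
   replacement within cases and sampled controls within controls (margins
   and sf are design constants), the corrected estimate recomputed per
   replicate, and the empirical (1±level)/2 quantiles taken with numpy's
   linear interpolation between order statistics (the convention is fixed
   and documented; nothing in the method pins it down). Replicates with an
   empty denominator are continuity-corrected in place and tallied. In
   rare tiny-count configurations a percentile interval need not bracket
   the observed statistic; endpoints are widened to include it so the
   ordering invariant lower ≤ estimate ≤ upper always holds.
4. **Delta method, probability scale.** Treating p as known and Se, Sp as
   independent binomial proportions on n₁ = a+c cases and n₀ = b₁+d₁
   controls,
   Var(PPV) = p²(1−p)²[(1−Sp)²Se(1−Se)/n₁ + Se²Sp(1−Sp)/n₀]/D⁴,
   D = Se·p + (1−Sp)(1−p), and the NPV analogue with
   E = Sp(1−p) + (1−Se)p. The implementation uses the full delta-method
   derivation (squares on every partial-derivative factor) and is
   cross-checked in the tests against numerical differentiation of the
   Bayes formula.
5. **Weighted logistic regression.** logit P(disease|x) = α + βx with
   x = 1 for a positive test; each case weighs N₁/N, each sampled control
   (N₁/N)/sf, so the weights sum to the nested sample size N₁ (the
   effective sample size of the covariance). Var(logit PPV) =
   var(α) + var(β) + 2cov(α, β); logit NPV = −α so its SE is √var(α). The
   interval is formed on the logit scale and back-transformed — the method
   description stops at the logit SE, and the logit-Wald construction is
   the one that uses that SE directly while keeping bounds inside (0, 1).
6. **Delta method, logit scale.**
   Var(logit PPV) = (1−Se)/(Se·n₁) + Sp/((1−Sp)·n₀),
   Var(logit NPV) = Se/((1−Se)·n₁) + (1−Sp)/(Sp·n₀), back-transformed.

Probability-scale Wald intervals are truncated to [0, 1] and flagged.
Approaches 4 and 6 require Se, Sp strictly inside (0, 1) and raise a
boundary error otherwise (or accept the continuity correction).

Note that approaches 5 and 6 do **not** share a variance: approach 5's
model-based Var(logit PPV) is 1/(w_case·a) + 1/(w_ctrl·b₁) (test-result
margins fixed), while approach 6 conditions on the case/control margins
and treats p as known; at sf = 1 they differ by exactly
1/(a+c) + 1/(b₁+d₁). This is why they behave differently in the coverage
study (5 over-covers, 6 under-covers).

## Weighted GLM fitting

The fit operates on the grouped 2×2 representation (four weighted binomial
rows — identical likelihood to per-subject rows, O(1) per iteration) by
damped Newton–Raphson: full Newton steps with step-halving until the
weighted log-likelihood ascends, which is always possible because the
likelihood is concave. Start values: α at the logit of the weighted
overall disease proportion, β = 0. Convergence: gradient max-norm < 1e−8
or relative log-likelihood change < 1e−10, within 50 iterations; the
iteration trace is carried on the convergence error. A zero cell raises a
separation error (the saturated MLE is on the boundary). The covariance is
the inverse *expected* (= observed, for the canonical link) weighted
Fisher information at the optimum — a model-based covariance, no
sandwich correction. Because the model is saturated, the fitted
probabilities equal the weighted cell proportions exactly; this identity
(to 1e−8 over 1000 random tables) is the module's primary oracle, with
statsmodels' freq-weighted GLM and a derivative-free likelihood search as
independent cross-checks.

## Simulation design

A **source population** is reconstructed from (p, Se, Sp, N):
cases = round(p·N), TP = round(Se·cases), TN = round(Sp·controls)
(round-half-even on the float product), remaining cells by subtraction;
the realized parameters must round-trip the stated ones at 2 decimals.
The built-in catalogue covers the D-dimer and calf-circumference-
difference tests at prevalences 0.05/0.1/0.2 with N = 1400 (e.g. the
prevalence-0.1 D-dimer population is 140 cases, TP=136, TN=416, giving
PPV 0.14 and NPV 0.99).

Each replicate then:

1. draws a cohort of N = 1400 with replacement from the source population
   (one multinomial draw), so cohort prevalence varies (SD ≈ 0.008 at
   p = 0.1);
2. keeps all cohort cases and draws ratio·cases controls from the cohort
   control pool. By default controls are drawn **with replacement**,
   capped at the pool size. This choice is deliberate: it keeps the
   1:4-ratio design feasible at prevalence 0.2 (where the requested
   controls exceed the pool in about half the cohorts, and redrawing those
   cohorts would condition the prevalence distribution heavily), and the
   extra control-sampling variance it induces — Sp noise of order
   Sp(1−Sp)(1/pool + 1/n₀) rather than the delta-method's assumed
   Sp(1−Sp)/n₀ — is what produces the documented degradation of the
   delta-method approaches as ratio and prevalence grow. A
   without-replacement (hypergeometric) mode is available
   (`replace=False`) and is validated against the exact hypergeometric
   law; under it every approach with a correct within-sample variance
   covers near-nominally and the ratio effect disappears.
3. evaluates every requested approach on the nested sample at the
   *realized* cohort prevalence and scores it against the truth.

**Truth policy.** The default truth is the predictive value implied by the
source population's (prevalence-invariant) Se and Sp at the replicate's
realized cohort prevalence. Rationale: once the cohort is drawn, its
prevalence is a known design quantity used by every estimator, and none
of the six variance formulas contains a term for cohort-level prevalence
noise; scoring against the fixed source value (`truth_policy="source"`)
charges all approaches for that common noise (dPPV/dp ≈ 1.3 at these
operating points) and drives even a correctly specified full-cohort Wald
interval far below nominal whenever prevalence information is recycled
into the estimate. The fixed-source policy remains available and is used
in the test suite for the sf=1 binomial Wald sanity check, where the
estimator does not use prevalence.

Bookkeeping: cohorts with no cases (or too few controls in
without-replacement mode) are redrawn with a logged counter, keeping
exactly B usable replicates. Replicates an approach cannot process
(boundary Se/Sp for 4/6, a zero cell for 5) are excluded *for that
approach only* and tallied per approach, so coverage denominators are
explicit. One RNG stream per replicate (plus a separate bootstrap stream)
is spawned from the root seed, so results are bit-reproducible and
independent of which approaches are requested.

The acceptability band for empirical coverage is
level ± 2·√(level(1−level)/B) — (0.936, 0.964) for a 95% level at
B = 1000, with Monte-Carlo SE 0.0069.

## Problem sizes and defaults

Defaults mirror the study conditions: B = 1000 replicates, 1000 bootstrap
resamples, 95% level, N = 1400 cohorts, ratios 1–4. The package's own
acceptance tests run the qualitative coverage reproduction at B = 500 with
500 bootstrap resamples (four design cells, about two seconds in total),
which keeps Monte-Carlo SE ≈ 0.011 — small enough to separate the
documented over-/under-coverage patterns from the nominal band. The
delta-method coverage summary in `scripts/acceptance.py` uses B = 1000 and
no bootstrap (only approaches 4 and 6 are involved).

## What the generator does and does not emulate

The simulation reproduces the two-stage sampling noise (cohort draw plus
control subsampling) for a dichotomous test with known reference
classification. It does not model covariate-dependent test performance,
verification bias, imperfect reference standards, matched or stratified
control sampling, or continuous markers with threshold choice — passing
coverage here says nothing about those complications. The DVT populations
are reconstructions from rounded published accuracy values, not the
original patient records; quantities that depend on unrounded cell counts
(e.g. the diagnostic odds ratios, or the original cohort's exact
positive-test counts) are deliberately not reproduced.

## Known limitations

- The weighted GLM supports exactly one binary covariate (the index
  test); general design matrices and sandwich covariances are out of
  scope.
- Wilson, Clopper–Pearson and Bayesian intervals are not implemented;
  the six constructions above are the package's subject matter.
- Exact coverage/width values from the published figures are readable
  only from plots; the package reproduces the qualitative ordering and
  the numerically stated ranges, not per-point figure values.
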