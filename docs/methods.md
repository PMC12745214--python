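# Methods

## The instrument and its summaries

The instrument scores 20 ICF categories, each on a 0–10 numerical rating
scale (0 = no problem, 10 = complete dysfunction); the total disability
score is the plain sum, 0–200. Items partition into three functional areas
(self-care & activities: 11, cognition & perception: 5, emotion & spirit: 4)
and four items (b130 energy/drive, b134 sleep, b152 emotional functions,
b280 pain) are self-reported rather than observer-rated.

Item-level cohort summaries follow these conventions, chosen because they
make the percentage columns of the reference item table internally
consistent (the source never states them explicitly):

* **dysfunction** = admission score > 0 (0 means "no problem at all");
* **improvement** = endpoint score strictly below admission score; ties
  count as no improvement;
* the **percentage improved** divides by the number dysfunctional, not the
  cohort size;
* admission/discharge **means are over all patients** (not only the
  dysfunctional ones), and the improvement rate is the mean improvement as
  a percentage of the mean admission score;
* the **endpoint** is each patient's last available assessment, whatever
  the discharge reason (discharge, referral, death, end of study are a
  single endpoint notion here; the pipeline surfaces no distinction).

## The trajectory model

**Model.** A K-group finite mixture for the longitudinal total score.
Conditional on group k, observations at rescaled times t = day/100 are
independent draws from a normal around the group polynomial (default order
2), censored to the instrument scale: interior values carry the normal
density, values at 0 or 200 the corresponding tail mass (CNORM). The
time rescaling conditions the optimisation; coefficients are reported on
both the rescaled and the raw day scale. σ is shared across groups by
default (per-group σ behind a flag). Censoring bounds default to the scale
ends (0, 200); infinite bounds turn the model into an ordinary normal
mixture.

**Estimation.** Multi-start EM. The E-step computes patient-level group
posteriors; the M-step updates p_k as mean posteriors and maximises the
posterior-weighted censored-normal regression over (β, log σ) by L-BFGS
with analytic gradients, warm-started at the current parameters; a step
that would decrease the weighted objective is rejected, so the EM
log-likelihood is monotone (asserted in tests at every iteration).
Initialisation: a quantile split of patient mean scores into K blocks (per
block OLS), plus seeded random perturbations for the remaining starts.
Convergence: relative log-likelihood change < 1e-8 or 500 EM iterations.
log σ is bounded in [log 0.01, log 1000] so noise-free data cannot
degenerate. After fitting, groups are relabelled by ascending day-0 mean,
making "group 1 = mildest" deterministic under label switching; assignment
ties break toward the lower group index.

**Selection.** For each candidate K: admissible ⇔ every group's AvePP
(mean posterior probability of assignment among its assigned members)
exceeds 0.7 and every group holds ≥ 5% of patients. Among admissible
candidates the BIC closest to zero wins; BIC = loglik − ½·k·ln(n_subjects)
(subject count, not observation count — both are recorded in the model
dump). With no admissible candidate the best-BIC fit is returned flagged
inadmissible. Free parameters counted: (K−1) shares + Σ(order_k+1)
coefficients + 1 shared σ.

## The synthetic cohort

The generator emulates the reference study population; its defaults are the
study conditions, fixed once:

* **Groups**: shares (17, 34, 26, 18)/95. Mean curves are the exact
  quadratics through three narrative anchors per group — (0 d, 25) → (34 d,
  18) → (68 d, 12); (0, 61) → (60, 40) → (93, 35); (0, 88) → (100, 58) →
  (280, 40); (0, 116) → (120, 82) → (210, 72) — and plateau beyond the last
  anchor (or the quadratic's minimum if that comes first), emulating the
  late recovery plateau.
* **Noise**: residual SD 12 points on the total-score scale, the order of
  the reference within-group admission SDs (12.4–14.6); totals are censored
  to [0, 200] and rounded to integers.
* **Visits** every 14 days from day 0 up to the length of stay. LOS is
  log-normal matched to the per-group means/SDs (31.9±18.1, 49.4±27.6,
  87.6±74.0, 88.9±49.4 days), truncated at ≥ 14 days (so every patient has
  ≥ 2 assessments, the study's inclusion criterion) and capped at 420 days.
* **Item scores** are apportioned from the total by largest-remainder
  allocation over fixed item weights (proportional to the reference
  admission item means), clamped to 0–10 with greedy redistribution, so
  totals are preserved exactly while the instrument layer is exercised.
* **Covariates**: per-group Bernoulli/categorical probabilities equal to
  the reference cohort frequencies (dysphagia, cognitive impairment,
  assistive-device need, urine bag/diaper, education, diagnosis, …); age
  and admission Barthel index normal per group; disease course log-normal
  around per-group medians. Covariates are **independent given group** —
  only marginal frequencies are published, so no within-group dependence is
  modelled.
* **Costs** = LOS × per-group daily cost (484.73, 531.28, 546.12, 633.53)
  × log-normal noise (sd 0.3 on the log scale, unit mean).
* **Seeding**: one root seed; each patient gets a deterministically spawned
  sub-stream, so cohorts are byte-for-byte reproducible and stable under
  partial regeneration.

What the generator does **not** emulate: referral/death processes, seasonal
admission effects, item-level longitudinal correlation beyond the shared
total, covariate dependence within group, and any direct coupling between
covariates and the score trajectory beyond group membership. Passing
recovery tests on these cohorts shows the estimator recovers the generative
structure it assumes — not that real rehabilitation data satisfy that
structure.

## Group comparisons

Univariate: one-way ANOVA for age-like continuous covariates,
Kruskal–Wallis (midrank tie correction) for skewed ones, and for
categorical covariates Pearson χ² — switching to the exact conditional
test when any expected cell is below 5 (configurable). The exact r×c test
enumerates all tables with the observed margins (probabilities are
multivariate hypergeometric; the two-sided p sums tables no more probable
than the observed, with a 1e-10 relative tolerance on the probability
comparison) under a configurable table budget; beyond it, a seeded
Monte-Carlo mode samples margin-fixed tables (Patefield's algorithm) and
reports the add-one estimate with its standard error. All p-values are
two-sided.

Multivariate: cumulative-logit proportional-odds regression
(P(Y ≤ j) = logit⁻¹(α_j − xβ), maximum likelihood via statsmodels), so a
positive β means greater odds of a more severe trajectory group. Reported
per term: Wald χ² = (β/SE)², OR = exp(β) with Wald 95% CI. Model-level: LR
χ² against the intercept-only model; a parallel-lines test comparing the
proportional-odds fit with an unconstrained cumulative-logit model (one
slope vector per cutpoint, fitted by direct likelihood maximisation with
cell probabilities clipped at 1e-12 — the unconstrained model need not be
coherent for every x, which is precisely what the test probes), df =
(J−2)·p; deviance and Pearson goodness of fit over distinct covariate
patterns (expected counts floored at 1e-10). Quasi-separation — diverging
coefficients on sparse cells — is detected (|β| > 15 on the logit scale or
exploding SE), the reported coefficient capped at ±15 and the term flagged;
sparse reference cohorts genuinely produce such terms, and a capped,
flagged estimate is more honest than either a failure or an astronomically
large "odds ratio".

With a 4-level outcome the model has 3 thresholds; all three are reported.
A published single "intercept" row cannot be mapped onto one specific
threshold and is not matched.

## Cost-effectiveness indices

All indices are ratios of group **means** — daily cost = mean cost / mean
LOS, effect index = 100 × mean improvement / mean admission, efficiency
index = effect / mean LOS, benefit index = mean cost / mean improvement —
because this convention reproduces the self-consistent published index
cells; means of per-patient ratios are available behind a flag for
sensitivity analysis. Zero improvement makes the benefit index undefined
(NaN with a warning); currency units are opaque.

## Numerical and design notes

* BIC uses the subject count; the "closer to zero" reading applies to its
  negative values.
* The sample-size helper implements the subjects-per-variable rule
  floor(n_vars × multiplier / (1 − dropout)); with 17 variables, 5–10× and
  10% dropout it gives 94–188.
* Analysis drivers use a 95-patient cohort (the study's size); recovery
  and selection properties are tested at n = 1000, where group shares are
  recovered within 4 percentage points and day-0 means within 5 points
  over 5 seeds, and the selection rule picks K = 4 in ≥ 8 of 10 seeds with
  candidates K ∈ {2, 3, 4, 5}, 2 starts each. Ordinal-regression recovery
  uses 100 simulations at n = 2000 (pooled 2-SE coverage ≥ 95%).
* The exact-test enumeration is validated against R's `fisher.test` values
  (frozen as oracles) and its own total-mass identity; published starred
  p-values were printed at a precision/convention that does not match exact
  enumeration and are not used as anchors.

## Known limitations

* No covariate-dependent group membership inside the GBTM (group
  probabilities are marginal); no dropout/informative-missingness
  modelling; no bootstrap CIs for trajectory parameters.
* The generator's item-allocation scheme induces deterministic item
  profiles given the total; item-level variances are therefore understated
  relative to real cohorts.
* Small-cohort (n = 95) runs can legitimately select K ≠ 4 or flag
  separation in the ordinal model; the drivers report whatever the rules
  produce.
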