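# icftraj

Trajectory and cost-effectiveness analysis of ICF disability scores in
inpatient stroke rehabilitation.

## The problem

Stroke inpatients enter rehabilitation with very different levels of
functional impairment and recover at very different rates. This package
implements an analysis chain built around a 20-item disability instrument
based on the WHO International Classification of Functioning, Disability and
Health (ICF): each item is scored on a 0–10 numerical rating scale (0 = no
problem, 10 = complete dysfunction), giving a total disability score on
0–200 that is re-assessed every two weeks during the hospital stay. The
questions the chain answers:

1. Which items are impaired at admission, and which improve? (item-level
   dysfunction/improvement summary)
2. Do patients fall into latent subgroups with distinct recovery
   trajectories? (group-based trajectory modelling, GBTM)
3. Which admission characteristics predict membership in a more severe
   trajectory? (univariate tests + proportional-odds ordinal regression)
4. How does the cost-effectiveness of rehabilitation differ across
   trajectory groups? (effect / efficiency / benefit indices)

Because the motivating study's patient-level data are not deposited, the
package ships a synthetic-cohort generator (`icftraj.simulate`) whose
defaults emulate the reference cohort: four trajectory groups with admission
means near 25, 61, 88 and 116 points, group shares 17/34/26/18 of 95,
group-conditional covariates, lengths of stay and treatment costs.

## The model

The core is a **censored-normal (CNORM) group-based trajectory model**: a
K-component finite mixture in which patient *i*, if in latent group *k*,
has observed score at rescaled time *t*

> y_it = β_k0 + β_k1 t + β_k2 t² + ε_it,  ε_it ~ N(0, σ²),

censored to the instrument scale [0, 200] — a normal density in the
interior and probability mass at the two scale ends. Parameters (group
probabilities p_k, polynomial coefficients β_k, residual SD σ) are
estimated by multi-start EM with a posterior-weighted censored-normal
regression in the M-step. Model selection over K follows the usual GBTM
admissibility rules: average posterior probability of assignment
(AvePP) > 0.7 in every group, ≥ 5% of patients per group, and among
admissible candidates the BIC (here `loglik − ½·k·ln N`, a negative number)
closest to zero.

Group comparisons use Pearson χ², an exact conditional r×c test (full
network enumeration of tables with fixed margins, or seeded Monte-Carlo),
one-way ANOVA and Kruskal–Wallis; the multivariate stage is a
cumulative-logit proportional-odds model with Wald statistics, odds ratios,
likelihood-ratio and parallel-lines tests, and deviance/Pearson goodness of
fit. Cost-effectiveness indices per group *g* are ratios of group means:
effect index = 100·improvement/admission, efficiency index = effect/LOS,
benefit index = cost/improvement.

## Worked example

The numbered drivers under `analysis/` run the full chain on a simulated
95-patient cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_item_summaries.py
python analysis/03_fit_trajectories.py
python analysis/04_compare_groups.py
python analysis/05_cost_effectiveness.py
```

`03_fit_trajectories.py` prints, for seed 1:

```
chosen model: K=4 (admissible=True), BIC=-2072.7, sigma=11.7
  group 1: share 16.8%, AvePP 0.97, day-0 mean 30.1
  group 2: share 32.6%, AvePP 0.96, day-0 mean 58.2
  group 3: share 31.6%, AvePP 1.00, day-0 mean 88.2
  group 4: share 18.9%, AvePP 1.00, day-0 mean 117.9
```

i.e. the selection rule recovers the four generating trajectories: every
group passes the AvePP > 0.7 and ≥ 5% share criteria, and the fitted day-0
means sit close to the generating admission levels (25/61/88/116; at n = 95
a few points of sampling error are expected). `04_compare_groups.py` then
finds dysphagia, cognitive impairment and urine-bag/diaper use among the
strongest predictors of a more severe trajectory (e.g. dysphagia OR 7.13,
95% CI 2.37–21.40), and `05_cost_effectiveness.py` reports the per-group
indices, with the mildest group improving fastest per day and the most
severe group costing the most per point of improvement.

The same chain is available as a CLI (`icftraj run-all --seed 1 --out out/`)
with subcommands `simulate-cohort`, `summarize-items`, `fit-trajectories`,
`compare-groups`, `cost-effectiveness`, `sample-size`.

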