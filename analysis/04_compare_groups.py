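"""Which admission characteristics separate the trajectory groups?

Runs the univariate comparisons (ANOVA / Kruskal-Wallis / chi-square or
exact test) of every covariate across the fitted trajectory groups, then a
proportional-odds ordinal regression on the univariately significant
variables (plus surgery, kept for clinical relevance), writing
results/table2_univariate.csv and results/table3_ordinal.csv.
"""

from pathlib import Path

import pandas as pd

from icftraj import compare, pipeline

COHORT = Path("results/cohort")
OUT = Path("results")
ALPHA = 0.05
SEED = 1


def main() -> None:
    cov = pd.read_csv(COHORT / "covariates.csv").merge(
        pd.read_csv(OUT / "posteriors.csv")[["patient_id", "group"]], on="patient_id"
    )
    tab = compare.univariate_table(
        cov,
        continuous=list(pipeline.CONTINUOUS_VARS),
        nonnormal=list(pipeline.NONNORMAL_VARS),
        categorical=[v for v in pipeline.CATEGORICAL_VARS if v in cov.columns],
        seed=SEED,
    )
    tab.to_csv(OUT / "table2_univariate.csv", index=False)
    sig = tab.loc[tab["p_value"] <= ALPHA, "variable"].tolist()
    print(f"univariately significant at {ALPHA}: {', '.join(sig) or 'none'}")

    predictors = sig + [v for v in ("surgery",) if v not in sig]
    fit = compare.ordinal_logit_fit(cov, predictors=predictors)
    fit.to_frame().to_csv(OUT / "table3_ordinal.csv", index=False)
    print(f"ordinal model: LR chi2={fit.lr_chi2:.2f} (df={fit.lr_df}, p={fit.lr_p:.2g}); "
          f"parallel-lines chi2={fit.parallel_chi2:.2f} "
          f"(df={fit.parallel_df}, p={fit.parallel_p:.2f})")
    print(f"GOF: deviance p={fit.deviance_p:.2f}, Pearson p={fit.pearson_p:.2f}")
    for t in fit.terms:
        flag = " [capped: separation]" if t.capped else ""
        print(f"  {t.name}: OR {t.odds_ratio:.2f} ({t.ci_low:.2f}-{t.ci_high:.2f}), "
              f"p={t.p_value:.3f}{flag}")
    print(f"wrote {OUT}/table2_univariate.csv, table3_ordinal.csv")


if __name__ == "__main__":
    main()
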