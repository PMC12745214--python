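"""Trajectory-group comparisons: univariate tests and ordinal regression.

Univariate comparisons across the (ordinal) trajectory groups use Pearson's
chi-square for well-filled contingency tables, an exact conditional (Fisher-
type) test for sparse r x c tables, one-way ANOVA for approximately normal
continuous covariates and Kruskal-Wallis otherwise.  The multivariate stage
is a cumulative-logit proportional-odds model of group membership, oriented
so that a positive coefficient means greater odds of a more severe
trajectory, with Wald statistics, odds ratios with Wald CIs, a likelihood-
ratio test against the intercept-only model, a parallel-lines test against
an unconstrained cumulative-logit model, and deviance/Pearson goodness of
fit over distinct covariate patterns.

The exact r x c test enumerates all tables with the observed margins
(conditional multivariate hypergeometric) and sums the probabilities of
tables no more probable than the observed one; a seeded Monte-Carlo mode
covers tables too large to enumerate.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln
from statsmodels.miscmodels.ordinal_model import OrderedModel


class TestKind(enum.Enum):
    PEARSON_CHI2 = "pearson_chi2"
    FISHER_EXACT = "fisher_exact"
    ANOVA_F = "anova_f"
    KRUSKAL_WALLIS = "kruskal_wallis"


@dataclass
class UnivariateResult:
    variable: str
    test: TestKind
    statistic: float  # NaN for exact tests (no statistic is reported)
    df: float
    p_value: float
    mc_se: float = float("nan")  # Monte-Carlo standard error, if applicable
    notes: list[str] = field(default_factory=list)


def _drop_zero_margins(table: np.ndarray, variable: str, notes: list[str]) -> np.ndarray:
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        notes.append(f"{variable}: dropped empty rows/columns before testing")
    return table[rows][:, cols]


def pearson_chi2(table, variable: str = "") -> UnivariateResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0 or t.sum() <= 0:
        raise ValueError("table must be a nonnegative 2-D count table with a positive total")
    notes: list[str] = []
    t = _drop_zero_margins(t, variable, notes)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    res = stats.chi2_contingency(t, correction=False)
    return UnivariateResult(
        variable, TestKind.PEARSON_CHI2, float(res.statistic), float(res.dof),
        float(res.pvalue), notes=notes,
    )


def expected_counts(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


# ---------------------------------------------------------------------------
# Exact conditional r x c test

class EnumerationBudgetError(RuntimeError):
    """Enumeration would exceed the table budget; use monte_carlo mode."""


def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return float(log_const - gammaln(table + 1.0).sum())


def _enumerate_tables(row_sums, col_sums, max_tables):
    """Yield all nonnegative integer tables with the given margins."""
    r = len(row_sums)
    count = 0

    def rec(i, remaining_cols, rows):
        nonlocal count
        if i == r - 1:
            count += 1
            if count > max_tables:
                raise EnumerationBudgetError(
                    f"more than {max_tables} tables; use mode='monte_carlo'"
                )
            yield rows + [tuple(remaining_cols)]
            return
        total = row_sums[i]
        caps = remaining_cols
        for combo in _compositions(total, caps):
            new_cols = tuple(c - v for c, v in zip(caps, combo))
            yield from rec(i + 1, new_cols, rows + [combo])

    yield from rec(0, tuple(col_sums), [])


def _compositions(total, caps):
    """All tuples 0<=x_j<=caps_j with sum == total."""
    c = len(caps)
    if c == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    lo = max(0, total - sum(caps[1:]))
    hi = min(caps[0], total)
    for v in range(lo, hi + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield (v,) + rest


def fisher_exact_rxc(
    table,
    variable: str = "",
    mode: str = "enumerate",
    seed: int | None = None,
    n_draws: int = 100_000,
    max_tables: int = 2_000_000,
) -> UnivariateResult:
    """Exact conditional test of independence for an r x c count table.

    With margins fixed, table probabilities are multivariate hypergeometric:
    ``P(T) = prod(r_i!) prod(c_j!) / (N! prod(a_ij!))``.  The two-sided exact
    p-value sums ``P(T)`` over all tables no more probable than the observed
    one.  ``mode='monte_carlo'`` instead samples tables with the observed
    margins (Patefield's algorithm via scipy) and reports the add-one
    estimate with its standard error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0 or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a nonnegative integer 2-D table")
    notes: list[str] = []
    t = _drop_zero_margins(t, variable, notes).astype(int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    log_const = float(
        gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum() - gammaln(n + 1.0)
    )
    logp_obs = _log_table_prob(t, log_const)
    df = float((t.shape[0] - 1) * (t.shape[1] - 1))

    if mode == "enumerate":
        p = 0.0
        for tab in _enumerate_tables(tuple(row_sums), tuple(col_sums), max_tables):
            lp = _log_table_prob(np.asarray(tab, dtype=float), log_const)
            if lp <= logp_obs + 1e-10:
                p += float(np.exp(lp))
        return UnivariateResult(
            variable, TestKind.FISHER_EXACT, float("nan"), df, min(p, 1.0), notes=notes
        )
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        dist = stats.random_table(row_sums, col_sums)
        draws = dist.rvs(n_draws, random_state=rng)
        lps = log_const - gammaln(draws + 1.0).sum(axis=(1, 2))
        hits = int(np.sum(lps <= logp_obs + 1e-10))
        p = (hits + 1) / (n_draws + 1)
        se = float(np.sqrt(p * (1 - p) / n_draws))
        return UnivariateResult(
            variable, TestKind.FISHER_EXACT, float("nan"), df, float(p),
            mc_se=se, notes=notes + [f"monte_carlo with {n_draws} draws"],
        )
    raise ValueError(f"unknown mode {mode!r}")


def enumerated_total_mass(table) -> float:
    """Total probability over all margin-consistent tables (should be 1)."""
    t = np.asarray(table, dtype=int)
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    log_const = float(
        gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
        - gammaln(t.sum() + 1.0)
    )
    return float(
        sum(
            np.exp(_log_table_prob(np.asarray(tab, dtype=float), log_const))
            for tab in _enumerate_tables(tuple(row_sums), tuple(col_sums), 2_000_000)
        )
    )


# ---------------------------------------------------------------------------
# Continuous covariates

def anova_f(groups: Sequence[Sequence[float]], variable: str = "") -> UnivariateResult:
    """One-way ANOVA across trajectory groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 groups, each non-empty")
    k = len(gs)
    n = sum(len(g) for g in gs)
    df = float(k - 1)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    notes: list[str] = []
    if ss_within == 0.0:
        if ss_between == 0.0:
            return UnivariateResult(variable, TestKind.ANOVA_F, 0.0, df, 1.0)
        notes.append("zero within-group variance: F unbounded")
        return UnivariateResult(variable, TestKind.ANOVA_F, float("inf"), df, 0.0, notes=notes)
    res = stats.f_oneway(*gs)
    return UnivariateResult(
        variable, TestKind.ANOVA_F, float(res.statistic), df, float(res.pvalue), notes=notes
    )


def kruskal_wallis(groups: Sequence[Sequence[float]], variable: str = "") -> UnivariateResult:
    """Kruskal-Wallis H test with midrank tie correction."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 groups, each non-empty")
    df = float(len(gs) - 1)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return UnivariateResult(variable, TestKind.KRUSKAL_WALLIS, 0.0, df, 1.0)
    res = stats.kruskal(*gs)
    return UnivariateResult(
        variable, TestKind.KRUSKAL_WALLIS, float(res.statistic), df, float(res.pvalue)
    )


def choose_categorical_test(table, threshold: float = 5.0) -> TestKind:
    """Exact test when any expected cell is below the threshold, else Pearson."""
    if expected_counts(np.asarray(table, dtype=float)).min() < threshold:
        return TestKind.FISHER_EXACT
    return TestKind.PEARSON_CHI2


def univariate_table(
    covariates: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = (),
    nonnormal: Sequence[str] = (),
    categorical: Sequence[str] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Run the per-variable group comparisons and return a tidy table.

    ``continuous`` variables get one-way ANOVA, ``nonnormal`` ones
    Kruskal-Wallis, and ``categorical`` ones Pearson chi-square or the exact
    test depending on expected cell counts.
    """
    levels = sorted(covariates[group_col].unique())
    rows = []
    for var in continuous:
        res = anova_f(
            [covariates.loc[covariates[group_col] == g, var].to_numpy() for g in levels], var
        )
        rows.append(res)
    for var in nonnormal:
        res = kruskal_wallis(
            [covariates.loc[covariates[group_col] == g, var].to_numpy() for g in levels], var
        )
        rows.append(res)
    for var in categorical:
        tab = pd.crosstab(covariates[var], covariates[group_col]).to_numpy()
        kind = choose_categorical_test(tab)
        if kind is TestKind.PEARSON_CHI2:
            rows.append(pearson_chi2(tab, var))
        else:
            try:
                rows.append(fisher_exact_rxc(tab, var, mode="enumerate", max_tables=500_000))
            except EnumerationBudgetError:
                rows.append(fisher_exact_rxc(tab, var, mode="monte_carlo", seed=seed))
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "test": [r.test.value for r in rows],
            "statistic": [r.statistic for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Proportional-odds ordinal regression

def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with a Wald confidence interval: ``exp(beta -+ z se)``."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


@dataclass
class OrdinalTerm:
    name: str
    beta: float
    se: float
    wald_chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    capped: bool = False


@dataclass
class OrdinalFit:
    terms: list[OrdinalTerm]
    thresholds: np.ndarray  # J-1 strictly increasing cutpoints
    loglik: float
    loglik_null: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    parallel_chi2: float | None
    parallel_df: int | None
    parallel_p: float | None
    deviance: float | None
    deviance_df: float | None
    deviance_p: float | None
    pearson: float | None
    pearson_df: float | None
    pearson_p: float | None
    n: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [t.name for t in self.terms],
                "beta": [t.beta for t in self.terms],
                "se": [t.se for t in self.terms],
                "wald_chi2": [t.wald_chi2 for t in self.terms],
                "p_value": [t.p_value for t in self.terms],
                "odds_ratio": [t.odds_ratio for t in self.terms],
                "ci_low": [t.ci_low for t in self.terms],
                "ci_high": [t.ci_high for t in self.terms],
            }
        )


def _design(covariates: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    cols = []
    for var in predictors:
        s = covariates[var]
        if s.dtype.kind in "biufc":
            cols.append(s.astype(float).rename(var))
        else:
            levels = sorted(s.astype(str).unique())
            for lvl in levels[1:]:  # first level alphabetically is the reference
                cols.append((s.astype(str) == lvl).astype(float).rename(f"{var}[{lvl}]"))
    X = pd.concat(cols, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant predictor(s): {', '.join(const)}")
    return X


def _general_cumlogit_loglik(params, X, y_codes, J):
    """Unconstrained cumulative-logit model: slope per cutpoint.

    ``P(Y <= j) = expit(alpha_j - x beta_j)``; cell probabilities clipped at
    1e-12 (the unconstrained model need not be internally coherent for every
    x, which is exactly what the parallel-lines test probes).
    """
    p = X.shape[1]
    alphas = params[: J - 1]
    betas = params[J - 1 :].reshape(J - 1, p)
    cum = expit(alphas[None, :] - X @ betas.T)  # (n, J-1)
    full = np.hstack([np.zeros((X.shape[0], 1)), cum, np.ones((X.shape[0], 1))])
    cell = np.clip(np.diff(full, axis=1), 1e-12, None)
    return float(np.sum(np.log(cell[np.arange(len(y_codes)), y_codes])))


def ordinal_logit_fit(
    covariates: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "group",
    cap: float = 15.0,
    diagnostics: bool = True,
    level: float = 0.95,
) -> OrdinalFit:
    """Proportional-odds model of ordinal trajectory-group membership.

    Dummy coding uses the first level (alphabetically) of each categorical
    predictor as reference; the outcome is ordered by its sorted unique
    values, and positive coefficients mean greater odds of a more severe
    group.  Coefficients whose magnitude exceeds ``cap`` on the logit scale
    are flagged and capped in the report (quasi-separation produces the huge,
    meaningless odds ratios familiar from sparse tables).
    """
    y = covariates[outcome]
    levels_y = sorted(y.unique())
    J = len(levels_y)
    if J < 3:
        raise ValueError("outcome needs >= 3 ordinal levels")
    y_cat = pd.Categorical(y, categories=levels_y, ordered=True)
    y_codes = np.asarray(y_cat.codes)
    X = _design(covariates, predictors)
    Xv = X.to_numpy(dtype=float)
    n = len(y_codes)

    model = OrderedModel(pd.Series(y_cat), Xv, distr="logit")
    warns: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(method="nm", maxiter=5000, disp=0, start_params=res.params)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        warns.append("maximum-likelihood fit did not fully converge")

    p = Xv.shape[1]
    betas = np.asarray(res.params[:p], dtype=float)
    ses = np.asarray(res.bse[:p], dtype=float)
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    loglik = float(res.llf)
    counts = np.bincount(y_codes, minlength=J)
    loglik_null = float(np.sum(counts * np.log(counts / n)))
    lr = 2.0 * (loglik - loglik_null)
    lr_df = p
    lr_p = float(stats.chi2.sf(lr, lr_df))

    terms = []
    for name, b, s in zip(X.columns, betas, ses):
        capped = abs(b) > cap or not np.isfinite(s) or s > 1e4
        if capped:
            warns.append(f"{name}: quasi-separation (|beta| or SE diverging); capped at {cap}")
        b_rep = float(np.clip(b, -cap, cap)) if capped else float(b)
        o, lo_ci, hi_ci = or_ci(b_rep, float(s), level) if s > 0 else (np.exp(b_rep), 0.0, np.inf)
        wald = (b_rep / s) ** 2 if s > 0 else float("nan")
        terms.append(
            OrdinalTerm(
                name=name, beta=b_rep, se=float(s), wald_chi2=float(wald),
                p_value=float(stats.chi2.sf(wald, 1)) if np.isfinite(wald) else float("nan"),
                odds_ratio=o, ci_low=lo_ci, ci_high=hi_ci, capped=capped,
            )
        )

    par_chi2 = par_df = par_p = None
    dev = dev_df = dev_p = pea = pea_df = pea_p = None
    if diagnostics:
        # parallel-lines test: PO fit vs slope-per-cutpoint cumulative model
        x0 = np.concatenate([np.asarray(thresholds, float), np.tile(betas, J - 1)])
        from scipy.optimize import minimize as _minimize

        obj = lambda prm: -_general_cumlogit_loglik(prm, Xv, y_codes, J)
        gen = _minimize(obj, x0, method="BFGS", options={"maxiter": 2000})
        ll_gen = max(-float(gen.fun), loglik)  # the general model nests the PO model
        par_chi2 = 2.0 * (ll_gen - loglik)
        par_df = (J - 2) * p
        par_p = float(stats.chi2.sf(par_chi2, par_df))

        # goodness of fit on distinct covariate patterns
        pat = pd.DataFrame(Xv).groupby(list(range(p)), sort=False)
        probs = np.asarray(res.predict(Xv))  # (n, J)
        obs_tot, exp_tot, n_pat = [], [], 0
        for _, idx in pat.indices.items():
            idx = np.asarray(idx)
            o_counts = np.bincount(y_codes[idx], minlength=J).astype(float)
            e_counts = probs[idx].sum(axis=0)
            obs_tot.append(o_counts)
            exp_tot.append(e_counts)
            n_pat += 1
        O = np.vstack(obs_tot)
        E = np.clip(np.vstack(exp_tot), 1e-10, None)
        pea = float(((O - E) ** 2 / E).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = float(2.0 * np.nansum(np.where(O > 0, O * np.log(O / E), 0.0)))
        gof_df = max(n_pat * (J - 1) - (p + J - 1), 1)
        dev_df = pea_df = float(gof_df)
        dev_p = float(stats.chi2.sf(dev, gof_df))
        pea_p = float(stats.chi2.sf(pea, gof_df))

    return OrdinalFit(
        terms=terms,
        thresholds=np.asarray(thresholds, dtype=float),
        loglik=loglik,
        loglik_null=loglik_null,
        lr_chi2=float(lr),
        lr_df=lr_df,
        lr_p=lr_p,
        parallel_chi2=par_chi2,
        parallel_df=par_df,
        parallel_p=par_p,
        deviance=dev,
        deviance_df=dev_df,
        deviance_p=dev_p,
        pearson=pea,
        pearson_df=pea_df,
        pearson_p=pea_p,
        n=n,
        converged=converged,
        warnings=warns,
    )


def predicted_severe_probability(fit_terms_beta, thresholds, x):
    """P(most severe level) under the fitted proportional-odds model."""
    eta = float(np.dot(fit_terms_beta, x))
    return float(1.0 - expit(thresholds[-1] - eta))
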