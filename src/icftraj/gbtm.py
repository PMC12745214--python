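"""Censored-normal group-based trajectory modelling (GBTM).

A finite mixture of polynomial trajectories for a bounded score observed
longitudinally.  Patient ``i`` in latent group ``k`` has, at (rescaled) time
``t``, a latent score ``mu_k(t) + e`` with ``e ~ N(0, sigma^2)``; the
observed score is the latent score censored to the instrument scale
``[s_min, s_max]`` (CNORM): a normal density in the interior and probability
mass at the two boundaries.  Group membership probabilities ``p_k`` and the
per-group polynomial coefficients are estimated jointly by EM: posteriors in
the E-step, and a posterior-weighted censored-normal polynomial regression
(L-BFGS with analytic gradients) in the M-step.

Model selection follows the usual GBTM admissibility rules for a candidate
set of group counts: every group's average posterior probability of
assignment (AvePP) must exceed 0.7 and every group must hold at least 5% of
patients; among admissible candidates the BIC closest to zero wins (BIC here
is ``loglik - 0.5 * n_params * ln(n_subjects)``, a negative quantity under
which "closer to 0" means better fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TrajectorySpec:
    """Structure of a candidate trajectory model."""

    n_groups: int
    poly_orders: int | Sequence[int] = 2
    bounds: tuple[float, float] = (0.0, 200.0)
    shared_sigma: bool = True
    time_scale: float = 100.0

    def orders(self) -> tuple[int, ...]:
        if isinstance(self.poly_orders, int):
            return (self.poly_orders,) * self.n_groups
        return tuple(self.poly_orders)

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        orders = self.orders()
        if len(orders) != self.n_groups:
            raise ValueError("one polynomial order needed per group")
        if any(o not in (0, 1, 2, 3) for o in orders):
            raise ValueError("polynomial orders must be in {0,1,2,3}")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy s_min < s_max")

    @property
    def n_params(self) -> int:
        """Free parameters: (K-1) shares + coefficients + sigma(s)."""
        k = self.n_groups
        return (k - 1) + sum(o + 1 for o in self.orders()) + (1 if self.shared_sigma else k)


@dataclass
class FittedTrajectoryModel:
    spec: TrajectorySpec
    group_probs: np.ndarray
    coeffs: list[np.ndarray]  # polyval convention, highest degree first
    sigma: np.ndarray  # shape (K,); identical entries when shared
    loglik: float
    bic: float
    posteriors: np.ndarray  # (n_subjects, K)
    assignment: np.ndarray  # argmax group per subject, ties to lower index
    avepp: np.ndarray
    shares: np.ndarray
    patient_ids: list
    n_subjects: int
    n_obs: int
    converged: bool
    n_iter: int
    loglik_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def day0_means(self) -> np.ndarray:
        """Fitted mean score at day 0 per group (the curve intercepts)."""
        return np.array([np.polyval(b, 0.0) for b in self.coeffs])

    def curve(self, group: int, days: np.ndarray) -> np.ndarray:
        return np.polyval(self.coeffs[group], np.asarray(days, float) / self.spec.time_scale)

    def coeffs_day_scale(self) -> list[np.ndarray]:
        """Coefficients re-expressed against raw days instead of rescaled time."""
        out = []
        for b in self.coeffs:
            deg = len(b) - 1
            out.append(b * self.spec.time_scale ** -np.arange(deg, -1, -1.0))
        return out


# ---------------------------------------------------------------------------
# Censored-normal kernel

def cnorm_logdensity(y, mu, sigma, bounds=(0.0, 200.0)):
    """Log density/mass of the censored normal at observed score(s) ``y``.

    Interior scores get the normal log-density; scores at the lower bound the
    log probability mass ``log Phi((s_min-mu)/sigma)``; scores at the upper
    bound ``log(1-Phi((s_max-mu)/sigma))``.  Vectorized over ``y``/``mu``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    s_min, s_max = bounds
    if np.any(y < s_min) or np.any(y > s_max):
        raise ValueError(f"score outside bounds [{s_min}, {s_max}]")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    z = (y - mu) / sigma
    interior = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma) * np.ones_like(z)
    out = interior
    lo = y == s_min
    hi = y == s_max
    if np.any(lo):
        out = np.where(lo, log_ndtr((s_min - mu) / sigma * np.ones_like(z)), out)
    if np.any(hi):
        out = np.where(hi, log_ndtr(-(s_max - mu) / sigma * np.ones_like(z)), out)
    return out if out.shape else float(out)


def _cnorm_ll_grads(y, mu, sigma, bounds):
    """Pointwise log-likelihood and its gradients wrt mu and log(sigma)."""
    s_min, s_max = bounds
    z = (y - mu) / sigma
    ll = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma)
    dmu = z / sigma
    dls = z * z - 1.0

    lo = y == s_min
    if np.any(lo):
        a = (s_min - mu[lo]) / sigma
        log_mills = (-0.5 * a * a - _LOG_SQRT_2PI) - log_ndtr(a)
        r = np.exp(log_mills)  # phi(a)/Phi(a)
        ll[lo] = log_ndtr(a)
        dmu[lo] = -r / sigma
        dls[lo] = -r * a
    hi = y == s_max
    if np.any(hi):
        b = (s_max - mu[hi]) / sigma
        log_mills = (-0.5 * b * b - _LOG_SQRT_2PI) - log_ndtr(-b)
        r = np.exp(log_mills)  # phi(b)/(1-Phi(b))
        ll[hi] = log_ndtr(-b)
        dmu[hi] = r / sigma
        dls[hi] = r * b
    return ll, dmu, dls


# ---------------------------------------------------------------------------
# Data preparation

class _Prepared:
    """Sorted observation arrays with per-patient slices and design matrices."""

    def __init__(self, data: pd.DataFrame, spec: TrajectorySpec):
        need = {"patient_id", "day", "total"}
        if not need.issubset(data.columns):
            raise ValueError(f"data needs columns {sorted(need)}")
        df = data.sort_values(["patient_id", "day"], kind="mergesort")
        self.patient_ids = list(dict.fromkeys(df["patient_id"]))
        codes = df["patient_id"].map({p: i for i, p in enumerate(self.patient_ids)}).to_numpy()
        self.y = df["total"].to_numpy(dtype=float)
        self.t = df["day"].to_numpy(dtype=float) / spec.time_scale
        self.obs_patient = codes
        self.n_subjects = len(self.patient_ids)
        self.n_obs = len(self.y)
        self.starts = np.searchsorted(codes, np.arange(self.n_subjects))
        # Vandermonde per distinct order, columns t^deg ... t^0 (polyval order)
        self.X = {
            o: np.vander(self.t, o + 1, increasing=False) for o in set(spec.orders())
        }
        self.spec = spec

    def group_obs_loglik(self, coeffs, sigma):
        """(n_obs, K) pointwise log-likelihood per group."""
        K = self.spec.n_groups
        out = np.empty((self.n_obs, K))
        for k in range(K):
            mu = self.X[len(coeffs[k]) - 1] @ coeffs[k]
            out[:, k] = cnorm_logdensity(self.y, mu, float(sigma[k]), self.spec.bounds)
        return out

    def per_patient(self, obs_matrix):
        """Sum an (n_obs, K) matrix within patients -> (n_subjects, K)."""
        return np.add.reduceat(obs_matrix, self.starts, axis=0)


def mixture_loglikelihood(data, spec, group_probs, coeffs, sigma) -> float:
    """Observed-data log-likelihood of the censored-normal mixture.

    ``sum_i log sum_k p_k prod_t f_cnorm(y_it | beta_k, sigma_k)`` with
    group-conditional independence across a patient's time points.
    """
    spec.validate()
    p = np.asarray(group_probs, dtype=float)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(), (spec.n_groups,))
    if not np.all(np.isfinite(p)) or not all(np.all(np.isfinite(b)) for b in coeffs):
        raise ValueError("non-finite parameter")
    prep = _Prepared(data, spec)
    L = prep.per_patient(prep.group_obs_loglik([np.asarray(b, float) for b in coeffs], sig))
    return float(np.sum(logsumexp(L + np.log(p), axis=1)))


# ---------------------------------------------------------------------------
# EM fit

def _pack(coeffs, log_sigma):
    return np.concatenate([np.concatenate(coeffs), np.atleast_1d(log_sigma)])


def _unpack(x, spec: TrajectorySpec):
    orders = spec.orders()
    coeffs, pos = [], 0
    for o in orders:
        coeffs.append(x[pos : pos + o + 1])
        pos += o + 1
    log_sigma = x[pos:]
    return coeffs, log_sigma


def _weighted_cnorm_objective(x, prep: _Prepared, post_obs):
    """Negative Q and gradient for the M-step regression.

    ``post_obs`` is the (n_obs, K) matrix of posteriors expanded to
    observations.  Returns (-Q, -dQ/dx).
    """
    spec = prep.spec
    coeffs, log_sigma = _unpack(x, spec)
    K = spec.n_groups
    sig = np.exp(log_sigma if len(log_sigma) == K else np.repeat(log_sigma, K))
    q = 0.0
    grad = np.zeros_like(x)
    pos = 0
    g_ls = np.zeros(K)
    for k in range(K):
        X = prep.X[len(coeffs[k]) - 1]
        mu = X @ coeffs[k]
        ll, dmu, dls = _cnorm_ll_grads(prep.y, mu, float(sig[k]), spec.bounds)
        w = post_obs[:, k]
        q += float(w @ ll)
        grad[pos : pos + X.shape[1]] = X.T @ (w * dmu)
        g_ls[k] = float(w @ dls)
        pos += X.shape[1]
    if len(log_sigma) == K:
        grad[pos:] = g_ls
    else:
        grad[pos] = g_ls.sum()
    return -q, -grad


def _initial_assignment(prep: _Prepared, K: int, rng: np.random.Generator, perturb: bool):
    """Quantile split of patient mean scores into K blocks, optionally
    perturbed by randomly reassigning ~25% of patients."""
    means = prep.per_patient(prep.y[:, None])[:, 0] / np.diff(
        np.append(prep.starts, prep.n_obs)
    )
    order = np.argsort(means, kind="mergesort")
    assign = np.empty(prep.n_subjects, dtype=int)
    blocks = np.array_split(order, K)
    for k, idx in enumerate(blocks):
        assign[idx] = k
    if perturb:
        flip = rng.random(prep.n_subjects) < 0.25
        assign[flip] = rng.integers(0, K, size=int(flip.sum()))
    return assign


def _init_params(prep: _Prepared, assign, spec: TrajectorySpec):
    K = spec.n_groups
    coeffs, resid_ss, resid_n = [], 0.0, 0
    for k in range(K):
        o = spec.orders()[k]
        mask = assign[prep.obs_patient] == k
        if mask.sum() <= o:
            coeffs.append(np.zeros(o + 1))
            coeffs[-1][-1] = float(prep.y.mean())
            continue
        X = prep.X[o][mask]
        b, *_ = np.linalg.lstsq(X, prep.y[mask], rcond=None)
        coeffs.append(b)
        r = prep.y[mask] - X @ b
        resid_ss += float(r @ r)
        resid_n += int(mask.sum())
    sigma0 = max(np.sqrt(resid_ss / max(resid_n, 1)), 1.0)
    counts = np.bincount(assign, minlength=K).astype(float)
    p = np.clip(counts, 0.5, None)
    p /= p.sum()
    n_ls = 1 if spec.shared_sigma else K
    return p, coeffs, np.full(n_ls, np.log(sigma0))


def avepp(posteriors: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Average posterior probability of assignment per group.

    For each group, the mean of ``posteriors[i, assignment[i]]`` over the
    patients assigned to it; NaN marks an empty group.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    assignment = np.asarray(assignment)
    K = posteriors.shape[1]
    out = np.full(K, np.nan)
    own = posteriors[np.arange(len(assignment)), assignment]
    for k in range(K):
        m = assignment == k
        if m.any():
            out[k] = float(own[m].mean())
    return out


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """``loglik - 0.5 * n_params * ln(n_subjects)``: negative, closer to 0 is
    better."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return float(loglik - 0.5 * n_params * np.log(n_subjects))


def fit(
    data: pd.DataFrame,
    spec: TrajectorySpec,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedTrajectoryModel:
    """Fit the censored-normal mixture by multi-start EM.

    ``data`` is a long table with columns patient_id, day, total.  The first
    start uses a quantile split of patient mean scores; the remaining
    ``n_starts - 1`` perturb it with a seeded RNG.  Groups in the returned
    model are relabelled in ascending order of fitted day-0 mean, so group 1
    is always the mildest trajectory.
    """
    spec.validate()
    prep = _Prepared(data, spec)
    K = spec.n_groups
    if prep.n_subjects < K:
        raise ValueError(f"need at least {K} patients to fit {K} groups")
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(n_starts, 1)):
        assign0 = _initial_assignment(prep, K, rng, perturb=start > 0)
        p, coeffs, log_sigma = _init_params(prep, assign0, spec)
        x = _pack(coeffs, log_sigma)
        ll_prev = -np.inf
        history: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            coeffs, log_sigma = _unpack(x, spec)
            sig = np.exp(log_sigma if len(log_sigma) == K else np.repeat(log_sigma, K))
            L = prep.per_patient(prep.group_obs_loglik(coeffs, sig))
            logw = L + np.log(np.clip(p, 1e-300, None))
            ll_patient = logsumexp(logw, axis=1)
            ll = float(ll_patient.sum())
            history.append(ll)
            post = np.exp(logw - ll_patient[:, None])
            if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and n_iter > 1:
                converged = True
                break
            ll_prev = ll
            # M-step
            p = post.mean(axis=0)
            post_obs = post[prep.obs_patient]
            f0 = _weighted_cnorm_objective(x, prep, post_obs)[0]
            n_sig = 1 if spec.shared_sigma else K
            # sigma kept away from 0 so noise-free data cannot degenerate
            bnds = [(None, None)] * (len(x) - n_sig) + [(np.log(1e-2), np.log(1e3))] * n_sig
            res = minimize(
                _weighted_cnorm_objective,
                x,
                args=(prep, post_obs),
                jac=True,
                method="L-BFGS-B",
                bounds=bnds,
                options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-9},
            )
            if np.isfinite(res.fun) and res.fun <= f0:
                x = res.x
        cand = (ll, p, x, post, converged, n_iter, history)
        if best is None or cand[0] > best[0]:
            best = cand

    ll, p, x, post, converged, n_iter, history = best
    coeffs, log_sigma = _unpack(x, spec)
    sigma = np.exp(log_sigma if len(log_sigma) == K else np.repeat(log_sigma, K))

    # canonical labels: ascending day-0 mean
    order = np.argsort([np.polyval(b, 0.0) for b in coeffs], kind="mergesort")
    p = np.asarray(p)[order]
    coeffs = [np.asarray(coeffs[k], dtype=float) for k in order]
    sigma = sigma[order]
    post = post[:, order]

    assignment = np.argmax(post, axis=1)
    shares = np.bincount(assignment, minlength=K) / prep.n_subjects
    warn: list[str] = []
    if not converged:
        warn.append(f"EM did not converge within {max_iter} iterations")
    mass = post.sum(axis=0)
    for k in np.flatnonzero(mass < 1.0):
        warn.append(f"group {k + 1} is degenerate (posterior mass {mass[k]:.3f} < 1)")

    model = FittedTrajectoryModel(
        spec=spec,
        group_probs=p,
        coeffs=coeffs,
        sigma=sigma,
        loglik=ll,
        bic=bic(ll, spec.n_params, prep.n_subjects),
        posteriors=post,
        assignment=assignment,
        avepp=avepp(post, assignment),
        shares=shares,
        patient_ids=prep.patient_ids,
        n_subjects=prep.n_subjects,
        n_obs=prep.n_obs,
        converged=converged,
        n_iter=n_iter,
        loglik_history=history,
        warnings=warn,
    )
    return model


# ---------------------------------------------------------------------------
# Model selection

@dataclass
class CandidateSummary:
    spec: TrajectorySpec
    bic: float
    min_avepp: float
    min_share: float
    admissible: bool


@dataclass
class SelectionResult:
    candidates: list[CandidateSummary]
    chosen: FittedTrajectoryModel
    admissible: bool


def select_model(
    data: pd.DataFrame,
    K_range: Sequence[int],
    order_menu: int | Sequence[int] = 2,
    avepp_threshold: float = 0.7,
    share_threshold: float = 0.05,
    bounds: tuple[float, float] = (0.0, 200.0),
    **fit_kwargs,
) -> SelectionResult:
    """Fit one candidate per group count and apply the admissibility rule.

    A candidate is admissible when every group's AvePP exceeds
    ``avepp_threshold`` and every group holds at least ``share_threshold`` of
    patients; the admissible candidate with BIC closest to 0 is chosen.  When
    none is admissible the best-BIC candidate is returned flagged
    ``admissible=False``.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K_range")
    fitted: list[FittedTrajectoryModel] = []
    summaries: list[CandidateSummary] = []
    for K in K_range:
        spec = TrajectorySpec(n_groups=K, poly_orders=order_menu, bounds=bounds)
        model = fit(data, spec, **fit_kwargs)
        min_avepp = float(np.nanmin(model.avepp))
        min_share = float(model.shares.min())
        admissible = (min_avepp > avepp_threshold) and (min_share >= share_threshold)
        fitted.append(model)
        summaries.append(
            CandidateSummary(spec, model.bic, min_avepp, min_share, admissible)
        )
    admissible_idx = [i for i, s in enumerate(summaries) if s.admissible]
    pool = admissible_idx if admissible_idx else range(len(summaries))
    # BIC is negative; closest to 0 = largest
    best = max(pool, key=lambda i: summaries[i].bic)
    if not admissible_idx:
        warnings.warn("no admissible candidate; returning best-BIC model")
    return SelectionResult(summaries, fitted[best], bool(admissible_idx))


# ---------------------------------------------------------------------------
# Persistence

def model_to_yaml(model: FittedTrajectoryModel, path) -> None:
    d = {
        "spec": {
            "n_groups": model.spec.n_groups,
            "poly_orders": list(model.spec.orders()),
            "bounds": list(model.spec.bounds),
            "shared_sigma": model.spec.shared_sigma,
            "time_scale": model.spec.time_scale,
        },
        "group_probs": [float(v) for v in model.group_probs],
        "coeffs_rescaled_time": [[float(c) for c in b] for b in model.coeffs],
        "coeffs_day_scale": [[float(c) for c in b] for b in model.coeffs_day_scale()],
        "sigma": [float(s) for s in model.sigma],
        "loglik": float(model.loglik),
        "bic": float(model.bic),
        "avepp": [float(v) for v in model.avepp],
        "shares": [float(v) for v in model.shares],
        "n_subjects": model.n_subjects,
        "n_obs": model.n_obs,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "warnings": list(model.warnings),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def posteriors_frame(model: FittedTrajectoryModel) -> pd.DataFrame:
    df = pd.DataFrame(
        model.posteriors,
        columns=[f"post_group{k + 1}" for k in range(model.spec.n_groups)],
    )
    df.insert(0, "patient_id", model.patient_ids)
    df["group"] = model.assignment + 1
    return df


def curves_frame(model: FittedTrajectoryModel, day_max: int = 280, step: int = 7) -> pd.DataFrame:
    days = np.arange(0, day_max + 1, step)
    rows = []
    for k in range(model.spec.n_groups):
        for d, v in zip(days, model.curve(k, days)):
            rows.append({"group": k + 1, "day": int(d), "mean_total": float(v)})
    return pd.DataFrame(rows)
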