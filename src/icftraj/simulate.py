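"""Synthetic inpatient stroke-rehabilitation cohorts.

The study cohort this package analyses is not publicly deposited, so every
downstream stage is exercised on synthetic cohorts generated here.  The
generative model mirrors the structure the analysis assumes:

* a latent trajectory group per patient (default: 4 groups);
* a declining polynomial mean curve of the total disability score over days
  since admission, with additive normal noise censored to the instrument's
  0-200 scale;
* assessments every 14 days from admission to a log-normally distributed
  length of stay;
* item scores apportioned from the total via fixed item weights, so the
  instrument-level summaries are exercised;
* group-conditional covariates (independent given group) and group-
  conditional costs (length of stay x daily cost x log-normal noise).

``default_stroke_config`` encodes the reference inpatient stroke cohort the
defaults emulate: group shares 17/34/26/18 of 95, admission means near
25/61/88/116 declining to the levels described for each severity group, and
the published covariate frequencies, lengths of stay and daily costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .items import ITEM_CODES, AssessmentRecord, assign_stages, write_assessments


class ConfigError(ValueError):
    """Inconsistent synthetic-cohort configuration."""


@dataclass
class SyntheticCohortConfig:
    """Generative model for a synthetic rehabilitation cohort.

    ``curves`` are per-group polynomial coefficients (highest degree first,
    ``numpy.polyval`` convention) for the mean total score as a function of
    rescaled time ``day / time_scale``.  ``plateau_day`` optionally freezes
    each group's mean beyond a horizon, emulating the late recovery plateau;
    ``None`` evaluates the raw polynomial everywhere.
    """

    n_patients: int
    group_probs: Sequence[float]
    curves: Sequence[Sequence[float]]
    sigma: float = 12.0
    bounds: tuple[float, float] = (0.0, 200.0)
    visit_interval: int = 14
    time_scale: float = 100.0
    plateau_day: Sequence[float] | None = None
    los_mean: Sequence[float] = (31.9, 49.4, 87.6, 88.9)
    los_sd: Sequence[float] = (18.1, 27.6, 74.0, 49.4)
    los_min: float = 14.0
    los_max: float = 420.0
    daily_cost_mean: Sequence[float] = (484.73, 531.28, 546.12, 633.53)
    cost_log_sd: float = 0.3
    age_mean: Sequence[float] = (45.4, 53.2, 63.7, 61.8)
    age_sd: Sequence[float] = (15.7, 16.0, 15.4, 13.0)
    mbi_mean: Sequence[float] = (84.7, 59.4, 32.4, 20.0)
    mbi_sd: Sequence[float] = (11.0, 20.0, 17.0, 12.9)
    course_median: Sequence[float] = (86.0, 66.0, 56.0, 84.5)
    course_log_sd: float = 0.9
    binary_probs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    categorical_probs: Mapping[str, tuple[Sequence[str], Sequence[Sequence[float]]]] = field(
        default_factory=dict
    )
    item_weights: Sequence[float] | None = None
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        p = np.asarray(self.group_probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigError("group_probs must be nonnegative and sum to 1")
        if len(self.curves) != self.n_groups:
            raise ConfigError(
                f"{len(self.curves)} curves for {self.n_groups} group probabilities"
            )
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.visit_interval < 1:
            raise ConfigError("visit_interval must be >= 1")
        if self.bounds[0] >= self.bounds[1]:
            raise ConfigError("bounds must satisfy s_min < s_max")
        for name, probs in self.binary_probs.items():
            if len(probs) != self.n_groups:
                raise ConfigError(f"covariate {name}: needs one probability per group")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its latent truth."""

    assessments: list[AssessmentRecord]
    covariates: pd.DataFrame
    episodes: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _draw_los(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    mu, s = _lognormal_params(mean, sd)
    for _ in range(1000):
        v = float(rng.lognormal(mu, s))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def allocate_items(total: int, weights: Sequence[float]) -> dict[str, int]:
    """Apportion a total score over the 20 items by fixed weights.

    Largest-remainder apportionment with per-item clamping to [0, 10]; the
    result always sums exactly to ``total`` (feasible for any total in
    [0, 200]).
    """
    if not 0 <= total <= 200:
        raise ValueError(f"total {total} outside [0, 200]")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(ITEM_CODES),) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be 20 nonnegative values with a positive sum")
    target = total * w / w.sum()
    alloc = np.minimum(np.floor(target), 10).astype(int)
    resid = target - alloc
    deficit = int(total - alloc.sum())
    # distribute the remainder one point at a time to the item with the
    # largest unmet target among those not yet clamped at 10
    order_key = resid.copy()
    while deficit > 0:
        open_items = np.flatnonzero(alloc < 10)
        j = open_items[np.argmax(order_key[open_items])]
        alloc[j] += 1
        order_key[j] -= 1.0
        deficit -= 1
    while deficit < 0:  # cannot occur with floor(), kept for safety
        open_items = np.flatnonzero(alloc > 0)
        j = open_items[np.argmin(order_key[open_items])]
        alloc[j] -= 1
        order_key[j] += 1.0
        deficit += 1
    return {code: int(v) for code, v in zip(ITEM_CODES, alloc)}


def group_mean(config: SyntheticCohortConfig, group: int, day: float) -> float:
    """The group's latent mean total score at a given day since admission."""
    d = float(day)
    if config.plateau_day is not None:
        d = min(d, float(config.plateau_day[group]))
    return float(np.polyval(config.curves[group], d / config.time_scale))


def generate(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from the configured generative model.

    One global seed feeds a root ``SeedSequence``; each patient gets a
    deterministically spawned sub-stream, so cohorts are reproducible and
    stable under partial regeneration.
    """
    config.validate()
    k = config.n_groups
    weights = (
        np.asarray(config.item_weights, dtype=float)
        if config.item_weights is not None
        else np.ones(len(ITEM_CODES))
    )
    root = np.random.SeedSequence(config.seed)
    group_rng = np.random.default_rng(root.spawn(1)[0])
    groups = group_rng.choice(k, size=config.n_patients, p=np.asarray(config.group_probs))
    streams = root.spawn(config.n_patients + 1)[1:]

    s_min, s_max = config.bounds
    width = len(str(config.n_patients))
    assessments: list[AssessmentRecord] = []
    cov_rows, epi_rows, truth_rows = [], [], []
    for i in range(config.n_patients):
        rng = np.random.default_rng(streams[i])
        g = int(groups[i])
        pid = f"P{i + 1:0{width}d}"
        los = _draw_los(
            rng, config.los_mean[g], config.los_sd[g], config.los_min, config.los_max
        )
        days = np.arange(0, int(los) + 1, config.visit_interval)
        for day in days:
            latent = group_mean(config, g, day) + (
                rng.normal(0.0, config.sigma) if config.sigma > 0 else 0.0
            )
            total = int(round(float(np.clip(latent, s_min, s_max))))
            total = int(np.clip(total, 0, 200))
            assessments.append(
                AssessmentRecord(pid, int(day), allocate_items(total, weights))
            )
        cov = {
            "patient_id": pid,
            "age": float(rng.normal(config.age_mean[g], config.age_sd[g])),
            "mbi_admission": float(
                np.clip(rng.normal(config.mbi_mean[g], config.mbi_sd[g]), 0, 100)
            ),
            "disease_course": float(
                rng.lognormal(np.log(config.course_median[g]), config.course_log_sd)
            ),
        }
        for name, probs in config.binary_probs.items():
            cov[name] = ["no", "yes"][int(rng.random() < probs[g])]
        for name, (levels, probs) in config.categorical_probs.items():
            cov[name] = str(rng.choice(levels, p=np.asarray(probs[g], dtype=float)))
        cov_rows.append(cov)
        cost = (
            los
            * config.daily_cost_mean[g]
            * float(rng.lognormal(-config.cost_log_sd**2 / 2.0, config.cost_log_sd))
        )
        epi_rows.append({"patient_id": pid, "length_of_stay": los, "cost": cost})
        truth_rows.append({"patient_id": pid, "group": g + 1})

    assign_stages(assessments)
    return SyntheticCohort(
        assessments=assessments,
        covariates=pd.DataFrame(cov_rows),
        episodes=pd.DataFrame(epi_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# Reference configuration

#: Narrative anchors (day, mean total score) per severity group, used to pin
#: each group's quadratic mean curve; beyond the last anchor the mean
#: plateaus.
CURVE_ANCHORS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((0, 25), (34, 18), (68, 12)),
    ((0, 61), (60, 40), (93, 35)),
    ((0, 88), (100, 58), (280, 40)),
    ((0, 116), (120, 82), (210, 72)),
)

#: Admission means of the 20 items in the reference cohort, in catalogue
#: order; used as default item-allocation weights.
REFERENCE_ITEM_MEANS: tuple[float, ...] = (
    7.38, 8.05, 4.14, 2.27, 2.04, 6.57, 6.91, 7.39, 7.35, 7.07, 2.86,
    1.66, 1.54, 0.92, 0.20, 1.98,
    1.53, 1.27, 1.06, 1.38,
)

#: Per-group "yes" probabilities of the binary covariates in the reference
#: cohort (groups of sizes 17/34/26/18).
REFERENCE_BINARY_PROBS: dict[str, tuple[float, float, float, float]] = {
    "female": (3 / 17, 5 / 34, 14 / 26, 4 / 18),
    "hypertension": (14 / 17, 25 / 34, 20 / 26, 14 / 18),
    "diabetes": (3 / 17, 7 / 34, 6 / 26, 4 / 18),
    "emotional_disorders": (1 / 17, 4 / 34, 3 / 26, 4 / 18),
    "shoulder_pain": (0 / 17, 3 / 34, 2 / 26, 2 / 18),
    "dysphagia": (1 / 17, 4 / 34, 9 / 26, 8 / 18),
    "urine_bag_or_diaper": (0 / 17, 3 / 34, 4 / 26, 9 / 18),
    "assistive_device": (7 / 17, 25 / 34, 25 / 26, 16 / 18),
    "surgery": (5 / 17, 10 / 34, 7 / 26, 9 / 18),
    "ataxia": (2 / 17, 1 / 34, 3 / 26, 2 / 18),
    "cognitive_impairment": (0 / 17, 4 / 34, 12 / 26, 12 / 18),
    "aphasia": (2 / 17, 4 / 34, 5 / 26, 4 / 18),
}

REFERENCE_CATEGORICAL_PROBS: dict[str, tuple[tuple[str, ...], tuple[tuple[float, ...], ...]]] = {
    "diagnosis": (
        ("hemorrhage", "infarction"),
        ((11 / 17, 6 / 17), (19 / 34, 15 / 34), (9 / 26, 17 / 26), (9 / 18, 9 / 18)),
    ),
    "education": (
        ("illiterate", "primary", "secondary_technical", "college_or_above"),
        (
            (1 / 17, 0 / 17, 3 / 17, 13 / 17),
            (0 / 34, 2 / 34, 8 / 34, 24 / 34),
            (2 / 26, 5 / 26, 9 / 26, 10 / 26),
            (0 / 18, 2 / 18, 7 / 18, 9 / 18),
        ),
    ),
    "hemiplegic_side": (
        ("left", "right", "bilateral"),
        (
            (6 / 17, 9 / 17, 2 / 17),
            (17 / 34, 14 / 34, 3 / 34),
            (14 / 26, 7 / 26, 5 / 26),
            (9 / 18, 7 / 18, 2 / 18),
        ),
    ),
}


def _fit_anchor_curves(time_scale: float) -> tuple[list[list[float]], list[float]]:
    """Exact quadratics through each group's anchors, plus the plateau day.

    The plateau starts at the last anchor or at the quadratic's minimum,
    whichever comes first, so the latent mean never rises with time.
    """
    curves, plateaus = [], []
    for anchors in CURVE_ANCHORS:
        d = np.array([a[0] for a in anchors], dtype=float) / time_scale
        y = np.array([a[1] for a in anchors], dtype=float)
        a2, a1, _ = np.polyfit(d, y, 2)
        curves.append(list(np.polyfit(d, y, 2)))
        horizon = anchors[-1][0]
        if a2 > 0:
            horizon = min(horizon, -a1 / (2 * a2) * time_scale)
        plateaus.append(float(horizon))
    return curves, plateaus


def default_stroke_config(n_patients: int = 95, seed: int = 0) -> SyntheticCohortConfig:
    """The reference 4-group stroke-rehabilitation generative model.

    Group shares 17/34/26/18 of 95; quadratic mean curves anchored at
    admission means 25/61/88/116 and the late levels described for each
    severity group, with a plateau past each group's last anchor; residual
    SD 12 score points; 14-day assessment interval; log-normal lengths of
    stay with means (31.9, 49.4, 87.6, 88.9) days; daily treatment costs
    (484.73, 531.28, 546.12, 633.53) currency units per day; covariate
    frequencies matching the reference cohort margins.
    """
    time_scale = 100.0
    curves, plateaus = _fit_anchor_curves(time_scale)
    return SyntheticCohortConfig(
        n_patients=n_patients,
        group_probs=(17 / 95, 34 / 95, 26 / 95, 18 / 95),
        curves=curves,
        sigma=12.0,
        time_scale=time_scale,
        plateau_day=tuple(plateaus),
        binary_probs=dict(REFERENCE_BINARY_PROBS),
        categorical_probs=dict(REFERENCE_CATEGORICAL_PROBS),
        item_weights=REFERENCE_ITEM_MEANS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# On-disk interface

def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write assessments/covariates/episodes/truth CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assessments": outdir / "assessments.csv",
        "covariates": outdir / "covariates.csv",
        "episodes": outdir / "episodes.csv",
        "truth": outdir / "truth.csv",
    }
    write_assessments(cohort.assessments, paths["assessments"])
    cohort.covariates.to_csv(paths["covariates"], index=False)
    cohort.episodes.to_csv(paths["episodes"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths


def config_to_yaml(config: SyntheticCohortConfig, path) -> None:
    d = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    d["curves"] = [list(map(float, c)) for c in config.curves]
    d["binary_probs"] = {k: list(map(float, v)) for k, v in config.binary_probs.items()}
    d["categorical_probs"] = {
        k: {"levels": list(v[0]), "probs": [list(map(float, p)) for p in v[1]]}
        for k, v in config.categorical_probs.items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> SyntheticCohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["bounds"] = tuple(d.get("bounds", (0.0, 200.0)))
    cat = d.get("categorical_probs") or {}
    d["categorical_probs"] = {
        k: (tuple(v["levels"]), tuple(tuple(p) for p in v["probs"])) for k, v in cat.items()
    }
    return SyntheticCohortConfig(**d)


def with_seed(config: SyntheticCohortConfig, seed: int) -> SyntheticCohortConfig:
    return replace(config, seed=seed)
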