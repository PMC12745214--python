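"""Per-trajectory-group rehabilitation efficacy and cost indices.

Three ratios summarise cost-effectiveness per group, each computed from
group MEANS (not means of per-patient ratios — the convention under which
the published index rows are internally consistent; a per-patient variant is
available for sensitivity analysis):

* effect index   = 100 x mean improvement / mean admission score   [%]
* efficiency index = effect index / mean length of stay            [%/day]
* benefit index  = mean treatment cost / mean improvement          [cost per
  1-point improvement of the total disability score]

plus the daily treatment cost = mean cost / mean length of stay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


def daily_cost(cost_mean: float, los_mean: float) -> float:
    """Mean treatment cost per hospital day."""
    if los_mean <= 0:
        raise ValueError("length of stay must be > 0")
    return cost_mean / los_mean


def effect_index(improvement: float, admission_mean: float) -> float:
    """Percentage functional gain relative to the admission level."""
    if admission_mean <= 0:
        raise ValueError("admission mean must be > 0")
    return 100.0 * improvement / admission_mean


def efficiency_index(effect_index_pct: float, los_mean: float) -> float:
    """Effect index per hospital day (percentage points per day)."""
    if los_mean <= 0:
        raise ValueError("length of stay must be > 0")
    return effect_index_pct / los_mean


def benefit_index(cost_mean: float, improvement: float) -> float:
    """Treatment cost per 1-point improvement of the total score."""
    if improvement == 0:
        warnings.warn("zero improvement: benefit index undefined")
        return float("nan")
    if improvement < 0:
        warnings.warn("negative improvement: benefit index not meaningful")
    return cost_mean / improvement


@dataclass
class GroupCostSummary:
    group: int
    n: int
    admission_mean: float
    discharge_mean: float
    improvement: float
    los_mean: float
    cost_mean: float
    daily_cost: float
    effect_index: float
    efficiency_index: float
    benefit_index: float


def summary_from_means(
    group: int,
    admission_mean: float,
    discharge_mean: float,
    los_mean: float,
    cost_mean: float,
    n: int = 0,
) -> GroupCostSummary:
    """All four indices from group-level means (e.g. published values)."""
    improvement = admission_mean - discharge_mean
    eff = effect_index(improvement, admission_mean)
    return GroupCostSummary(
        group=group,
        n=n,
        admission_mean=admission_mean,
        discharge_mean=discharge_mean,
        improvement=improvement,
        los_mean=los_mean,
        cost_mean=cost_mean,
        daily_cost=daily_cost(cost_mean, los_mean),
        effect_index=eff,
        efficiency_index=efficiency_index(eff, los_mean),
        benefit_index=benefit_index(cost_mean, improvement),
    )


def group_cost_table(
    totals: pd.DataFrame,
    episodes: pd.DataFrame,
    assignment: pd.DataFrame,
    per_patient_ratios: bool = False,
) -> list[GroupCostSummary]:
    """Group-wise efficacy/cost summary of a cohort.

    ``totals``: long table (patient_id, day, total); the first and last
    assessment per patient provide the admission and discharge scores.
    ``episodes``: per-patient (patient_id, length_of_stay, cost).
    ``assignment``: per-patient (patient_id, group) with groups labelled from 1.

    With ``per_patient_ratios=True`` the indices are means of per-patient
    ratios instead of ratios of group means (sensitivity analysis).
    """
    t = totals.sort_values(["patient_id", "day"])
    first = t.groupby("patient_id", sort=True).first()["total"]
    last = t.groupby("patient_id", sort=True).last()["total"]
    pids = set(first.index)
    for name, frame in (("episodes", episodes), ("assignment", assignment)):
        if set(frame["patient_id"]) != pids:
            odd = sorted(set(frame["patient_id"]) ^ pids)
            raise ValueError(f"{name} does not cover the cohort (mismatch: {odd[:5]})")
    per = pd.DataFrame({"admission": first, "discharge": last}).reset_index()
    per = per.merge(episodes, on="patient_id", validate="one_to_one")
    per = per.merge(assignment[["patient_id", "group"]], on="patient_id", validate="one_to_one")

    out: list[GroupCostSummary] = []
    for g, sub in per.groupby("group", sort=True):
        if len(sub) == 0:
            warnings.warn(f"group {g}: no members, omitted")
            continue
        adm = float(sub["admission"].mean())
        dis = float(sub["discharge"].mean())
        los = float(sub["length_of_stay"].mean())
        cost = float(sub["cost"].mean())
        if per_patient_ratios:
            imp = sub["admission"] - sub["discharge"]
            eff = float((100.0 * imp / sub["admission"]).mean())
            s = GroupCostSummary(
                group=int(g), n=len(sub),
                admission_mean=adm, discharge_mean=dis, improvement=adm - dis,
                los_mean=los, cost_mean=cost,
                daily_cost=float((sub["cost"] / sub["length_of_stay"]).mean()),
                effect_index=eff,
                efficiency_index=float(
                    (100.0 * imp / sub["admission"] / sub["length_of_stay"]).mean()
                ),
                benefit_index=float((sub["cost"] / imp.where(imp != 0)).mean()),
            )
        else:
            s = summary_from_means(int(g), adm, dis, los, cost, n=len(sub))
        out.append(s)
    return out


def cost_table_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
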