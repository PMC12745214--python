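"""The 20-item ICF disability instrument and its item-level cohort summaries.

The instrument scores 20 ICF categories on a 0-10 numerical rating scale
(0 = no problem, 10 = complete dysfunction), giving a total disability score
on 0-200.  Items span three functional areas -- self-care & activities (11
items), cognition & perception (5) and emotion & spirit (4) -- and four of
them (b130, b134, b152, b280) are self-reported rather than observer-rated.

This module holds the item catalogue, the longitudinal assessment record,
validation of a cohort of records, and the per-item dysfunction/improvement
summary computed between admission and the study endpoint.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class FunctionalArea(enum.Enum):
    SELF_CARE_ACTIVITIES = "self_care_activities"
    COGNITION_PERCEPTION = "cognition_perception"
    EMOTION_SPIRIT = "emotion_spirit"


class RatingMode(enum.Enum):
    SELF_REPORTED = "self_reported"
    OBSERVER_RATED = "observer_rated"


class Stage(enum.Enum):
    ADMISSION = "admission"
    INTERIM = "interim"
    ENDPOINT = "endpoint"


@dataclass(frozen=True)
class IcfItem:
    """One instrument item: an ICF category code plus its classification."""

    code: str
    name: str
    functional_area: FunctionalArea
    rating_mode: RatingMode


_SELF_REPORTED = {"b130", "b134", "b152", "b280"}

_CATALOGUE = [
    # self-care and activities (11 items)
    ("d450", "Walking", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d455", "Moving around", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("b455", "Exercise tolerance functions", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("b525", "Defecation functions", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("b620", "Urination functions", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d530", "Toileting", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d230", "Carrying out daily routine", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d510", "Washing oneself", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d520", "Caring for body parts", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d540", "Dressing", FunctionalArea.SELF_CARE_ACTIVITIES),
    ("d550", "Eating", FunctionalArea.SELF_CARE_ACTIVITIES),
    # cognition and perception (5 items)
    ("b114", "Orientation functions", FunctionalArea.COGNITION_PERCEPTION),
    ("b144", "Memory functions", FunctionalArea.COGNITION_PERCEPTION),
    ("b210", "Seeing functions", FunctionalArea.COGNITION_PERCEPTION),
    ("b230", "Hearing functions", FunctionalArea.COGNITION_PERCEPTION),
    ("d710", "Basic interpersonal interactions", FunctionalArea.COGNITION_PERCEPTION),
    # emotion and spirit (4 items)
    ("b130", "Energy and drive functions", FunctionalArea.EMOTION_SPIRIT),
    ("b152", "Emotional functions", FunctionalArea.EMOTION_SPIRIT),
    ("b280", "Sensation of pain", FunctionalArea.EMOTION_SPIRIT),
    ("b134", "Sleep functions", FunctionalArea.EMOTION_SPIRIT),
]

ITEMS: tuple[IcfItem, ...] = tuple(
    IcfItem(
        code=code,
        name=name,
        functional_area=area,
        rating_mode=(
            RatingMode.SELF_REPORTED if code in _SELF_REPORTED else RatingMode.OBSERVER_RATED
        ),
    )
    for code, name, area in _CATALOGUE
)

ITEM_CODES: tuple[str, ...] = tuple(item.code for item in ITEMS)

SCORE_MIN, SCORE_MAX = 0, 10
TOTAL_MIN, TOTAL_MAX = 0, len(ITEMS) * SCORE_MAX


class SchemaError(ValueError):
    """An assessment record violates the instrument schema."""


class PairingError(ValueError):
    """Admission and endpoint records cannot be paired by patient."""


@dataclass
class AssessmentRecord:
    """One patient x one day: the 20 item scores of a single assessment."""

    patient_id: str
    day: int
    scores: Mapping[str, int]
    stage: Stage | None = None

    def validate(self) -> None:
        missing = [c for c in ITEM_CODES if c not in self.scores]
        if missing:
            raise SchemaError(f"missing item scores for: {', '.join(missing)}")
        unknown = [c for c in self.scores if c not in ITEM_CODES]
        if unknown:
            raise SchemaError(f"unknown item codes: {', '.join(unknown)}")
        for code in ITEM_CODES:
            v = self.scores[code]
            if not (isinstance(v, (int,)) or float(v).is_integer()):
                raise SchemaError(f"item {code}: score {v!r} is not an integer")
            if not SCORE_MIN <= int(v) <= SCORE_MAX:
                raise SchemaError(f"item {code}: score {v} outside [0, 10]")
        if self.day < 0:
            raise SchemaError(f"day {self.day} is negative")


def total_score(record: AssessmentRecord) -> int:
    """Total disability score: the sum of the 20 item scores, in [0, 200]."""
    missing = [c for c in ITEM_CODES if c not in record.scores]
    if missing:
        raise SchemaError(f"missing item scores for: {', '.join(missing)}")
    return int(sum(int(record.scores[c]) for c in ITEM_CODES))


@dataclass
class ItemSummary:
    """Per-item dysfunction and improvement summary between admission and endpoint.

    ``n_dysfunction`` counts patients with a nonzero admission score;
    ``n_improved`` counts, among those, patients whose endpoint score is
    strictly below their admission score.  Means are taken over all patients,
    and ``improvement_rate`` is the mean improvement as a percentage of the
    mean admission score -- the convention under which the percentage columns
    of the published item table are internally consistent.
    """

    item: IcfItem
    n_dysfunction: int
    pct_dysfunction: float
    n_improved: int
    pct_improved: float
    mean_admission: float
    mean_discharge: float
    improvement: float
    improvement_rate: float


def item_cohort_summary(
    admissions: Sequence[AssessmentRecord],
    endpoints: Sequence[AssessmentRecord],
) -> list[ItemSummary]:
    """Item-level cohort summary from paired admission and endpoint records.

    Records are paired by ``patient_id``; every patient must appear exactly
    once in each list.
    """
    if not admissions:
        raise PairingError("empty cohort")
    adm = {r.patient_id: r for r in admissions}
    end = {r.patient_id: r for r in endpoints}
    if len(adm) != len(admissions) or len(end) != len(endpoints):
        raise PairingError("duplicate patient_id in admissions or endpoints")
    if set(adm) != set(end):
        odd = sorted(set(adm) ^ set(end))
        raise PairingError(f"unpaired patients: {', '.join(map(str, odd))}")

    n = len(adm)
    out: list[ItemSummary] = []
    for item in ITEMS:
        a = [int(adm[p].scores[item.code]) for p in adm]
        e = [int(end[p].scores[item.code]) for p in adm]
        dys = [i for i, v in enumerate(a) if v > 0]
        n_dys = len(dys)
        n_imp = sum(1 for i in dys if e[i] < a[i])
        mean_a = sum(a) / n
        mean_e = sum(e) / n
        improvement = mean_a - mean_e
        out.append(
            ItemSummary(
                item=item,
                n_dysfunction=n_dys,
                pct_dysfunction=100.0 * n_dys / n,
                n_improved=n_imp,
                pct_improved=(100.0 * n_imp / n_dys) if n_dys else 0.0,
                mean_admission=mean_a,
                mean_discharge=mean_e,
                improvement=improvement,
                improvement_rate=(100.0 * improvement / mean_a) if mean_a > 0 else 0.0,
            )
        )
    return out


def summary_frame(summaries: Iterable[ItemSummary]) -> pd.DataFrame:
    """Item summaries as a table shaped like the published item table."""
    rows = [
        {
            "functional_area": s.item.functional_area.value,
            "code": s.item.code,
            "name": s.item.name,
            "n_dysfunction": s.n_dysfunction,
            "pct_dysfunction": s.pct_dysfunction,
            "n_improved": s.n_improved,
            "pct_improved": s.pct_improved,
            "mean_admission": s.mean_admission,
            "mean_discharge": s.mean_discharge,
            "improvement": s.improvement,
            "improvement_rate": s.improvement_rate,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Report-only cohort validation: nothing raises, everything is counted."""

    too_few_assessments: list[str] = field(default_factory=list)
    out_of_range: list[tuple[str, int, str, int]] = field(default_factory=list)
    duplicated_days: list[tuple[str, int]] = field(default_factory=list)
    missing_items: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return (
            len(self.too_few_assessments)
            + len(self.out_of_range)
            + len(self.duplicated_days)
            + len(self.missing_items)
        )

    @property
    def clean(self) -> bool:
        return self.n_violations == 0

    def counts(self) -> dict[str, int]:
        return {
            "too_few_assessments": len(self.too_few_assessments),
            "out_of_range": len(self.out_of_range),
            "duplicated_days": len(self.duplicated_days),
            "missing_items": len(self.missing_items),
        }


def validate_cohort(records: Sequence[AssessmentRecord]) -> ValidationReport:
    """Flag patients with <2 assessments, out-of-range scores, duplicate days."""
    report = ValidationReport()
    by_patient: dict[str, list[AssessmentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for pid, recs in by_patient.items():
        if len(recs) < 2:
            report.too_few_assessments.append(pid)
        days = [r.day for r in recs]
        for d in sorted({d for d in days if days.count(d) > 1}):
            report.duplicated_days.append((pid, d))
        for r in recs:
            for code in ITEM_CODES:
                if code not in r.scores:
                    report.missing_items.append((pid, r.day, code))
                else:
                    v = int(r.scores[code])
                    if not SCORE_MIN <= v <= SCORE_MAX:
                        report.out_of_range.append((pid, r.day, code, v))
    return report


def assign_stages(records: Sequence[AssessmentRecord]) -> None:
    """Set stage in place: admission at each patient's first day, endpoint at
    the last available assessment (whatever the discharge reason), interim
    in between."""
    by_patient: dict[str, list[AssessmentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for recs in by_patient.values():
        recs.sort(key=lambda r: r.day)
        for r in recs:
            r.stage = Stage.INTERIM
        recs[0].stage = Stage.ADMISSION
        recs[-1].stage = Stage.ENDPOINT


# ---------------------------------------------------------------------------
# CSV interface: long format, one row per patient x day, item columns named
# by ICF code.  Header is validated strictly.

def read_assessments(path) -> list[AssessmentRecord]:
    df = pd.read_csv(path)
    expected = ["patient_id", "day", *ITEM_CODES]
    if list(df.columns) != expected:
        raise SchemaError(
            f"bad assessment header: expected {expected}, got {list(df.columns)}"
        )
    records = [
        AssessmentRecord(
            patient_id=str(row.patient_id),
            day=int(row.day),
            scores={c: int(getattr(row, c)) for c in ITEM_CODES},
        )
        for row in df.itertuples(index=False)
    ]
    assign_stages(records)
    return records


def write_assessments(records: Sequence[AssessmentRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "day": r.day, **{c: int(r.scores[c]) for c in ITEM_CODES}}
        for r in sorted(records, key=lambda r: (str(r.patient_id), r.day))
    ]
    pd.DataFrame(rows, columns=["patient_id", "day", *ITEM_CODES]).to_csv(path, index=False)


def split_admission_endpoint(
    records: Sequence[AssessmentRecord],
) -> tuple[list[AssessmentRecord], list[AssessmentRecord]]:
    """First and last assessment per patient, in a stable patient order."""
    by_patient: dict[str, list[AssessmentRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    admissions, endpoints = [], []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: r.day)
        admissions.append(recs[0])
        endpoints.append(recs[-1])
    return admissions, endpoints


def totals_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    """Long table (patient_id, day, total) of total disability scores."""
    rows = [
        {"patient_id": r.patient_id, "day": r.day, "total": total_score(r)}
        for r in sorted(records, key=lambda r: (str(r.patient_id), r.day))
    ]
    return pd.DataFrame(rows)
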