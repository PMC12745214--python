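"""End-to-end orchestration of the trajectory analysis.

One call runs the full sequence on a cohort (loaded from the three input
CSVs or generated synthetically): cohort validation, item-level instrument
summaries, censored-normal GBTM fitting with the AvePP/share/BIC selection
rule, univariate group comparisons, proportional-odds regression of group
membership, and the per-group cost-effectiveness table.  Every stage writes
a plain CSV (or YAML) output; the run report lists each emitted file with a
checksum so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import math
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import compare, costs, gbtm, items, simulate


def required_sample_size(n_vars: int, multiplier: float = 5, dropout_rate: float = 0.10) -> int:
    """Minimum cohort size: ``floor(n_vars * multiplier / (1 - dropout))``.

    The events-per-variable rule of 5-10 subjects per independent variable,
    inflated for the anticipated dropout fraction.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    return math.floor(n_vars * multiplier / (1.0 - dropout_rate))


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    synthetic: bool = True
    cohort: simulate.SyntheticCohortConfig | None = None
    assessments_path: str | None = None
    covariates_path: str | None = None
    episodes_path: str | None = None
    k_range: Sequence[int] = (2, 3, 4, 5)
    poly_order: int = 2
    n_starts: int = 2
    avepp_threshold: float = 0.7
    share_threshold: float = 0.05
    alpha: float = 0.05
    always_include: Sequence[str] = ("surgery",)
    verbosity: int = 1

    def validate(self) -> None:
        if not self.k_range:
            raise ValueError("k_range must be nonempty")
        for t in (self.avepp_threshold, self.share_threshold, self.alpha):
            if not 0 < t < 1:
                raise ValueError("thresholds must be in (0, 1)")
        if not self.synthetic:
            for p in (self.assessments_path, self.covariates_path, self.episodes_path):
                if p is None:
                    raise FileNotFoundError("non-synthetic runs need all three input paths")
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cohort = d.pop("cohort", None)
        cfg = cls(**d)
        if cohort is not None:
            if "bounds" in cohort:
                cohort["bounds"] = tuple(cohort["bounds"])
            cfg.cohort = simulate.SyntheticCohortConfig(**cohort)
        return cfg


@dataclass
class StageStatus:
    name: str
    status: str  # "ok" | "failed" | "skipped"
    seconds: float = 0.0
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    config: dict
    stages: list[StageStatus] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages)

    def to_yaml(self, path) -> None:
        d = {
            "versions": self.versions,
            "config": self.config,
            "stages": [s.__dict__ for s in self.stages],
            "manifest": self.manifest,
            "ok": self.ok,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "icftraj": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


CONTINUOUS_VARS = ("age",)
NONNORMAL_VARS = ("disease_course",)
CATEGORICAL_VARS = (
    "female", "hypertension", "diabetes", "education", "diagnosis",
    "emotional_disorders", "shoulder_pain", "dysphagia", "urine_bag_or_diaper",
    "assistive_device", "surgery", "ataxia", "hemiplegic_side",
    "cognitive_impairment", "aphasia",
)


def run(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; a failed stage skips everything after it."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: str(v) for k, v in config.__dict__.items()},
                       versions=_versions())
    state: dict = {}
    failed = False

    def stage(name):
        def deco(fn):
            nonlocal failed
            st = StageStatus(name=name, status="skipped")
            if not failed:
                t0 = time.perf_counter()
                try:
                    fn(st)
                    st.status = "ok"
                except Exception as exc:  # recorded, downstream skipped
                    st.status = "failed"
                    st.error = f"{type(exc).__name__}: {exc}"
                    if config.verbosity > 1:
                        traceback.print_exc()
                    failed = True
                st.seconds = time.perf_counter() - t0
            report.stages.append(st)
            if config.verbosity:
                print(f"[{st.status:>7}] {name} ({st.seconds:.1f}s)")

        return deco

    def emit(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(obj)
        report.manifest[name] = _sha256(path)

    @stage("acquire")
    def _(st):
        if config.synthetic:
            cfg = config.cohort or simulate.default_stroke_config(seed=config.seed)
            cfg = simulate.with_seed(cfg, config.seed)
            cohort = simulate.generate(cfg)
            state["assessments"] = cohort.assessments
            state["covariates"] = cohort.covariates
            state["episodes"] = cohort.episodes
            emit("truth.csv", cohort.truth)
        else:
            state["assessments"] = items.read_assessments(config.assessments_path)
            state["covariates"] = pd.read_csv(config.covariates_path)
            state["episodes"] = pd.read_csv(config.episodes_path)
        items.write_assessments(state["assessments"], outdir / "assessments.csv")
        report.manifest["assessments.csv"] = _sha256(outdir / "assessments.csv")
        emit("covariates.csv", state["covariates"])
        emit("episodes.csv", state["episodes"])

    @stage("validate")
    def _(st):
        rep = items.validate_cohort(state["assessments"])
        st.warnings += [f"{k}: {v}" for k, v in rep.counts().items() if v]
        emit("validation.yaml", yaml.safe_dump(rep.counts()))

    @stage("item_summary")
    def _(st):
        adm, end = items.split_admission_endpoint(state["assessments"])
        summaries = items.item_cohort_summary(adm, end)
        emit("table1_items.csv", items.summary_frame(summaries))

    @stage("trajectories")
    def _(st):
        totals = items.totals_frame(state["assessments"])
        sel = gbtm.select_model(
            totals,
            K_range=config.k_range,
            order_menu=config.poly_order,
            avepp_threshold=config.avepp_threshold,
            share_threshold=config.share_threshold,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        state["selection"] = sel
        state["model"] = sel.chosen
        st.warnings += sel.chosen.warnings
        if not sel.admissible:
            st.warnings.append("no admissible candidate; best-BIC model used")
        emit(
            "selection.csv",
            pd.DataFrame(
                {
                    "n_groups": [c.spec.n_groups for c in sel.candidates],
                    "bic": [c.bic for c in sel.candidates],
                    "min_avepp": [c.min_avepp for c in sel.candidates],
                    "min_share": [c.min_share for c in sel.candidates],
                    "admissible": [c.admissible for c in sel.candidates],
                }
            ),
        )
        gbtm.model_to_yaml(sel.chosen, outdir / "model.yaml")
        report.manifest["model.yaml"] = _sha256(outdir / "model.yaml")
        emit("posteriors.csv", gbtm.posteriors_frame(sel.chosen))
        emit("trajectory_curves.csv", gbtm.curves_frame(sel.chosen))

    @stage("univariate")
    def _(st):
        model = state["model"]
        cov = state["covariates"].copy()
        groups = gbtm.posteriors_frame(model)[["patient_id", "group"]]
        cov = cov.merge(groups, on="patient_id", validate="one_to_one")
        state["cov_grouped"] = cov
        cats = [v for v in CATEGORICAL_VARS if v in cov.columns]
        tab = compare.univariate_table(
            cov,
            continuous=[v for v in CONTINUOUS_VARS if v in cov.columns],
            nonnormal=[v for v in NONNORMAL_VARS if v in cov.columns],
            categorical=cats,
            seed=config.seed,
        )
        state["univariate"] = tab
        emit("table2_univariate.csv", tab)

    @stage("ordinal_regression")
    def _(st):
        cov = state["cov_grouped"]
        tab = state["univariate"]
        chosen = list(tab.loc[tab["p_value"] <= config.alpha, "variable"])
        for v in config.always_include:
            if v in cov.columns and v not in chosen:
                chosen.append(v)
        if not chosen:
            st.warnings.append("no significant univariate predictors; skipping model")
            return
        fit = compare.ordinal_logit_fit(cov, predictors=chosen)
        st.warnings += fit.warnings
        emit("table3_ordinal.csv", fit.to_frame())
        emit(
            "table3_model.yaml",
            yaml.safe_dump(
                {
                    "predictors": chosen,
                    "thresholds": [float(v) for v in fit.thresholds],
                    "loglik": fit.loglik,
                    "lr_chi2": fit.lr_chi2,
                    "lr_df": fit.lr_df,
                    "lr_p": fit.lr_p,
                    "parallel_chi2": fit.parallel_chi2,
                    "parallel_df": fit.parallel_df,
                    "parallel_p": fit.parallel_p,
                    "deviance": fit.deviance,
                    "deviance_p": fit.deviance_p,
                    "pearson": fit.pearson,
                    "pearson_p": fit.pearson_p,
                },
                sort_keys=False,
            ),
        )

    @stage("cost_effectiveness")
    def _(st):
        model = state["model"]
        totals = items.totals_frame(state["assessments"])
        assignment = gbtm.posteriors_frame(model)[["patient_id", "group"]]
        table = costs.group_cost_table(totals, state["episodes"], assignment)
        emit("table4_cost_effectiveness.csv", costs.cost_table_frame(table))

    report.versions = _versions()
    report.to_yaml(outdir / "run_report.yaml")
    return report
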