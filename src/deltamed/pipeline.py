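"""End-to-end study orchestration.

``run_study`` executes simulate -> missingness -> panel QC -> delta/g'
measurement model -> composites -> descriptive table -> base (a-path)
model -> ROC validation -> per-protein mediation screen -> split-half
replication, as a pure function of a :class:`StudyConfig`, optionally
writing every artefact (CSV/JSON) plus a run log to an output
directory.  With simulation ground truth available it appends recovery
diagnostics for the a/b/c paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .delta import DeltaModel, roc_auc, severity_correlation
from .mediation import MediationScreen
from .qc import BiomarkerQC, QcConfig
from .replication import constrained_comparison, split_half
from .mediation import build_mediation_spec
from .simulate import COVARIATES, INDICATORS, SimConfig, inject_missingness, simulate_cohort

logger = logging.getLogger("deltamed")

__all__ = ["StudyConfig", "StudyReport", "descriptive_summary", "run_study"]


@dataclass
class StudyConfig:
    """Everything a study run depends on; fully serializable."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    alpha: float = 0.001  # fixed Bonferroni-style screen threshold
    invariance_alpha: float = 0.05
    gds_threshold: int = 10
    delta_missing: str = "fiml"
    mediation_missing: str = "listwise"
    apply_missingness: bool = True
    use_qc_panel: bool = True
    split_seed: int = 0
    replicate_top: int = 10  # cap on proteins taken to split-half replication

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["c_true"] = [float(x) for x in self.sim.c_true]
        d["sim"]["b_true"] = [float(x) for x in self.sim.b_true]
        d["sim"]["loadings"] = self.sim.loadings.to_dict()
        d["sim"]["covariate_effects"] = self.sim.covariate_effects.to_dict()
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "loadings" in sim:
            sim["loadings"] = pd.DataFrame(sim["loadings"]).reindex(INDICATORS)
        if "covariate_effects" in sim:
            sim["covariate_effects"] = pd.DataFrame(sim["covariate_effects"]).reindex(COVARIATES)
        if "c_true" in sim and sim["c_true"] is not None:
            sim["c_true"] = np.asarray(sim["c_true"], float)
        if "b_true" in sim and sim["b_true"] is not None:
            sim["b_true"] = np.asarray(sim["b_true"], float)
        if "missing_rates" in sim:
            sim["missing_rates"] = dict(sim["missing_rates"])
        if "batch_shifts" in sim:
            sim["batch_shifts"] = tuple(sim["batch_shifts"])
        if "diagnosis_fracs" in sim:
            sim["diagnosis_fracs"] = tuple(sim["diagnosis_fracs"])
        qc = dict(d.pop("qc", {}))
        return cls(sim=SimConfig(**sim), qc=QcConfig(**qc), **d)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> StudyConfig:
    """Small demonstration study: n=2000, 20 proteins of which 3 are
    designed mediators (plus 2 GDS-only and 2 delta-only proteins)."""
    from .simulate import default_true_paths

    c_true, b_true = default_true_paths(20, n_mediators=3, n_gds_only=2, n_delta_only=2)
    sim = SimConfig(n_subjects=2000, seed=seed, n_proteins=20, c_true=c_true, b_true=b_true)
    return StudyConfig(sim=sim)


def descriptive_summary(cohort: pd.DataFrame, gds_threshold: int = 10) -> dict:
    """Table-1-style descriptives plus the clinically-depressed fraction.

    Returns a dict with the per-variable table (n/mean/SD), the count
    and percentage of GDS-observed subjects at or above the threshold,
    and the complete-case count over GDS, covariates and indicators.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    num = cohort.select_dtypes(include=[np.number])
    table = pd.DataFrame(
        {"n": num.notna().sum(), "mean": num.mean(), "sd": num.std(ddof=1)}
    )
    out = {"table": table, "n_subjects": len(cohort)}
    if "gds" in cohort.columns:
        gds = cohort["gds"].dropna()
        out["gds_observed"] = int(len(gds))
        if len(gds):
            n_dep = int((gds >= gds_threshold).sum())
            out["gds_depressed_n"] = n_dep
            out["gds_depressed_pct"] = 100.0 * n_dep / len(gds)
        else:
            out["gds_depressed_n"] = 0
            out["gds_depressed_pct"] = float("nan")
    core = [c for c in ["gds"] + COVARIATES + INDICATORS if c in cohort.columns]
    out["complete_cases"] = int(cohort[core].dropna().shape[0])
    return out


@dataclass
class StudyReport:
    config_hash: str
    descriptives: dict
    delta_fit_indices: dict
    delta_determinacy: dict
    base_a_path: dict
    roc: dict
    screen_table: pd.DataFrame
    class1: list[str]
    delta_only: list[str]
    gds_only: list[str]
    replication: pd.DataFrame
    recovery: dict | None

    def to_dict(self) -> dict:
        d = {
            "config_hash": self.config_hash,
            "descriptives": {
                k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                for k, v in self.descriptives.items()
            },
            "delta_fit_indices": self.delta_fit_indices,
            "delta_determinacy": self.delta_determinacy,
            "base_a_path": self.base_a_path,
            "roc": self.roc,
            "screen": self.screen_table.to_dict(orient="index"),
            "class1": self.class1,
            "delta_only": self.delta_only,
            "gds_only": self.gds_only,
            "replication": self.replication.to_dict(orient="index"),
            "recovery": self.recovery,
        }
        return d


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the full analysis sequence for one configuration."""
    if config.sim.n_proteins == 0:
        raise ValueError("study needs at least one protein in the panel")
    t0 = time.time()
    stage_times = {}
    chash = config.hash()

    def _stage(name):
        stage_times[name] = time.time() - t0

    logger.info("run %s: simulating cohort (n=%d)", chash, config.sim.n_subjects)
    cohort = simulate_cohort(config.sim)
    if config.apply_missingness:
        cohort = inject_missingness(cohort, config.sim)
    _stage("simulate")

    # analysis table: observed covariates/GDS/indicators + QC'd panel
    analysis = cohort.observed.drop(columns=cohort.protein_columns).copy()
    if config.use_qc_panel:
        qc = BiomarkerQC(config.qc).fit(cohort.raw_panel)
        panel = qc.panel_
        analysis = analysis.merge(panel, left_on="subject_id", right_index=True, how="left")
        qc_report = qc.report_
    else:
        analysis = cohort.observed.copy()
        qc_report = None
    proteins = [c for c in analysis.columns if c.startswith("protein_")]
    _stage("qc")

    desc = descriptive_summary(analysis, config.gds_threshold)

    dm = DeltaModel(missing=config.delta_missing).fit(analysis)
    scores = dm.transform(analysis)
    analysis["deq_w2"] = scores["deq"]
    analysis["gprime_w2"] = scores["gprime"]
    _stage("delta")

    # base model: GDS direct association with the Wave-2 composite,
    # adjusted for the covariates but with no mediator in the system
    from scipy import stats as _st

    from .sem import fit_sem
    from .sem.model import Term
    from .simulate import standardize

    covs = [c for c in COVARIATES if c in analysis.columns]
    analysis["gds_z"] = np.nan
    gds_obs = analysis["gds"].notna()
    analysis.loc[gds_obs, "gds_z"] = standardize(analysis.loc[gds_obs, "gds"])
    from .sem.model import SemModelSpec as _Spec

    base_spec = _Spec(
        terms=[Term("deq_w2", "~", "gds_z", tag="a")]
        + [Term("deq_w2", "~", cv) for cv in covs],
        latents=[],
    )
    base = fit_sem(base_spec, analysis, missing=config.mediation_missing)
    a_est, a_se = base.estimates["a"], base.se.get("a", np.nan)
    base_a = {
        "a": a_est,
        "se": a_se,
        "p": float(2.0 * _st.norm.sf(abs(a_est / a_se))) if a_se > 0 else float("nan"),
        "n": base.n,
    }
    _stage("base")

    ad_nc = analysis[analysis["diagnosis"].isin(["AD", "NC"])]
    roc_deq = roc_auc(ad_nc["deq_w2"], ad_nc["diagnosis"] == "AD")
    roc_gp = roc_auc(ad_nc["gprime_w2"], ad_nc["diagnosis"] == "AD")
    r_cdr, p_cdr = severity_correlation(analysis["deq_w2"], analysis["cdr_sb"])
    roc = {
        "deq_auc": roc_deq.auc,
        "deq_ci": [roc_deq.ci_low, roc_deq.ci_high],
        "deq_orientation": roc_deq.orientation,
        "gprime_auc": roc_gp.auc,
        "gprime_ci": [roc_gp.ci_low, roc_gp.ci_high],
        "cdr_r": r_cdr,
        "cdr_p": p_cdr,
    }
    _stage("roc")

    screen = MediationScreen(
        proteins=tuple(proteins),
        alpha=config.alpha,
        missing=config.mediation_missing,
    ).fit(analysis)
    table = screen.summary_
    class1 = screen.class1_
    delta_only = list(table.index[table["class"] == "delta_only"])
    gds_only = list(table.index[table["class"] == "gds_only"])
    _stage("screen")

    # split-half replication of the Class-1 mediators
    g1, g2 = split_half(analysis, seed=config.split_seed)
    rep_rows = []
    for protein in class1[: config.replicate_top]:
        g1p = g1.copy()
        g2p = g2.copy()
        from .simulate import standardize

        for g in (g1p, g2p):
            obs = g["gds"].notna()
            g["gds_z"] = np.nan
            g.loc[obs, "gds_z"] = standardize(g.loc[obs, "gds"])
        spec = build_mediation_spec(protein, "gds_z", "deq_w2",
                                    [c for c in COVARIATES if c in analysis.columns])
        inv = constrained_comparison(
            spec, g1p, g2p, ["a", "b", "c"],
            missing=config.mediation_missing, alpha=config.invariance_alpha,
            seed=config.split_seed,
        )
        rep_rows.append(
            {
                "protein": protein,
                "delta_chi2": inv.delta_chi2,
                "delta_df": inv.delta_df,
                "p": inv.p,
                "generalizes": inv.generalizes,
                "a_constrained": inv.group1_estimates.get("a", np.nan),
                "b_constrained": inv.group1_estimates.get("b", np.nan),
                "c_constrained": inv.group1_estimates.get("c", np.nan),
            }
        )
    replication = pd.DataFrame(rep_rows).set_index("protein") if rep_rows else pd.DataFrame()
    _stage("replication")

    recovery = None
    truth = cohort.truth
    if truth is not None:
        est_c = table["path_c"].reindex([f"protein_{j + 1:03d}" for j in range(len(truth.c_true))])
        ok = est_c.notna().to_numpy()
        bias_c = float(np.nanmean(est_c.to_numpy()[ok] - truth.c_true[ok])) if ok.any() else np.nan
        se_c = table["se_c"].reindex(est_c.index).to_numpy()
        cover_c = (
            float(np.nanmean(np.abs(est_c.to_numpy() - truth.c_true) <= 3 * se_c))
            if ok.any()
            else np.nan
        )
        designed = [p for j, p in enumerate(est_c.index)
                    if truth.c_true[j] != 0 and truth.b_true[j] != 0]
        sens = (
            float(np.mean([p in class1 for p in designed])) if designed else float("nan")
        )
        recovery = {
            "bias_c": bias_c,
            "coverage_c_3se": cover_c,
            "designed_mediators": designed,
            "class1_sensitivity": sens,
        }
    _stage("recovery")

    report = StudyReport(
        config_hash=chash,
        descriptives=desc,
        delta_fit_indices={
            "chi_square": dm.fit_indices_.chi_square,
            "df": dm.fit_indices_.df,
            "cmin_df": dm.fit_indices_.cmin_df,
            "cfi": dm.fit_indices_.cfi,
            "rmsea": dm.fit_indices_.rmsea,
        },
        delta_determinacy=dm.determinacy_.to_dict(),
        base_a_path=base_a,
        roc=roc,
        screen_table=table,
        class1=class1,
        delta_only=delta_only,
        gds_only=gds_only,
        replication=replication,
        recovery=recovery,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(config.to_yaml())
        cohort.observed.to_csv(outdir / "cohort.csv", index=False)
        cohort.raw_panel.to_csv(outdir / "raw_panel.csv", index=False)
        analysis.to_csv(outdir / "analysis_table.csv", index=False)
        table.to_csv(outdir / "mediation_screen.csv")
        if len(replication):
            replication.to_csv(outdir / "replication.csv")
        if qc_report is not None:
            (outdir / "qc_report.json").write_text(qc_report.to_json(indent=2))
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=_json_default)
        )
        import platform

        log = {
            "config_hash": chash,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
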