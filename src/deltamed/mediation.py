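"""Per-protein longitudinal mediation screen.

For each serum protein the three-path model of the screen is the
recursive system

    protein ~ c * GDS + covariates          (exposure -> mediator)
    dEQ_w2  ~ a * GDS + b * protein + covariates

fitted simultaneously by maximum likelihood (full-information over
incomplete rows when requested); on complete data the path estimates
coincide with equation-by-equation least squares.  The indirect effect
c*b is tested with the product-of-coefficients (MacKinnon/Sobel) z
statistic, screened at a fixed Bonferroni-style threshold (p < 0.001),
and each protein is assigned one of four classes: *mediator* (both b
and c significant), *gds_only* (c only), *delta_only* (b only) or
*unrelated*.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .sem import FitIndices, SemModelSpec, fit_indices_from, fit_sem
from .sem.model import Term
from .simulate import COVARIATES, standardize

__all__ = [
    "PathEstimates",
    "MediationResult",
    "MediationScreen",
    "fit_mediation_model",
    "mackinnon_z",
    "percent_mediated",
    "classify_protein",
    "screen_panel",
    "results_frame",
]


@dataclass
class PathEstimates:
    """Paths of one protein's mediation model (standardized exposure)."""

    protein: str
    a: float  # exposure -> outcome, adjusted for the mediator
    se_a: float
    b: float  # mediator -> outcome
    se_b: float
    c: float  # exposure -> mediator
    se_c: float
    covariate_slopes: dict[str, float]
    fit: FitIndices | None
    n: int
    converged: bool

    def p_values(self) -> dict[str, float]:
        out = {}
        for path in ("a", "b", "c"):
            est = getattr(self, path)
            se = getattr(self, f"se_{path}")
            out[path] = 2.0 * stats.norm.sf(abs(est / se)) if se and se > 0 else float("nan")
        return out


def build_mediation_spec(
    protein: str,
    exposure: str = "gds_z",
    outcome: str = "deq_w2",
    covariates: list[str] | None = None,
) -> SemModelSpec:
    covs = list(covariates) if covariates is not None else list(COVARIATES)
    terms = [Term(protein, "~", exposure, tag="c")]
    terms += [Term(protein, "~", cv) for cv in covs]
    terms += [Term(outcome, "~", exposure, tag="a"), Term(outcome, "~", protein, tag="b")]
    terms += [Term(outcome, "~", cv) for cv in covs]
    return SemModelSpec(terms=terms, latents=[])


def fit_mediation_model(
    data: pd.DataFrame,
    protein: str,
    exposure: str = "gds",
    outcome: str = "deq_w2",
    covariates: list[str] | None = None,
    missing: str = "listwise",
    alpha: float = 0.001,
) -> PathEstimates:
    """Fit one protein's covariate-adjusted mediation model by ML.

    The exposure is standardized in-sample so path coefficients are in
    standardized-exposure units.  ``missing`` is ``"listwise"`` or
    ``"fiml"``.
    """
    for col in (protein, exposure, outcome):
        if col not in data.columns:
            raise KeyError(f"column {col!r} not found in data")
    covs = list(covariates) if covariates is not None else [
        c for c in COVARIATES if c in data.columns
    ]
    frame = data[[protein, exposure, outcome] + covs].copy().astype(float)
    frame["gds_z"] = np.nan
    obs = frame[exposure].notna()
    frame.loc[obs, "gds_z"] = standardize(frame.loc[obs, exposure])
    spec = build_mediation_spec(protein, "gds_z", outcome, covs)
    fit = fit_sem(spec, frame, missing=missing)
    est, se = fit.estimates, fit.se
    cov_slopes = {
        k: v for k, v in est.items() if k.startswith("beta_") and not k.endswith("gds_z")
    }
    indices = fit_indices_from(fit) if fit.df > 0 else None
    return PathEstimates(
        protein=protein,
        a=est["a"],
        se_a=se.get("a", float("nan")),
        b=est["b"],
        se_b=se.get("b", float("nan")),
        c=est["c"],
        se_c=se.get("c", float("nan")),
        covariate_slopes=cov_slopes,
        fit=indices,
        n=fit.n,
        converged=fit.converged,
    )


MackinnonResult = namedtuple("MackinnonResult", ["indirect", "se", "z", "p"])


def mackinnon_z(c, se_c, b, se_b, exact_term: bool = False) -> MackinnonResult:
    """Product-of-coefficients test of the indirect effect c*b.

    First-order delta-method standard error
    sqrt(b^2 se_c^2 + c^2 se_b^2); ``exact_term`` adds the
    second-order se_c^2 se_b^2 term.  Two-sided normal p.  Accepts
    scalars or arrays (broadcast).
    """
    c = np.asarray(c, float)
    b = np.asarray(b, float)
    se_c = np.asarray(se_c, float)
    se_b = np.asarray(se_b, float)
    if np.any(se_c < 0) or np.any(se_b < 0):
        raise ValueError("standard errors must be non-negative")
    indirect = c * b
    var = b**2 * se_c**2 + c**2 * se_b**2
    if exact_term:
        var = var + se_c**2 * se_b**2
    se = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, indirect / np.where(se > 0, se, 1.0), np.nan)
        z = np.where((se == 0) & (indirect == 0), np.nan, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(z) == 0:
        return MackinnonResult(float(indirect), float(se), float(z), float(p))
    return MackinnonResult(indirect, se, z, p)


def percent_mediated(direct_a, indirect) -> float:
    """Share of the total exposure effect carried through the mediator:
    100 |indirect| / (|indirect| + |direct|); undefined when both are 0."""
    direct_a = np.asarray(direct_a, float)
    indirect = np.asarray(indirect, float)
    if not (np.all(np.isfinite(direct_a)) and np.all(np.isfinite(indirect))):
        raise ValueError("inputs must be finite")
    denom = np.abs(indirect) + np.abs(direct_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * np.abs(indirect) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(pct) if np.ndim(pct) == 0 else pct


CLASS_LABELS = ("mediator", "gds_only", "delta_only", "unrelated")


def classify_protein(paths: PathEstimates, alpha: float = 0.001) -> str:
    """Four-class taxonomy from the b/c significance pattern.

    mediator: b and c both significant; gds_only: c only (related to
    depressive symptoms but not to delta); delta_only: b only
    (dementia-severity biomarker independent of the GDS); unrelated:
    neither.
    """
    if not paths.converged:
        raise ValueError(f"model for {paths.protein!r} did not converge")
    p = paths.p_values()
    sig_b = p["b"] < alpha
    sig_c = p["c"] < alpha
    if sig_b and sig_c:
        return "mediator"
    if sig_c:
        return "gds_only"
    if sig_b:
        return "delta_only"
    return "unrelated"


@dataclass
class MediationResult:
    protein: str
    paths: PathEstimates
    indirect: float
    se_indirect: float
    z: float
    p: float
    percent_mediated: float
    class_label: str
    significant_after_bonferroni: bool

    def to_row(self) -> dict:
        return {
            "protein": self.protein,
            "adjusted_path_a": self.paths.a,
            "se_a": self.paths.se_a,
            "path_b": self.paths.b,
            "se_b": self.paths.se_b,
            "path_c": self.paths.c,
            "se_c": self.paths.se_c,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "z": self.z,
            "p": self.p,
            "effect_pct": self.percent_mediated,
            "class": self.class_label,
            "class1": self.class_label == "mediator" and self.significant_after_bonferroni,
        }


def screen_panel(
    data: pd.DataFrame,
    panel: list[str],
    alpha: float = 0.001,
    exposure: str = "gds",
    outcome: str = "deq_w2",
    covariates: list[str] | None = None,
    missing: str = "listwise",
    exact_term: bool = False,
) -> list[MediationResult]:
    """Run the mediation screen over a QC'd protein panel.

    Mediation (Class 1) is declared only for proteins whose b and c
    paths are both significant *and* whose MacKinnon p clears the fixed
    screen threshold ``alpha``.
    """
    if not panel:
        raise ValueError("empty protein panel")
    results = []
    for protein in panel:
        paths = fit_mediation_model(
            data, protein, exposure=exposure, outcome=outcome,
            covariates=covariates, missing=missing,
        )
        if not paths.converged:
            warnings.warn(f"mediation model for {protein!r} did not converge", UserWarning)
        mk = mackinnon_z(paths.c, paths.se_c, paths.b, paths.se_b, exact_term=exact_term)
        label = classify_protein(paths, alpha=alpha) if paths.converged else "unrelated"
        results.append(
            MediationResult(
                protein=protein,
                paths=paths,
                indirect=mk.indirect,
                se_indirect=mk.se,
                z=mk.z,
                p=mk.p,
                percent_mediated=percent_mediated(paths.a, mk.indirect),
                class_label=label,
                significant_after_bonferroni=bool(mk.p < alpha),
            )
        )
    return results


def results_frame(results: list[MediationResult]) -> pd.DataFrame:
    """Tabular roll-up of a screen (one row per protein)."""
    return pd.DataFrame([r.to_row() for r in results]).set_index("protein")


class MediationScreen(BaseEstimator):
    """Panel-wide mediation screen as an estimator.

    ``fit(X)`` expects a table holding the exposure, outcome, covariate
    and protein columns; proteins default to every column starting with
    ``protein_``.
    """

    def __init__(
        self,
        proteins: tuple | None = None,
        alpha: float = 0.001,
        exposure: str = "gds",
        outcome: str = "deq_w2",
        covariates: tuple = tuple(COVARIATES),
        missing: str = "listwise",
        exact_term: bool = False,
    ):
        self.proteins = proteins
        self.alpha = alpha
        self.exposure = exposure
        self.outcome = outcome
        self.covariates = covariates
        self.missing = missing
        self.exact_term = exact_term

    def fit(self, X: pd.DataFrame, y=None):
        panel = list(self.proteins) if self.proteins is not None else [
            c for c in X.columns if c.startswith("protein_")
        ]
        self.results_ = screen_panel(
            X,
            panel,
            alpha=self.alpha,
            exposure=self.exposure,
            outcome=self.outcome,
            covariates=[c for c in self.covariates if c in X.columns],
            missing=self.missing,
            exact_term=self.exact_term,
        )
        self.summary_ = results_frame(self.results_)
        self.class1_ = list(self.summary_.index[self.summary_["class1"]])
        return self
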