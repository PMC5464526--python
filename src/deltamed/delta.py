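"""The delta/g' measurement model and its composite d-scores.

delta is a latent dementia factor: the shared variance between
cognitive performance and informant-rated functional status (IADL).
g' is the orthogonal residual of Spearman's g -- cognitive variance
unrelated to functional impairment.  The bifactor model loads delta on
all five indicators (four cognitive tests + IADL) and g' on the four
cognitive tests only, with cov(delta, g') fixed to zero by definition.

Composites are regression-method factor scores applied to standardized
indicators; they are validated against diagnosis (ROC) and dementia
severity (CDR-SB correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .sem import (
    SemModelSpec,
    factor_determinacy,
    factor_score_weights,
    fit_indices_from,
    fit_sem,
)
from .sem.model import Term
from .simulate import COGNITIVE_INDICATORS, COVARIATES, INDICATORS

__all__ = [
    "build_delta_model",
    "DeltaModel",
    "RocResult",
    "compute_composites",
    "roc_auc",
    "severity_correlation",
]


def build_delta_model(
    indicators: list[str] | None = None,
    adjust_for_covariates: bool = False,
    covariates: list[str] | None = None,
    cognitive: list[str] | None = None,
    free_factor_covariance: bool = False,
) -> SemModelSpec:
    """Two-factor orthogonal (bifactor) specification for delta and g'.

    delta loads on every indicator (the functional scale among them
    anchors it); g' loads on the cognitive indicators only.  The factor
    covariance is fixed to zero -- g' is by construction the residual of
    g orthogonal to delta -- so requesting it free is rejected.  With
    ``adjust_for_covariates`` each indicator additionally receives
    regression paths from the covariates.
    """
    if free_factor_covariance:
        raise ValueError("cov(delta, gprime) is fixed to 0 by definition (orthogonal bifactor)")
    indicators = list(indicators) if indicators is not None else list(INDICATORS)
    cognitive = list(cognitive) if cognitive is not None else [
        i for i in indicators if i in COGNITIVE_INDICATORS
    ]
    missing = [i for i in cognitive if i not in indicators]
    if missing:
        raise ValueError(f"cognitive indicators not in indicator list: {missing}")
    if len(indicators) < 3:
        raise ValueError("need at least three indicators")
    terms = [Term("delta", "=~", ind) for ind in indicators]
    terms += [Term("gprime", "=~", ind) for ind in cognitive]
    terms += [Term("delta", "~~", "gprime", value=0.0)]
    if adjust_for_covariates:
        covariates = list(covariates) if covariates is not None else list(COVARIATES)
        for ind in indicators:
            for cov in covariates:
                terms.append(Term(ind, "~", cov))
    return SemModelSpec(terms=terms, latents=["delta", "gprime"])


class DeltaModel(BaseEstimator, TransformerMixin):
    """Fit the delta/g' bifactor model and score subjects.

    Parameters
    ----------
    indicators, cognitive
        Indicator column names; ``cognitive`` is the subset that loads
        on g' (defaults: the package's five-indicator battery).
    adjust_for_covariates, covariates
        Add covariate -> indicator regression paths.
    missing
        ``"fiml"`` (default) or ``"listwise"``.

    Attributes
    ----------
    sem_fit_ : SemFit
    weights_ : DataFrame       regression factor-score weights
    determinacy_ : Series      Grice determinacy per factor
    fit_indices_ : FitIndices
    mean_, scale_ : Series     standardization applied to indicators
    """

    def __init__(
        self,
        indicators: tuple = tuple(INDICATORS),
        cognitive: tuple = tuple(COGNITIVE_INDICATORS),
        adjust_for_covariates: bool = False,
        covariates: tuple = tuple(COVARIATES),
        missing: str = "fiml",
    ):
        self.indicators = indicators
        self.cognitive = cognitive
        self.adjust_for_covariates = adjust_for_covariates
        self.covariates = covariates
        self.missing = missing

    def fit(self, X: pd.DataFrame, y=None):
        inds = list(self.indicators)
        absent = [c for c in inds if c not in X.columns]
        if absent:
            raise ValueError(f"indicator columns missing from data: {absent}")
        self.spec_ = build_delta_model(
            inds,
            adjust_for_covariates=self.adjust_for_covariates,
            covariates=list(self.covariates),
            cognitive=list(self.cognitive),
        )
        sub = X[inds].astype(float)
        self.mean_ = sub.mean()
        self.scale_ = sub.std(ddof=1)
        if (self.scale_ == 0).any():
            raise ValueError("constant indicator; cannot standardize")
        frame = X.copy()
        frame[inds] = (sub - self.mean_) / self.scale_
        self.sem_fit_ = fit_sem(self.spec_, frame, missing=self.missing)
        self.weights_ = factor_score_weights(self.sem_fit_)
        # factor sign is arbitrary in a CFA; orient both factors so the
        # first cognitive test loads positively (higher score = better)
        anchor = next(i for i in inds if i in self.cognitive)
        for factor in list(self.weights_.index):
            lam = self.sem_fit_.estimates.get(f"lambda_{anchor}_{factor}")
            if lam is not None and lam < 0:
                self.weights_.loc[factor] *= -1.0
        self.determinacy_ = factor_determinacy(self.sem_fit_)
        self.fit_indices_ = fit_indices_from(self.sem_fit_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Composite d-scores (columns ``deq``, ``gprime``).

        Subjects with any missing indicator get missing scores: partial
        weighted sums would put subjects on different scales.
        """
        if not hasattr(self, "sem_fit_"):
            raise RuntimeError("DeltaModel must be fitted first")
        inds = list(self.indicators)
        Z = (X[inds].astype(float) - self.mean_) / self.scale_
        scores = compute_composites(self.weights_[inds], Z)
        scores = scores.rename(columns={"delta": "deq"})
        return scores


def compute_composites(weights: pd.DataFrame, indicators: pd.DataFrame) -> pd.DataFrame:
    """Apply factor-score weights to (standardized) indicator rows.

    ``weights`` is factor x indicator.  Rows with any missing indicator
    yield missing scores for every factor (no partial sums).
    """
    cols = list(weights.columns)
    absent = [c for c in cols if c not in indicators.columns]
    if absent:
        raise ValueError(f"indicator columns missing: {absent}")
    Z = indicators[cols].to_numpy(float)
    complete = ~np.isnan(Z).any(axis=1)
    out = np.full((len(indicators), weights.shape[0]), np.nan)
    out[complete] = Z[complete] @ weights.to_numpy().T
    return pd.DataFrame(out, index=indicators.index, columns=list(weights.index))


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    orientation: int  # +1 if higher score flags cases, -1 if flipped

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("ROC confidence interval out of order")


def roc_auc(
    scores, labels, higher_is_case: bool | None = None, ci_level: float = 0.95
) -> RocResult:
    """AUC by the rank (Mann-Whitney) construction with ties counted 1/2.

    Complete cases only.  ``higher_is_case=None`` auto-orients the score
    so cases rank higher (the chosen sign is recorded in
    ``orientation``); the Hanley-McNeil variance approximation gives the
    confidence interval.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    ok = ~np.isnan(s) & ~pd.isna(y)
    s, y = s[ok], y[ok].astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    orientation = 1
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if higher_is_case is None:
        if auc < 0.5:
            auc = 1.0 - auc
            orientation = -1
    elif not higher_is_case:
        auc = 1.0 - auc
        orientation = -1
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=n1,
        n_neg=n0,
        orientation=orientation,
    )


def severity_correlation(scores, severity) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) on pairwise-complete data.

    Returns (nan, nan) when either vector has zero variance.
    """
    s = np.asarray(scores, float)
    c = np.asarray(severity, float)
    ok = ~np.isnan(s) & ~np.isnan(c)
    s, c = s[ok], c[ok]
    if len(s) < 3:
        raise ValueError("need at least 3 paired complete observations")
    if np.std(s) == 0 or np.std(c) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(s, c)
    return float(r), float(p)
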