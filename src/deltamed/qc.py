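"""Serum-panel QC cascade for multiplex immunoassay data.

Fixed pipeline order:

1. duplicate reconciliation — pairs differing by more than 5% of the
   pair mean are discarded (the observation becomes missing);
2. LOW handling — analytes with more than half of their usable samples
   below the least detectable dose (LDD) are dropped; remaining LOW
   readings are imputed at LDD/2;
3. outlier deletion — a single pass removing values beyond 3 SD of the
   analyte mean (mean/SD computed once on the input);
4. log transform of highly skewed analytes, then standardization to
   mean 0 / unit variance;
5. batch adjustment — residualisation on batch dummy variables,
   re-standardized to unit variance.

`BiomarkerQC` wraps the cascade as a scikit-learn style transformer over
the long-format raw panel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QcConfig",
    "QcReport",
    "BiomarkerQC",
    "reconcile_duplicates",
    "resolve_low",
    "remove_outliers",
    "normalize_and_standardize",
    "adjust_batch",
]


@dataclass
class QcConfig:
    duplicate_tolerance: float = 0.05  # relative to the pair mean
    low_drop_fraction: float = 0.50  # strict inequality drops the analyte
    outlier_sd: float = 3.0
    skew_threshold: float = 1.0  # |skewness| above which log applies

    def __post_init__(self):
        for name in ("duplicate_tolerance", "low_drop_fraction", "outlier_sd", "skew_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QcReport:
    """Per-analyte accounting of every reading's fate."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        t = self.table
        if t.empty:
            return
        counts = ["n_input", "n_discarded_duplicates", "n_low", "n_outliers"]
        if (t[counts] < 0).any().any():
            raise ValueError("negative counts in QC report")
        reconciled = t["n_retained"] + t["n_discarded_duplicates"]
        if not (reconciled == t["n_input"]).all():
            raise ValueError("QC report does not reconcile input readings")

    def to_json(self, **kw) -> str:
        rec = self.table.reset_index().to_dict(orient="records")
        return json.dumps(rec, default=str, **kw)

    @classmethod
    def from_json(cls, s: str) -> "QcReport":
        df = pd.DataFrame(json.loads(s))
        if "analyte" in df.columns:
            df = df.set_index("analyte")
        return cls(table=df)


def reconcile_duplicates(
    panel: pd.DataFrame, config: QcConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Collapse duplicate reads into one value per subject x analyte.

    The relative difference is |x1 - x2| / mean(x1, x2); pairs within
    tolerance are retained as the pair mean, others become missing.
    Pairs in which both reads are LOW bypass the difference rule (their
    values are below quantification) and are carried as LOW for
    :func:`resolve_low`.

    Returns (values, low_flags, ldd, batch, per-analyte counts); the
    wide frames are subject x analyte.
    """
    config = config or QcConfig()
    required = {"subject_id", "analyte", "rep1", "rep2", "low1", "low2", "ldd", "batch"}
    missing_cols = required - set(panel.columns)
    if missing_cols:
        raise KeyError(f"panel is missing columns {sorted(missing_cols)}")
    r1 = panel["rep1"].to_numpy(float)
    r2 = panel["rep2"].to_numpy(float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        bad = panel.loc[(r1 <= 0) | (r2 <= 0), "analyte"].unique()
        raise ValueError(f"non-positive readings (concentrations must be positive): {list(bad)[:5]}")
    mean = 0.5 * (r1 + r2)
    rel = np.abs(r1 - r2) / mean
    low_pair = panel["low1"].to_numpy(bool) & panel["low2"].to_numpy(bool)
    keep = (rel <= config.duplicate_tolerance) | low_pair
    value = np.where(keep, mean, np.nan)

    wide = panel.assign(_value=value, _low=low_pair, _keep=keep)
    values = wide.pivot(index="subject_id", columns="analyte", values="_value")
    lows = wide.pivot(index="subject_id", columns="analyte", values="_low").fillna(False).astype(bool)
    ldd = panel.groupby("analyte")["ldd"].first()
    batch = panel.groupby("subject_id")["batch"].first()
    counts = wide.groupby("analyte").agg(
        n_input=("_value", "size"),
        n_retained=("_keep", "sum"),
    )
    counts["n_discarded_duplicates"] = counts["n_input"] - counts["n_retained"]
    return values, lows, ldd, batch, counts


def resolve_low(
    values: pd.DataFrame,
    low_flags: pd.DataFrame,
    ldd: pd.Series,
    config: QcConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Impute LOW readings at LDD/2 or drop saturated analytes.

    An analyte whose LOW fraction (among usable samples) strictly
    exceeds ``low_drop_fraction`` is removed entirely; at exactly the
    threshold it is retained.
    """
    config = config or QcConfig()
    if (ldd <= 0).any():
        raise ValueError("LDD must be positive")
    out = values.copy()
    dropped = {}
    n_low = {}
    for analyte in values.columns:
        low = low_flags[analyte]
        usable = low | values[analyte].notna()
        n_usable = int(usable.sum())
        nl = int(low.sum())
        n_low[analyte] = nl
        frac = nl / n_usable if n_usable else 0.0
        if frac > config.low_drop_fraction:
            out = out.drop(columns=analyte)
            dropped[analyte] = True
        else:
            out.loc[low, analyte] = ldd[analyte] / 2.0
            dropped[analyte] = False
    return out, pd.Series(dropped, name="dropped"), pd.Series(n_low, name="n_low")


def remove_outliers(
    values: pd.DataFrame | pd.Series, config: QcConfig | None = None
) -> tuple[pd.DataFrame | pd.Series, pd.Series]:
    """Single-pass deletion of values beyond ``outlier_sd`` SDs.

    Mean and sample SD are computed once on the input (no iterative
    re-screening); a zero-SD column is left untouched.
    """
    config = config or QcConfig()
    squeeze = isinstance(values, pd.Series)
    df = values.to_frame() if squeeze else values.copy()
    n_out = {}
    for col in df.columns:
        x = df[col]
        if x.notna().sum() < 3:
            raise ValueError(f"need at least 3 non-missing values for {col!r}")
        m = x.mean()
        s = x.std(ddof=1)
        if s == 0:
            n_out[col] = 0
            continue
        mask = (x - m).abs() / s > config.outlier_sd
        df.loc[mask, col] = np.nan
        n_out[col] = int(mask.sum())
    counts = pd.Series(n_out, name="n_outliers")
    return (df.iloc[:, 0], counts) if squeeze else (df, counts)


def normalize_and_standardize(
    values: pd.DataFrame | pd.Series, config: QcConfig | None = None
) -> tuple[pd.DataFrame | pd.Series, pd.Series]:
    """Log-transform highly skewed analytes, then z-score each one.

    The natural log applies iff the bias-corrected sample skewness
    exceeds ``skew_threshold`` in absolute value; standardization uses
    the n-1 denominator so [1, 2, 3] maps to [-1, 0, 1].
    """
    config = config or QcConfig()
    squeeze = isinstance(values, pd.Series)
    df = values.to_frame() if squeeze else values.copy()
    logged = {}
    for col in df.columns:
        x = df[col]
        sk = stats.skew(x.dropna(), bias=False) if x.notna().sum() > 2 else 0.0
        if abs(sk) > config.skew_threshold:
            if (x <= 0).any():
                raise ValueError(f"cannot log-transform non-positive values in {col!r}")
            x = np.log(x)
            logged[col] = True
        else:
            logged[col] = False
        s = x.std(ddof=1)
        if s == 0:
            raise ValueError(f"zero variance in {col!r}; cannot standardize")
        df[col] = (x - x.mean()) / s
    flags = pd.Series(logged, name="log_transformed")
    return (df.iloc[:, 0], flags) if squeeze else (df, flags)


def adjust_batch(
    values: pd.DataFrame | pd.Series, batch_labels: pd.Series
) -> tuple[pd.DataFrame | pd.Series, pd.DataFrame]:
    """Residualize each analyte on batch dummies and re-standardize.

    Least-squares on an intercept plus k-1 batch indicators; output
    batch means are zero to numerical tolerance.  Singleton batches are
    retained (their residual is exactly zero) with a warning.  With a
    single batch the output is the centered (re-standardized) input.
    """
    squeeze = isinstance(values, pd.Series)
    df = values.to_frame() if squeeze else values.copy()
    batch = pd.Series(batch_labels).reindex(df.index)
    sizes = batch.value_counts()
    if (sizes == 1).any():
        warnings.warn("batch with a single observation; its residual is 0", UserWarning)
    dummies = pd.get_dummies(batch, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(df))] + [dummies[c].to_numpy() for c in dummies.columns])
    coefs = {}
    for col in df.columns:
        y = df[col].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < X.shape[1]:
            raise ValueError(f"too few observations to adjust {col!r} for batch")
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - X[ok] @ beta
        s = np.nanstd(resid, ddof=1)
        if s > 0:
            resid = resid / s
        df[col] = resid
        coefs[col] = dict(zip(["intercept"] + list(dummies.columns), beta))
    coef_df = pd.DataFrame(coefs).T
    coef_df.index.name = "analyte"
    return (df.iloc[:, 0], coef_df) if squeeze else (df, coef_df)


class BiomarkerQC(BaseEstimator, TransformerMixin):
    """The full QC cascade as a transformer over the raw analyte panel.

    ``fit`` runs duplicates -> LOW -> outliers -> normalize/standardize
    -> batch adjustment and stores the standardized subject x analyte
    matrix plus a :class:`QcReport`; ``transform`` returns the matrix.
    """

    def __init__(self, config: QcConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None):
        cfg = self.config or QcConfig()
        values, lows, ldd, batch, counts = reconcile_duplicates(X, cfg)
        values, dropped, n_low = resolve_low(values, lows, ldd, cfg)
        values, n_out = remove_outliers(values, cfg)
        values, logged = normalize_and_standardize(values, cfg)
        values, batch_coefs = adjust_batch(values, batch)

        report = counts.copy()
        report["n_low"] = n_low
        report["dropped"] = dropped
        report["n_outliers"] = n_out.reindex(report.index).astype("float").fillna(0).astype(int)
        report["log_transformed"] = logged.reindex(report.index).astype("boolean").fillna(False).astype(bool)
        report.index.name = "analyte"
        self.values_ = values
        self.batch_ = batch
        self.batch_coefs_ = batch_coefs
        self.report_ = QcReport(table=report)
        self.report_.validate()
        self.analytes_ = list(values.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Standardized subject x analyte matrix for the fitted panel.

        The cascade's decisions (drops, log transforms, batch fits) are
        cohort-level quantities, so ``X`` must be the panel passed to
        ``fit``; it is accepted for pipeline compatibility.
        """
        return self.panel_

    @property
    def panel_(self) -> pd.DataFrame:
        if not hasattr(self, "values_"):
            raise RuntimeError("BiomarkerQC must be fitted first")
        return self.values_
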