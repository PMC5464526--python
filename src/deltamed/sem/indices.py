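"""Goodness-of-fit indices for covariance-structure models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitIndices", "fit_indices", "fit_indices_from"]


@dataclass(frozen=True)
class FitIndices:
    """chi-square based fit summary.

    ``cmin_df`` (chi2/df) and ``rmsea`` are NaN when ``df == 0`` (a
    just-identified model has no room to misfit); ``cfi`` is NaN when no
    baseline model was supplied.
    """

    chi_square: float
    df: int
    cmin_df: float
    cfi: float
    rmsea: float

    def adequate(self) -> bool:
        """Conventional screen: CMIN/DF < 5, CFI >= 0.95, RMSEA <= 0.08."""
        checks = []
        if np.isfinite(self.cmin_df):
            checks.append(self.cmin_df < 5.0)
        if np.isfinite(self.cfi):
            checks.append(self.cfi >= 0.95)
        if np.isfinite(self.rmsea):
            checks.append(self.rmsea <= 0.08)
        return bool(checks) and all(checks)


def fit_indices(
    chi_square: float,
    df: int,
    n: int,
    baseline_chi_square: float | None = None,
    baseline_df: int | None = None,
) -> FitIndices:
    """Compute CMIN/DF, CFI and RMSEA from chi-square statistics.

    CFI = 1 - max(chi2 - df, 0) / max(chi2_0 - df_0, 0) against the
    independence baseline; RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))).
    """
    if df < 0:
        raise ValueError("df must be non-negative")
    if n <= 1:
        raise ValueError("n must exceed 1")
    chi_square = float(chi_square)
    if df > 0:
        cmin_df = chi_square / df
        rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    else:
        cmin_df = float("nan")
        rmsea = float("nan")
    if baseline_chi_square is not None and baseline_df is not None:
        denom = max(baseline_chi_square - baseline_df, 0.0)
        num = max(chi_square - df, 0.0)
        cfi = 1.0 - num / denom if denom > 0 else (1.0 if num == 0 else 0.0)
        cfi = float(min(max(cfi, 0.0), 1.0))
    else:
        cfi = float("nan")
    return FitIndices(chi_square=chi_square, df=int(df), cmin_df=float(cmin_df), cfi=cfi, rmsea=rmsea)


def fit_indices_from(fit) -> FitIndices:
    """Fit indices for a :class:`~deltamed.sem.fit.SemFit`."""
    return fit_indices(fit.chi2, fit.df, fit.n, fit.baseline_chi2, fit.baseline_df)
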