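"""Split-half generalizability testing.

The cohort is randomly partitioned into two ~50% groups; the mediation
model is fitted to both simultaneously, once with the significant paths
constrained equal across groups and once unconstrained.  The chi-square
difference (referred to chi2 with df = number of constraints) tests
whether the paths generalize: a non-significant difference means the
constrained (shared-path) model fits as well, so mediation effects are
then read from the Group-1 estimates of the constrained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sem import SemModelSpec, fit_sem
from .sem.model import Term

__all__ = ["InvarianceResult", "split_half", "constrained_comparison"]


@dataclass
class InvarianceResult:
    chi2_unconstrained: float
    df_unconstrained: int
    chi2_constrained: float
    df_constrained: int
    delta_chi2: float
    delta_df: int
    p: float
    generalizes: bool
    converged: bool
    constrained_estimates: dict[str, float]
    group1_estimates: dict[str, float]
    seed: int | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def split_half(
    data: pd.DataFrame, seed: int, method: str = "exact"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random partition into two halves.

    ``method="exact"`` gives floor(n/2) / ceil(n/2) groups;
    ``"bernoulli"`` assigns each subject independently with probability
    1/2 (this reproduces the slightly unequal splits that simple random
    subset selection produces in practice).
    """
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    if method == "exact":
        perm = rng.permutation(n)
        idx1 = np.sort(perm[: n // 2])
        idx2 = np.sort(perm[n // 2 :])
    elif method == "bernoulli":
        pick = rng.random(n) < 0.5
        if pick.all() or (~pick).all():  # pathological tiny-n draw
            pick[0] = ~pick[0]
        idx1 = np.flatnonzero(pick)
        idx2 = np.flatnonzero(~pick)
    else:
        raise ValueError(f"unknown split method {method!r}")
    return data.iloc[idx1].copy(), data.iloc[idx2].copy()


def _retag(spec: SemModelSpec, keep_tags: set[str]) -> SemModelSpec:
    """Strip explicit tags not in ``keep_tags`` so only those are shared
    across groups in a constrained multigroup fit."""
    terms = []
    for t in spec.terms:
        if t.tag is not None and t.tag not in keep_tags:
            terms.append(Term(t.lhs, t.op, t.rhs, t.value, None))
        else:
            terms.append(t)
    return SemModelSpec(
        terms=terms,
        latents=list(spec.latents),
        identification=spec.identification,
        orthogonal_latents=spec.orthogonal_latents,
    )


def constrained_comparison(
    spec: SemModelSpec,
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    constrained_tags: list[str],
    missing: str = "listwise",
    alpha: float = 0.05,
    seed: int | None = None,
) -> InvarianceResult:
    """Constrained vs unconstrained multigroup fit of ``spec``.

    ``constrained_tags`` name the explicitly tagged free parameters to
    hold equal across the two groups.  ``generalizes`` is True when the
    chi-square difference is non-significant at ``alpha``.
    """
    tags = set(constrained_tags)
    have = {t.tag for t in spec.terms if t.tag is not None}
    unknown = tags - have
    if unknown:
        raise KeyError(f"constrained tags not in spec: {sorted(unknown)}")
    spec_kept = _retag(spec, tags)

    combined = pd.concat([group1.assign(_grp=0), group2.assign(_grp=1)], ignore_index=True)
    fit_u = fit_sem(spec_kept, combined, missing=missing, groups="_grp", share_tags=False)
    fit_c = fit_sem(spec_kept, combined, missing=missing, groups="_grp", share_tags=True)

    delta_df = fit_c.df - fit_u.df
    if tags and delta_df != len(tags):
        raise RuntimeError(
            f"constraint count mismatch: delta_df={delta_df}, expected {len(tags)}"
        )
    delta_chi2 = float(max(fit_c.chi2 - fit_u.chi2, 0.0))
    p = float(stats.chi2.sf(delta_chi2, delta_df)) if delta_df > 0 else float("nan")
    generalizes = bool(p > alpha) if delta_df > 0 else True

    est_c = fit_c.estimates
    group1_est = {t: est_c[t] for t in tags if t in est_c}
    # group-1-specific parameters carry the _g0 suffix in the multigroup fit
    group1_est.update({k: v for k, v in est_c.items() if k.endswith("_g0")})

    return InvarianceResult(
        chi2_unconstrained=float(fit_u.chi2),
        df_unconstrained=int(fit_u.df),
        chi2_constrained=float(fit_c.chi2),
        df_constrained=int(fit_c.df),
        delta_chi2=delta_chi2,
        delta_df=int(delta_df),
        p=p,
        generalizes=generalizes,
        converged=bool(fit_u.converged and fit_c.converged),
        constrained_estimates={k: float(v) for k, v in est_c.items()},
        group1_estimates={k: float(v) for k, v in group1_est.items()},
        seed=seed,
    )
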