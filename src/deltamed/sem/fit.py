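"""Maximum-likelihood fitting of structural equation models.

Two discrepancy modes are supported:

* ``listwise`` — complete rows only; minimises the Wishart ML
  discrepancy ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`` with
  ``chi2 = (N-1) F`` at the minimum.
* ``fiml`` — full-information ML; maximises the casewise Gaussian
  log-likelihood over each row's observed subset (rows grouped by
  missingness pattern), with a mean structure.  ``chi2`` is the
  likelihood-ratio statistic against the saturated model.

Gradients are analytic (RAM chain rule); standard errors come from the
inverse observed information (numerically differentiated analytic
gradient).  A Newton polish after L-BFGS-B drives the gradient to
near-zero so closed-form oracles (OLS equivalence, triad solutions) are
matched to tight tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import RamModel, SampleStats, SemModelSpec

__all__ = ["SemFit", "SemNotConvergedWarning", "fit_sem"]

_LN2PI = float(np.log(2.0 * np.pi))


class SemNotConvergedWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# data parts
# --------------------------------------------------------------------------
class _CompletePart:
    """Complete-data ML discrepancy for one group.

    ``likelihood="wishart"`` (default) uses the N-1 divisor sample
    covariance with chi2 = (N-1) F, the convention of classical SEM
    software; ``"normal"`` uses the N divisor, which makes the optimum
    coincide exactly with full-information ML on complete data.
    """

    def __init__(self, data: pd.DataFrame, columns: list[str], likelihood: str = "wishart"):
        sub = data[columns].dropna()
        self.n = len(sub)
        if self.n <= len(columns):
            raise ValueError(
                f"need more complete rows ({self.n}) than observed variables ({len(columns)})"
            )
        X = sub.to_numpy(float)
        ddof = 1 if likelihood == "wishart" else 0
        self.S = np.cov(X, rowvar=False, ddof=ddof)
        self.p = len(columns)
        sign, logdet = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "sample covariance matrix is not positive definite; "
                "check for collinear or constant indicators"
            )
        self.logdet_S = logdet
        self.n_moments = self.p * (self.p + 1) // 2
        self.weight = self.n - 1 if likelihood == "wishart" else self.n

    def value_and_M(self, Sigma, mu):
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Sinv = np.linalg.inv(Sigma)
        F = logdet + np.trace(self.S @ Sinv) - self.logdet_S - self.p
        M = self.weight * (Sinv - Sinv @ self.S @ Sinv)
        return self.weight * F, M, np.zeros(self.p)

    def baseline_chi2_df(self):
        F0 = float(np.sum(np.log(np.diag(self.S))) - self.logdet_S)
        return self.weight * F0, self.p * (self.p - 1) // 2


class _FimlPart:
    """Casewise Gaussian -2 log-likelihood for one group (with means)."""

    def __init__(self, data: pd.DataFrame, columns: list[str]):
        X = data[columns].to_numpy(float)
        keep = ~np.all(np.isnan(X), axis=1)
        X = X[keep]
        self.n = X.shape[0]
        if self.n == 0:
            raise ValueError("no rows with any observed data")
        self.p = len(columns)
        self.patterns = []
        mask = ~np.isnan(X)
        codes = np.array([m.tobytes() for m in mask])
        for code in np.unique(codes):
            rows = X[codes == code]
            oidx = np.flatnonzero(~np.isnan(rows[0]))
            sub = rows[:, oidx]
            ng = sub.shape[0]
            xbar = sub.mean(axis=0)
            dev = sub - xbar
            W = dev.T @ dev / ng  # ML divisor
            self.patterns.append((oidx, ng, xbar, W))
        self.n_moments = self.p * (self.p + 3) // 2  # cov + means

    def value_and_M(self, Sigma, mu):
        total = 0.0
        M = np.zeros((self.p, self.p))
        u = np.zeros(self.p)
        for oidx, ng, xbar, W in self.patterns:
            Sg = Sigma[np.ix_(oidx, oidx)]
            try:
                c = np.linalg.cholesky(Sg)
            except np.linalg.LinAlgError:
                return None
            k = len(oidx)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            Sginv = np.linalg.inv(Sg)
            d = xbar - mu[oidx]
            total += ng * (
                k * _LN2PI + logdet + np.trace(W @ Sginv) + d @ Sginv @ d
            )
            Mg = Sginv - Sginv @ (W + np.outer(d, d)) @ Sginv
            M[np.ix_(oidx, oidx)] += ng * Mg
            u[oidx] += -2.0 * ng * (Sginv @ d)
        return total, M, u


# --------------------------------------------------------------------------
# multigroup problem over a shared parameter vector
# --------------------------------------------------------------------------
class _Problem:
    def __init__(self, parts: list[tuple[RamModel, object]]):
        self.parts = parts
        names: list[str] = []
        seen = {}
        for ram, _ in parts:
            for t in ram.free_names:
                if t not in seen:
                    seen[t] = len(names)
                    names.append(t)
        self.free_names = names
        self.maps = [
            np.array([seen[t] for t in ram.free_names], dtype=int) for ram, _ in parts
        ]
        start = np.zeros(len(names))
        kinds = [None] * len(names)
        for (ram, _), mp in zip(parts, self.maps):
            start[mp] = ram.start
            for local, g in enumerate(mp):
                kinds[g] = ram.kinds[local]
        self.start = start
        self.kinds = kinds

    @property
    def n_free(self):
        return len(self.free_names)

    def bounds(self):
        return [(1e-8, None) if k == "variance" else (None, None) for k in self.kinds]

    def value_and_grad(self, theta: np.ndarray):
        total = 0.0
        grad = np.zeros_like(theta)
        for (ram, part), mp in zip(self.parts, self.maps):
            th = theta[mp]
            A, S, m = ram.matrices(th)
            nv = len(ram.names)
            try:
                B = np.linalg.inv(np.eye(nv) - A)
            except np.linalg.LinAlgError:
                return 1e15 + theta @ theta, 2.0 * theta
            oi = ram.obs_idx
            V = B @ S @ B.T
            Sigma = V[np.ix_(oi, oi)]
            bm = B @ m
            mu = bm[oi]
            res = part.value_and_M(Sigma, mu)
            if res is None:  # non-PD implied covariance: push back
                return 1e15 + theta @ theta, 2.0 * theta
            val, M, u = res
            total += val
            G = B[oi, :]  # p x v
            H = V[:, oi]  # v x p
            K = H @ M @ G  # v x v ; A-channel through Sigma
            L = G.T @ M @ G  # v x v ; S-channel
            w = G.T @ u  # v ; mean channel
            g_local = np.zeros(len(th))
            for ki, cell_list in enumerate(ram.free_cells):
                acc = 0.0
                for mat, i, j in cell_list:
                    if mat == "A":
                        acc += 2.0 * K[j, i] + w[i] * bm[j]
                    elif mat == "S":
                        acc += L[i, i] if i == j else 2.0 * L[i, j]
                    else:
                        acc += w[i]
                g_local[ki] = acc
            np.add.at(grad, mp, g_local)
        return total, grad


# --------------------------------------------------------------------------
# fit result
# --------------------------------------------------------------------------
@dataclass
class SemFit:
    """Result of a structural-equation-model fit."""

    spec: SemModelSpec
    free_names: list[str]
    theta: np.ndarray
    se_theta: np.ndarray | None
    minus2ll: float
    chi2: float
    df: int
    n: int
    n_groups: int
    missing: str
    converged: bool
    n_iter: int
    message: str
    grad_norm: float
    rams: list[RamModel] = field(repr=False)
    baseline_chi2: float | None = None
    baseline_df: int | None = None
    saturated_minus2ll: float | None = None

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.free_names, map(float, self.theta)))

    @property
    def se(self) -> dict[str, float]:
        if self.se_theta is None:
            return {}
        return dict(zip(self.free_names, map(float, self.se_theta)))

    @property
    def p_value(self) -> float:
        from scipy.stats import chi2 as chi2_dist

        if self.df <= 0:
            return float("nan")
        return float(chi2_dist.sf(self.chi2, self.df))

    def implied_moments(self, group: int = 0):
        """Model-implied covariance and mean vector for one group."""
        ram = self.rams[group]
        mp = self._theta_map(group)
        return ram.implied(self.theta[mp])

    def _theta_map(self, group: int = 0) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.free_names)}
        return np.array([pos[t] for t in self.rams[group].free_names], dtype=int)

    def param_table(self) -> pd.DataFrame:
        est = self.estimates
        se = self.se
        rows = []
        for name in self.free_names:
            z = est[name] / se[name] if se.get(name) else np.nan
            rows.append({"param": name, "estimate": est[name], "se": se.get(name, np.nan), "z": z})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------
def _newton_polish(problem, theta, max_steps=8, tol=1e-9):
    """Newton steps on the gradient to sharpen the optimum."""
    f, g = problem.value_and_grad(theta)
    for _ in range(max_steps):
        gmax = np.max(np.abs(g))
        if gmax < tol:
            break
        H = _numeric_hessian(problem, theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        ok = False
        lam = 1.0
        for _ in range(6):
            cand = theta - lam * step
            fc, gc = problem.value_and_grad(cand)
            if np.isfinite(fc) and (fc < f + 1e-12 or np.max(np.abs(gc)) < gmax):
                theta, f, g = cand, fc, gc
                ok = True
                break
            lam *= 0.25
        if not ok:
            break
    return theta, f, g


def _numeric_hessian(problem, theta):
    q = len(theta)
    H = np.zeros((q, q))
    for k in range(q):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        _, gp = problem.value_and_grad(tp)
        _, gm = problem.value_and_grad(tm)
        H[:, k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _minimize(problem, start, max_iter, tol):
    res = optimize.minimize(
        problem.value_and_grad,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=problem.bounds(),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9, "maxcor": 20},
    )
    theta, f, g = _newton_polish(problem, res.x)
    return theta, f, g, res


def _saturated_minus2ll(data: pd.DataFrame, columns: list[str], max_iter, tol) -> float:
    spec = _moment_spec(columns, diagonal=False)
    prob = _Problem([(spec.compile(meanstructure=True, sample_stats=_safe_stats(data[columns])), _FimlPart(data, columns))])
    _, f, _, _ = _minimize(prob, prob.start, max_iter, tol)
    return f


def _independence_minus2ll(data: pd.DataFrame, columns: list[str], max_iter, tol) -> float:
    spec = _moment_spec(columns, diagonal=True)
    prob = _Problem([(spec.compile(meanstructure=True, sample_stats=_safe_stats(data[columns])), _FimlPart(data, columns))])
    _, f, _, _ = _minimize(prob, prob.start, max_iter, tol)
    return f


def _moment_spec(columns: list[str], diagonal: bool) -> SemModelSpec:
    from .model import Term

    terms = [Term(c, "~~", c) for c in columns]
    if not diagonal:
        for i, a in enumerate(columns):
            for b in columns[:i]:
                terms.append(Term(a, "~~", b))
    return SemModelSpec(terms=terms, latents=[])


def _safe_stats(data: pd.DataFrame):
    try:
        return SampleStats(data)
    except Exception:
        return None


def fit_sem(
    spec: SemModelSpec,
    data: pd.DataFrame,
    missing: str = "listwise",
    groups: pd.Series | np.ndarray | str | None = None,
    share_tags: bool = True,
    se: bool = True,
    baseline: bool = True,
    likelihood: str = "wishart",
    max_iter: int = 500,
    tol: float = 1e-12,
    restarts: int = 0,
    seed: int | None = None,
) -> SemFit:
    """Fit ``spec`` to ``data`` by maximum likelihood.

    Parameters
    ----------
    missing
        ``"listwise"`` (complete rows, covariance structure only) or
        ``"fiml"`` (full-information ML with a mean structure).
    groups
        Optional group labels (column name or array) for a multigroup
        fit.  Explicitly tagged parameters are shared across groups when
        ``share_tags`` is True; auto-named parameters are always
        group-specific.
    restarts
        Extra random restarts from jittered start values; the best
        optimum is kept (guards against local minima).
    """
    if missing not in ("listwise", "fiml"):
        raise ValueError(f"missing must be 'listwise' or 'fiml', got {missing!r}")
    spec.validate()
    columns = [c for c in spec.observed if c in data.columns]
    absent = set(spec.observed) - set(columns)
    if absent:
        raise KeyError(f"observed variables missing from data: {sorted(absent)}")

    if groups is None:
        frames = [(data, "")]
    else:
        gvals = data[groups] if isinstance(groups, str) else pd.Series(np.asarray(groups), index=data.index)
        frames = [(data.loc[gvals == g], f"_g{k}") for k, g in enumerate(pd.unique(gvals.dropna()))]
        if len(frames) < 2:
            raise ValueError("multigroup fit needs at least two groups")

    parts = []
    for frame, suffix in frames:
        stats = _safe_stats(frame[columns].dropna()) if len(frame[columns].dropna()) > len(columns) else None
        eff_suffix = suffix if (groups is not None) else ""
        ram = spec.compile(
            meanstructure=(missing == "fiml"),
            tag_suffix=eff_suffix,
            sample_stats=stats,
        )
        if groups is not None and not share_tags:
            # suffix *every* tag so nothing is shared
            ram.free_names = [t + suffix if not t.endswith(suffix) else t for t in ram.free_names]
        part = (
            _CompletePart(frame, columns, likelihood)
            if missing == "listwise"
            else _FimlPart(frame, columns)
        )
        parts.append((ram, part))

    problem = _Problem(parts)
    n_total = sum(part.n for _, part in parts)
    n_moments = sum(part.n_moments for _, part in parts)
    if problem.n_free > n_moments:
        raise ValueError(
            f"model has {problem.n_free} free parameters but only {n_moments} sample moments"
        )
    if n_total <= problem.n_free:
        raise ValueError("need more observations than free parameters")

    theta, f, g, res = _minimize(problem, problem.start, max_iter, tol)

    def _grad_ok(gv, fv):
        return bool(np.isfinite(fv)) and np.max(np.abs(gv)) < 1e-3 * max(1.0, n_total)

    n_extra = restarts if restarts else (3 if not _grad_ok(g, f) else 0)
    if n_extra:
        rng = np.random.default_rng(seed if seed is not None else 0)
        is_var = np.array(problem.kinds) == "variance"
        for _ in range(n_extra):
            jitter = problem.start + rng.normal(scale=0.25, size=problem.n_free)
            jitter = np.where(is_var, np.clip(jitter, 1e-4, None), jitter)
            t2, f2, g2, _ = _minimize(problem, jitter, max_iter, tol)
            better = (f2 < f - 1e-10) or (not _grad_ok(g, f) and _grad_ok(g2, f2) and f2 < f + 1e-6)
            if better:
                theta, f, g = t2, f2, g2
            if restarts == 0 and _grad_ok(g, f):
                break

    grad_norm = float(np.max(np.abs(g)))
    converged = _grad_ok(g, f)
    if not converged:
        warnings.warn(
            f"SEM fit did not converge cleanly (|grad|max={grad_norm:.3g}): {res.message}",
            SemNotConvergedWarning,
        )

    # chi-square
    sat_m2ll = None
    if missing == "listwise":
        chi2 = float(f)
        minus2ll = float(f)
    else:
        sat_m2ll = sum(
            _saturated_minus2ll(frame, columns, max_iter, tol) for frame, _ in frames
        )
        chi2 = float(max(f - sat_m2ll, 0.0))
        minus2ll = float(f)
    df = n_moments - problem.n_free

    base_chi2 = base_df = None
    if baseline:
        if missing == "listwise":
            pairs = [part.baseline_chi2_df() for _, part in parts]
            base_chi2 = float(sum(c for c, _ in pairs))
            base_df = int(sum(d for _, d in pairs))
        else:
            ind = sum(_independence_minus2ll(frame, columns, max_iter, tol) for frame, _ in frames)
            base_chi2 = float(max(ind - sat_m2ll, 0.0))
            base_df = sum(part.p * (part.p - 1) // 2 for _, part in parts)

    se_theta = None
    if se:
        H = _numeric_hessian(problem, theta)
        try:
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov).copy()
            diag[diag < 0] = np.nan
            se_theta = np.sqrt(diag)
        except np.linalg.LinAlgError:
            se_theta = np.full(problem.n_free, np.nan)

    return SemFit(
        spec=spec,
        free_names=problem.free_names,
        theta=theta,
        se_theta=se_theta,
        minus2ll=minus2ll,
        chi2=chi2,
        df=df,
        n=n_total,
        n_groups=len(parts),
        missing=missing,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        grad_norm=grad_norm,
        rams=[ram for ram, _ in parts],
        baseline_chi2=base_chi2,
        baseline_df=base_df,
        saturated_minus2ll=sat_m2ll,
    )
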