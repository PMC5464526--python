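"""Model specification for linear structural equation models.

A model is a set of *terms* relating named variables:

``factor =~ ind1 + ind2``   loadings (measurement model)
``y ~ x1 + x2``             regressions (structural model)
``x ~~ y``                  (co)variances; ``x ~~ x`` is a variance

Each free parameter carries a unique *tag*.  Tags may be assigned
explicitly (``y ~ x [b]``) so the same parameter can be constrained
equal across groups in a multigroup fit, or fixed to a constant with a
numeric prefix (``1*x``).  The spec compiles to a RAM (reticular action
model) parameterisation: directed paths in ``A``, symmetric
(co)variances in ``S``, means in ``m``, with the model-implied moments

    Sigma = F (I - A)^-1 S (I - A)^-T F',     mu = F (I - A)^-1 m

where ``F`` filters the observed variables.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["Term", "SemModelSpec", "RamModel", "parse_model"]


@dataclass(frozen=True)
class Term:
    """One relation in a model specification."""

    lhs: str
    op: str  # "=~", "~", "~~"
    rhs: str
    value: float | None = None  # fixed value; None means free
    tag: str | None = None  # parameter label (free parameters only)

    def __post_init__(self):
        if self.op not in ("=~", "~", "~~"):
            raise ValueError(f"unknown operator {self.op!r}")
        if self.value is not None and not np.isfinite(self.value):
            raise ValueError(f"non-finite fixed value in term {self}")


_TERM_RE = re.compile(
    r"^\s*(?:(?P<value>[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\*)?"
    r"(?P<name>[A-Za-z_][\w.]*)\s*(?:\[(?P<tag>[^\]]+)\])?\s*$"
)


def _parse_rhs_term(token: str) -> tuple[str, float | None, str | None]:
    m = _TERM_RE.match(token)
    if m is None:
        raise ValueError(f"cannot parse model term {token!r}")
    value = float(m.group("value")) if m.group("value") is not None else None
    tag = m.group("tag").strip() if m.group("tag") else None
    if value is not None and tag is not None:
        raise ValueError(f"term {token!r} is both fixed and tagged")
    return m.group("name"), value, tag


def parse_model(text: str) -> list[Term]:
    """Parse model syntax into a list of :class:`Term`."""
    terms: list[Term] = []
    for raw_line in text.splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = line.split(op, 1)
                lhs = lhs.strip()
                if not re.match(r"^[A-Za-z_][\w.]*$", lhs):
                    raise ValueError(f"bad left-hand side {lhs!r}")
                for token in rhs.split("+"):
                    name, value, tag = _parse_rhs_term(token)
                    terms.append(Term(lhs, op, name, value, tag))
                break
        else:
            raise ValueError(f"cannot parse model line {raw_line!r}")
    return terms


@dataclass
class SemModelSpec:
    """A latent-variable model specification.

    Parameters
    ----------
    terms
        Relations among variables (see module docstring).
    latents
        Names of latent variables; everything else mentioned in the
        terms is treated as observed.
    identification
        ``"unit_variance"`` fixes exogenous latent variances to one
        (default; keeps loadings comparable across groups) or
        ``"unit_loading"`` fixes the first loading of each factor.
    orthogonal_latents
        If True (default) latent covariances are fixed to zero unless a
        ``~~`` term frees them explicitly.
    """

    terms: list[Term]
    latents: list[str] = field(default_factory=list)
    identification: str = "unit_variance"
    orthogonal_latents: bool = True

    @classmethod
    def from_syntax(cls, text: str, latents: list[str] | None = None, **kw) -> "SemModelSpec":
        terms = parse_model(text)
        if latents is None:
            latents = sorted({t.lhs for t in terms if t.op == "=~"})
        return cls(terms=terms, latents=list(latents), **kw)

    # ---- introspection -------------------------------------------------
    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.lhs)
            seen.setdefault(t.rhs)
        return list(seen)

    @property
    def observed(self) -> list[str]:
        lat = set(self.latents)
        return [v for v in self.variables if v not in lat]

    def validate(self) -> None:
        if self.identification not in ("unit_variance", "unit_loading"):
            raise ValueError(f"unknown identification rule {self.identification!r}")
        tags = [t.tag for t in self.terms if t.tag is not None]
        dup_cells: set[tuple] = set()
        for t in self.terms:
            cell = (t.op, t.lhs, t.rhs) if t.op != "~~" else ("~~",) + tuple(sorted((t.lhs, t.rhs)))
            if cell in dup_cells:
                raise ValueError(f"duplicate term for {cell}")
            dup_cells.add(cell)
        # explicit tags must not collide across distinct defaults accidentally:
        # a tag may appear on several cells (equality constraint) -- allowed.
        del tags
        self._check_acyclic()
        for lat in self.latents:
            if not any(t.op == "=~" and t.lhs == lat for t in self.terms) and not any(
                t.op == "~" and lat in (t.lhs, t.rhs) for t in self.terms
            ):
                raise ValueError(f"latent {lat!r} appears in no term")

    def _check_acyclic(self) -> None:
        # directed edges rhs -> lhs for "~", lhs -> rhs for "=~" (factor -> indicator)
        edges: dict[str, set[str]] = {}
        for t in self.terms:
            if t.op == "~":
                edges.setdefault(t.rhs, set()).add(t.lhs)
            elif t.op == "=~":
                edges.setdefault(t.lhs, set()).add(t.rhs)
        indeg: dict[str, int] = {v: 0 for v in self.variables}
        for src, dsts in edges.items():
            for d in dsts:
                indeg[d] = indeg.get(d, 0) + 1
        queue = [v for v, k in indeg.items() if k == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for d in edges.get(v, ()):
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
        if seen != len(indeg):
            raise ValueError("structural graph is cyclic; only recursive models are supported")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "terms": [asdict(t) for t in self.terms],
            "latents": list(self.latents),
            "identification": self.identification,
            "orthogonal_latents": self.orthogonal_latents,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SemModelSpec":
        return cls(
            terms=[Term(**t) for t in d["terms"]],
            latents=list(d.get("latents", [])),
            identification=d.get("identification", "unit_variance"),
            orthogonal_latents=d.get("orthogonal_latents", True),
        )

    @classmethod
    def from_json(cls, s: str) -> "SemModelSpec":
        return cls.from_dict(json.loads(s))

    # ---- compilation ---------------------------------------------------
    def compile(
        self,
        meanstructure: bool = False,
        tag_suffix: str = "",
        sample_stats: "SampleStats | None" = None,
    ) -> "RamModel":
        """Compile to a :class:`RamModel` with auto-completed defaults.

        Auto-completion: residual variances for every endogenous
        variable, free variances and a saturated covariance block for
        exogenous observed variables, identification constraints for
        latents, and (under ``meanstructure``) free means/intercepts for
        observed variables.  ``tag_suffix`` is appended to automatically
        generated tags (used for unconstrained multigroup fits); explicit
        tags are kept verbatim so they can be shared across groups.
        """
        self.validate()
        lat = list(self.latents)
        obs = self.observed
        names = obs + lat
        idx = {v: i for i, v in enumerate(names)}
        nv = len(names)

        A_fixed = np.zeros((nv, nv))
        S_fixed = np.zeros((nv, nv))
        m_fixed = np.zeros(nv)
        cells: dict[str, list[tuple[str, int, int]]] = {}
        start: dict[str, float] = {}
        kinds: dict[str, str] = {}

        def add_free(tag, mat, i, j, start_val, kind):
            cells.setdefault(tag, []).append((mat, i, j))
            start.setdefault(tag, start_val)
            kinds.setdefault(tag, kind)

        has_incoming = {v: False for v in names}
        explicit_S: set[tuple[int, int]] = set()
        loadings_by_factor: dict[str, list[Term]] = {}

        for t in self.terms:
            if t.op == "=~":
                loadings_by_factor.setdefault(t.lhs, []).append(t)

        # staggered loading starts break the exchange symmetry of
        # overlapping factors (identical starts sit on a saddle)
        factor_rank = {f: r for r, f in enumerate(lat)}
        for t in self.terms:
            if t.op in ("=~", "~"):
                if t.op == "=~":
                    i, j = idx[t.rhs], idx[t.lhs]  # indicator <- factor
                else:
                    i, j = idx[t.lhs], idx[t.rhs]
                has_incoming[names[i]] = True
                if t.value is not None:
                    A_fixed[i, j] = t.value
                else:
                    tag = t.tag or f"{'lambda' if t.op == '=~' else 'beta'}_{names[i]}_{names[j]}"
                    if t.tag is None:
                        tag += tag_suffix
                    if t.op == "=~":
                        s0 = 0.7 / (1.0 + factor_rank.get(t.lhs, 0))
                    else:
                        s0 = 0.0
                    add_free(tag, "A", i, j, s0, "path")
            else:  # "~~"
                i, j = idx[t.lhs], idx[t.rhs]
                i, j = max(i, j), min(i, j)
                explicit_S.add((i, j))
                if t.value is not None:
                    S_fixed[i, j] = S_fixed[j, i] = t.value
                else:
                    tag = t.tag or (f"var_{names[i]}" if i == j else f"cov_{names[i]}_{names[j]}")
                    if t.tag is None:
                        tag += tag_suffix
                    add_free(tag, "S", i, j, 0.5 if i == j else 0.0, "variance" if i == j else "path")

        # identification for latents
        for f in lat:
            fi = idx[f]
            endogenous = has_incoming[f]
            if (fi, fi) in explicit_S:
                pass  # user took responsibility
            elif endogenous:
                add_free(f"var_{f}{tag_suffix}", "S", fi, fi, 0.5, "variance")
                terms = loadings_by_factor.get(f, [])
                if terms and all(t.value is None and t.tag is None for t in terms):
                    # anchor scale on the first loading
                    t0 = terms[0]
                    tag0 = f"lambda_{t0.rhs}_{f}{tag_suffix}"
                    if tag0 in cells:
                        del cells[tag0], start[tag0], kinds[tag0]
                    A_fixed[idx[t0.rhs], fi] = 1.0
            else:
                if self.identification == "unit_variance":
                    S_fixed[fi, fi] = 1.0
                else:
                    add_free(f"var_{f}{tag_suffix}", "S", fi, fi, 0.5, "variance")
                    terms = loadings_by_factor.get(f, [])
                    if not terms:
                        raise ValueError(f"cannot anchor latent {f!r} without loadings")
                    t0 = terms[0]
                    tag0 = t0.tag or f"lambda_{t0.rhs}_{f}{tag_suffix}"
                    if t0.value is None and tag0 in cells:
                        del cells[tag0], start[tag0], kinds[tag0]
                        A_fixed[idx[t0.rhs], fi] = 1.0

        # residual variances for endogenous observed, free variances for exogenous
        exo_obs = []
        for v in obs:
            vi = idx[v]
            if (vi, vi) in explicit_S:
                continue
            sv = 1.0
            if sample_stats is not None and v in sample_stats.columns:
                sv = float(sample_stats.variance(v))
            if has_incoming[v]:
                add_free(f"var_{v}{tag_suffix}", "S", vi, vi, 0.5 * sv, "variance")
            else:
                exo_obs.append(v)
                add_free(f"var_{v}{tag_suffix}", "S", vi, vi, sv, "variance")

        # saturated covariances among exogenous observed variables
        for a_i, va in enumerate(exo_obs):
            for vb in exo_obs[:a_i]:
                i, j = idx[va], idx[vb]
                if (max(i, j), min(i, j)) in explicit_S:
                    continue
                sv = 0.0
                if sample_stats is not None and va in sample_stats.columns and vb in sample_stats.columns:
                    sv = float(sample_stats.covariance(va, vb))
                add_free(f"cov_{va}_{vb}{tag_suffix}", "S", max(i, j), min(i, j), sv, "path")

        if meanstructure:
            for v in obs:
                vi = idx[v]
                mv = 0.0
                if sample_stats is not None and v in sample_stats.columns:
                    mv = float(sample_stats.mean(v))
                add_free(f"mean_{v}{tag_suffix}", "m", vi, 0, mv if not has_incoming[v] else 0.0, "mean")

        free_names = list(cells)
        return RamModel(
            names=names,
            obs_names=obs,
            A_fixed=A_fixed,
            S_fixed=S_fixed,
            m_fixed=m_fixed,
            free_cells=[cells[t] for t in free_names],
            free_names=free_names,
            start=np.array([start[t] for t in free_names]),
            kinds=[kinds[t] for t in free_names],
            meanstructure=meanstructure,
        )


class SampleStats:
    """Per-column sample moments used to seed start values."""

    def __init__(self, data):
        self._means = data.mean()
        self._cov = data.cov()
        self.columns = list(data.columns)

    def mean(self, v):
        return self._means[v]

    def variance(self, v):
        return self._cov.loc[v, v]

    def covariance(self, a, b):
        return self._cov.loc[a, b]


@dataclass
class RamModel:
    """Compiled RAM matrices with a free-parameter map."""

    names: list[str]
    obs_names: list[str]
    A_fixed: np.ndarray
    S_fixed: np.ndarray
    m_fixed: np.ndarray
    free_cells: list[list[tuple[str, int, int]]]
    free_names: list[str]
    start: np.ndarray
    kinds: list[str]
    meanstructure: bool = False

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def obs_idx(self) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.names)}
        return np.array([pos[v] for v in self.obs_names])

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = self.A_fixed.copy()
        S = self.S_fixed.copy()
        m = self.m_fixed.copy()
        for val, cell_list in zip(theta, self.free_cells):
            for mat, i, j in cell_list:
                if mat == "A":
                    A[i, j] = val
                elif mat == "S":
                    S[i, j] = val
                    S[j, i] = val
                else:
                    m[i] = val
        return A, S, m

    def implied(self, theta: np.ndarray):
        """Model-implied (Sigma, mu) over the observed variables."""
        A, S, m = self.matrices(theta)
        B = np.linalg.inv(np.eye(len(self.names)) - A)
        V = B @ S @ B.T
        oi = self.obs_idx
        return V[np.ix_(oi, oi)], (B @ m)[oi]

    def bounds(self, lower_variance: float = 1e-8) -> list[tuple[float | None, float | None]]:
        return [
            (lower_variance, None) if k == "variance" else (None, None) for k in self.kinds
        ]
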