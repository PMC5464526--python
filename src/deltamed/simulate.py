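"""Synthetic cohort generator with retained ground truth.

Emulates the data-generating structure the mediation analysis assumes:
densely intercorrelated covariates, a right-skewed 0-30 depressive
symptom score (GDS), serum proteins causally downstream of the GDS, and
a latent dementia factor delta driven by GDS, proteins and covariates,
measured one wave later by four cognitive tests plus an informant-rated
functional scale (IADL).  The raw analyte panel layer reproduces the
artefacts the QC cascade removes: right-skewed raw scales, batch mean
shifts, duplicate reads, censoring below a least-detectable dose (LDD)
and gross-error outliers.

Orientation: delta is scaled so that *higher is better* cognition; a
negative GDS -> delta slope therefore means depressive symptoms worsen
future dementia severity, and clinical severity (CDR-SB) decreases
monotonically in delta.

All randomness flows from ``SimConfig.seed``; the same config yields
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COVARIATES",
    "INDICATORS",
    "COGNITIVE_INDICATORS",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "default_true_paths",
    "default_loadings",
    "simulate_cohort",
    "distort_panel",
    "inject_missingness",
    "standardize",
]

COVARIATES = ["age", "educ", "ethnicity", "gender", "apoe4", "hcy", "hgba1c"]
INDICATORS = ["lmii", "vri", "cowa", "dst", "iadl"]
COGNITIVE_INDICATORS = ["lmii", "vri", "cowa", "dst"]

# Table-1-like marginal targets for the observed indicator scales
_SCALES = {"lmii": (8.05, 4.30), "vri": (7.88, 3.68), "cowa": (8.41, 3.49), "dst": (8.89, 3.01)}


def standardize(x: np.ndarray | pd.Series) -> np.ndarray:
    """In-sample z-score (ddof=1), ignoring NaN."""
    x = np.asarray(x, float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - m) / s


def default_true_paths(
    n_proteins: int,
    n_mediators: int = 10,
    n_gds_only: int = 3,
    n_delta_only: int = 5,
    c: float = 0.5,
    b: float = -0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein (c_true, b_true) arrays realising the four protein
    classes: mediators (both paths), GDS-only (c), delta-only (b), null."""
    if n_mediators + n_gds_only + n_delta_only > n_proteins:
        raise ValueError("designed classes exceed panel size")
    c_true = np.zeros(n_proteins)
    b_true = np.zeros(n_proteins)
    c_true[:n_mediators] = c
    b_true[:n_mediators] = b
    c_true[n_mediators : n_mediators + n_gds_only] = c
    b_true[n_mediators + n_gds_only : n_mediators + n_gds_only + n_delta_only] = b
    return c_true, b_true


def default_loadings() -> pd.DataFrame:
    """Bifactor loadings (rows: indicators; columns: delta, gprime).

    Cognitive tests load on both factors; the functional scale (IADL,
    higher = more impaired) anchors delta with a strong negative
    loading and is unrelated to g'.  The delta/g' loading ratios differ
    across tests (the memory tests weight delta more, the
    fluency/attention tests weight g' more): proportional ratios would
    leave the bifactor model empirically under-identified.
    """
    lam = pd.DataFrame(
        {
            "delta": [0.55, 0.50, 0.30, 0.25, -0.80],
            "gprime": [0.40, 0.30, 0.65, 0.55, 0.0],
        },
        index=INDICATORS,
    )
    return lam


def _default_covariate_effects() -> pd.DataFrame:
    """Covariate -> (gds, protein, delta) slopes on the copula z-scale."""
    eff = pd.DataFrame(
        {
            "gds": [0.05, -0.05, 0.05, 0.00, 0.05, 0.05, 0.05],
            "protein": [0.10, 0.00, 0.05, 0.10, 0.00, 0.10, 0.05],
            "delta": [-0.25, 0.15, -0.05, 0.00, -0.15, -0.05, -0.05],
        },
        index=COVARIATES,
    )
    return eff


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Path coefficients are in standardized units: the GDS enters the
    structural equations as an in-sample z-score, proteins are generated
    on an (approximately) unit-variance scale.
    """

    n_subjects: int = 3385
    seed: int = 0
    n_proteins: int = 115
    a_true: float = -0.10
    c_true: np.ndarray | None = None  # per-protein GDS -> protein
    b_true: np.ndarray | None = None  # per-protein protein -> delta
    loadings: pd.DataFrame = field(default_factory=default_loadings)
    covariate_effects: pd.DataFrame = field(default_factory=_default_covariate_effects)
    covariate_corr: float = 0.25  # exchangeable copula correlation
    delta_disturbance_sd: float = 0.6
    gds_mean: float = 5.6
    gds_size: float = 1.43  # negative-binomial size; gives SD ~ 5.25
    diagnosis_fracs: tuple[float, float] = (0.37, 0.20)  # AD, MCI (rest NC)
    n_batches: int = 4
    batch_shifts: tuple[float, ...] = (0.0, 0.15, -0.10, 0.05)  # log scale
    ldd_quantile: float = 0.05
    duplicate_cv: float = 0.02
    outlier_rate: float = 0.005
    missing_rates: dict = field(
        default_factory=lambda: {"gds": 0.112, "covariates": 0.01, "indicators": 0.02}
    )

    def __post_init__(self):
        if self.n_subjects < 50:
            raise ValueError("n_subjects must be at least 50")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")
        if self.c_true is None or self.b_true is None:
            P = self.n_proteins
            if P >= 18:
                c, b = default_true_paths(P)
            else:  # keep the four classes represented on small panels
                n_med = max(1, P // 3) if P else 0
                n_gds = 1 if P - n_med >= 2 else 0
                n_del = 1 if P - n_med - n_gds >= 2 else 0
                c, b = default_true_paths(P, n_med, n_gds, n_del)
            if self.c_true is None:
                self.c_true = c
            if self.b_true is None:
                self.b_true = b
        self.c_true = np.asarray(self.c_true, float)
        self.b_true = np.asarray(self.b_true, float)
        if len(self.c_true) != self.n_proteins or len(self.b_true) != self.n_proteins:
            raise ValueError("c_true/b_true length must equal n_proteins")
        for name, arr in (("a_true", [self.a_true]), ("c_true", self.c_true), ("b_true", self.b_true)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite slopes in {name}")
        if not np.all(np.isfinite(self.loadings.to_numpy())):
            raise ValueError("loadings must be finite")
        if not (0 <= self.ldd_quantile < 1):
            raise ValueError("ldd_quantile must be in [0, 1)")
        if self.duplicate_cv < 0:
            raise ValueError("duplicate_cv must be non-negative")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")
        for k, r in self.missing_rates.items():
            if not (0 <= r < 1):
                raise ValueError(f"missing rate for {k!r} must be in [0, 1)")
        if len(self.batch_shifts) != self.n_batches:
            raise ValueError("batch_shifts length must equal n_batches")

    def protein_names(self) -> list[str]:
        return [f"protein_{j + 1:03d}" for j in range(self.n_proteins)]


@dataclass
class SimTruth:
    """Ground truth retained from the generator."""

    delta: np.ndarray  # structural scale (units of the generating equation)
    delta_std: np.ndarray  # in-sample standardized copy used by the indicators
    gprime: np.ndarray
    z_gds: np.ndarray
    a_true: float
    c_true: np.ndarray
    b_true: np.ndarray
    loadings: pd.DataFrame
    unique_sd: pd.Series
    indicators_raw: pd.DataFrame  # pre-scaling continuous indicators
    subject_id: pd.Index


@dataclass
class SimulatedCohort:
    observed: pd.DataFrame
    raw_panel: pd.DataFrame
    truth: SimTruth

    @property
    def protein_columns(self) -> list[str]:
        return [c for c in self.observed.columns if c.startswith("protein_")]


def _simulate_covariates(n: int, rho: float, rng: np.random.Generator):
    k = len(COVARIATES)
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    Z = rng.multivariate_normal(np.zeros(k), R, size=n, method="cholesky")
    U = stats.norm.cdf(Z)
    cov = pd.DataFrame(index=range(n))
    cov["age"] = 70.9 + 9.5 * Z[:, 0]
    cov["educ"] = np.clip(np.round(13.2 + 4.25 * Z[:, 1]), 0, 22)
    cov["ethnicity"] = (U[:, 2] < 0.36).astype(int)
    cov["gender"] = (U[:, 3] < 0.39).astype(int)
    cov["apoe4"] = np.select([U[:, 4] < 0.64, U[:, 4] < 0.97], [0, 1], default=2)
    cov["hcy"] = np.exp(2.2 + 0.35 * Z[:, 5])
    cov["hgba1c"] = np.exp(1.75 + 0.13 * Z[:, 6])
    return cov, Z, R


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a cohort under ``config`` with full ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    P = config.n_proteins
    eff = config.covariate_effects.reindex(COVARIATES)

    cov, Z, R = _simulate_covariates(n, config.covariate_corr, rng)

    # GDS: latent Gaussian tied to covariates, mapped through a
    # negative-binomial quantile transform for a right-skewed count
    beta_g = eff["gds"].to_numpy()
    sys_var = float(beta_g @ R @ beta_g)
    u = Z @ beta_g + rng.normal(size=n) * np.sqrt(max(0.1, 1.0 - sys_var))
    u = standardize(u)
    size = config.gds_size
    p_nb = size / (size + config.gds_mean)
    gds = np.clip(stats.nbinom.ppf(stats.norm.cdf(u), size, p_nb), 0, 30).astype(int)
    z_gds = standardize(gds)

    # proteins: true (QC-ideal) levels on an approximately unit scale
    beta_p = eff["protein"].to_numpy()
    noise_sd = np.sqrt(np.clip(1.0 - config.c_true**2, 0.1, None))
    proteins = (
        np.outer(z_gds, config.c_true)
        + (Z @ beta_p)[:, None]
        + rng.normal(size=(n, P)) * noise_sd
    )

    # latent delta and the orthogonal g'
    beta_d = eff["delta"].to_numpy()
    delta = (
        config.a_true * z_gds
        + proteins @ config.b_true
        + Z @ beta_d
        + rng.normal(size=n) * config.delta_disturbance_sd
    )
    gprime = rng.normal(size=n)
    delta_std = standardize(delta)
    gprime_std = standardize(gprime)

    # indicators: bifactor measurement model on the standardized factors
    lam = config.loadings.reindex(INDICATORS)
    uniq_var = 1.0 - lam["delta"] ** 2 - lam["gprime"] ** 2
    uniq_sd = np.sqrt(uniq_var.clip(lower=0.05))
    raw = {}
    for ind in INDICATORS:
        raw[ind] = (
            lam.loc[ind, "delta"] * delta_std
            + lam.loc[ind, "gprime"] * gprime_std
            + rng.normal(size=n) * uniq_sd[ind]
        )
    indicators_raw = pd.DataFrame(raw)

    obs = cov.copy()
    obs.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])
    obs["gds"] = gds
    for ind in COGNITIVE_INDICATORS:
        m, s = _SCALES[ind]
        obs[ind] = np.clip(np.round(m + s * indicators_raw[ind]), 0, 30).astype(int)
    # IADL: eight informant-rated 0-3 items driven by the (impairment-
    # oriented) raw indicator, summed to 0-24
    x = indicators_raw["iadl"].to_numpy()
    items = np.clip(
        np.round(1.31 + 0.62 * (x[:, None] + 0.4 * rng.normal(size=(n, 8)))), 0, 3
    )
    obs["iadl"] = items.sum(axis=1).astype(int)

    # clinical severity: deterministic monotone decreasing transform of delta
    cdr = 18.0 * stats.norm.cdf(-(delta_std + 1.5))
    obs["cdr_sb"] = np.clip(np.round(cdr * 2.0) / 2.0, 0.0, 18.0)

    ad_f, mci_f = config.diagnosis_fracs
    q_ad, q_mci = np.quantile(delta_std, [ad_f, ad_f + mci_f])
    obs["diagnosis"] = np.select(
        [delta_std <= q_ad, delta_std <= q_mci], ["AD", "MCI"], default="NC"
    )

    batch = rng.integers(0, config.n_batches, size=n)
    obs["batch"] = np.array([f"B{b + 1}" for b in batch])

    pnames = config.protein_names()
    obs = pd.concat([obs, pd.DataFrame(proteins, columns=pnames, index=obs.index)], axis=1)

    raw_panel = distort_panel(
        pd.DataFrame(proteins, columns=pnames), config, batch_labels=obs["batch"], rng=rng,
        subject_id=obs["subject_id"],
    )

    truth = SimTruth(
        delta=delta,
        delta_std=delta_std,
        gprime=gprime_std,
        z_gds=z_gds,
        a_true=config.a_true,
        c_true=config.c_true.copy(),
        b_true=config.b_true.copy(),
        loadings=lam.copy(),
        unique_sd=uniq_sd,
        indicators_raw=indicators_raw,
        subject_id=pd.Index(obs["subject_id"]),
    )
    return SimulatedCohort(observed=obs, raw_panel=raw_panel, truth=truth)


def distort_panel(
    true_levels: pd.DataFrame,
    config: SimConfig,
    batch_labels: pd.Series | None = None,
    rng: np.random.Generator | None = None,
    subject_id: pd.Series | None = None,
) -> pd.DataFrame:
    """Turn true protein levels into a raw duplicate-read analyte panel.

    Applies an exponential link (right skew), additive log-scale batch
    shifts, duplicate splitting with relative error ``duplicate_cv``,
    LDD censoring at the ``ldd_quantile`` of each analyte's raw
    distribution, and gross-error outliers.  Returns a long table with
    one row per subject x analyte.
    """
    if not np.all(np.isfinite(true_levels.to_numpy())):
        raise ValueError("true levels must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, P = true_levels.shape
    if batch_labels is None:
        batch_labels = pd.Series(np.array([f"B{b + 1}" for b in rng.integers(0, config.n_batches, n)]))
    if subject_id is None:
        subject_id = pd.Series([f"S{i:05d}" for i in range(n)])
    shift_map = {f"B{i + 1}": s for i, s in enumerate(config.batch_shifts)}
    shifts = batch_labels.map(shift_map).to_numpy(float)

    # per-analyte raw scale (location/spread on the log scale)
    mus = rng.uniform(0.5, 3.0, size=P)
    sigmas = rng.uniform(0.3, 0.7, size=P)

    frames = []
    cv = config.duplicate_cv
    for j, name in enumerate(true_levels.columns):
        log_raw = mus[j] + sigmas[j] * true_levels.iloc[:, j].to_numpy() + shifts
        raw = np.exp(log_raw)
        reps = []
        for _ in range(2):
            r = raw * np.exp(cv * rng.normal(size=n) - 0.5 * cv**2) if cv > 0 else raw.copy()
            out = rng.random(n) < config.outlier_rate
            r[out] = r[out] * np.exp(rng.uniform(1.5, 3.0, size=int(out.sum())))
            reps.append(r)
        if config.ldd_quantile > 0:
            ldd = float(np.quantile(raw, config.ldd_quantile))
        else:
            ldd = float(raw.min()) * 0.5  # below every reading: no LOW flags
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id.to_numpy(),
                    "analyte": name,
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "low1": reps[0] < ldd,
                    "low2": reps[1] < ldd,
                    "ldd": ldd,
                    "batch": batch_labels.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def inject_missingness(cohort: SimulatedCohort, config: SimConfig) -> SimulatedCohort:
    """Missing-at-random deletion per block; ground truth untouched.

    The block rate applies independently to each column of the block
    (GDS, covariates, indicators), so the complete-case fraction under a
    rate r on k columns is (1-r)^k.
    """
    for k, r in config.missing_rates.items():
        if not (0 <= r < 1):
            raise ValueError(f"missing rate for {k!r} must be in [0, 1)")
    rng = np.random.default_rng([1, max(config.seed, 0)])
    obs = cohort.observed.copy()
    blocks = {
        "gds": ["gds"],
        "covariates": COVARIATES,
        "indicators": INDICATORS,
    }
    for block, cols in blocks.items():
        rate = config.missing_rates.get(block, 0.0)
        if rate <= 0:
            continue
        for c in cols:
            mask = rng.random(len(obs)) < rate
            obs.loc[mask, c] = np.nan
    return SimulatedCohort(observed=obs, raw_panel=cohort.raw_panel, truth=cohort.truth)
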