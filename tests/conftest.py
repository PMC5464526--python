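import numpy as np
import pandas as pd
import pytest


def make_exact_corr_data(R: np.ndarray, n: int = 200, seed: int = 0) -> np.ndarray:
    """Data whose *sample* correlation matrix (ddof=1) equals R exactly.

    Lets closed-form CFA oracles be checked to machine precision."""
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, R.shape[0]))
    Z = Z - Z.mean(axis=0)
    C = np.cov(Z, rowvar=False, ddof=1)
    W = np.linalg.cholesky(np.linalg.inv(C))
    return (Z @ W) @ np.linalg.cholesky(R).T


@pytest.fixture(scope="session")
def triad_data() -> pd.DataFrame:
    """Three indicators with sample correlations r12=.56, r13=.48, r23=.42,
    for which the one-factor model has the closed-form solution
    lambda = (0.8, 0.7, 0.6)."""
    R = np.array([[1.0, 0.56, 0.48], [0.56, 1.0, 0.42], [0.48, 0.42, 1.0]])
    return pd.DataFrame(make_exact_corr_data(R, n=200, seed=0), columns=["x1", "x2", "x3"])


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort reused across read-only tests."""
    from deltamed import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_subjects=800, seed=11, n_proteins=6))


@pytest.fixture(scope="session")
def path_model_data() -> pd.DataFrame:
    """Complete-data recursive mediation system with known coefficients."""
    rng = np.random.default_rng(42)
    n = 3000
    g = rng.normal(size=n)
    z1 = 0.3 * g + rng.normal(size=n)
    z2 = rng.normal(size=n)
    prot = 0.5 * g + 0.1 * z1 + rng.normal(size=n) * 0.85
    deq = -0.10 * g - 0.3 * prot + 0.15 * z1 - 0.05 * z2 + rng.normal(size=n) * 0.7
    return pd.DataFrame({"gds_z": g, "protein_x": prot, "deq_w2": deq, "z1": z1, "z2": z2})
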