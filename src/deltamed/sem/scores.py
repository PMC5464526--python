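"""Regression-method factor scores and factor determinacy.

The regression ("Thurstone") weights are W = C Sigma^-1 where C is the
model-implied factor-by-indicator covariance and Sigma the implied
indicator covariance; under unit-variance identification of a single
factor this reduces to the familiar W = Phi Lambda' Sigma^-1.  Factor
determinacy is the correlation between the weighted composite and the
factor it estimates (Grice's criterion: values near 1 mean the
composite can stand in for the factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["factor_score_weights", "factor_determinacy"]


def _latent_observed_cov(fit, group: int = 0):
    ram = fit.rams[group]
    theta = fit.theta[fit._theta_map(group)]
    A, S, _ = ram.matrices(theta)
    nv = len(ram.names)
    B = np.linalg.inv(np.eye(nv) - A)
    V = B @ S @ B.T
    pos = {v: i for i, v in enumerate(ram.names)}
    lat = [v for v in fit.spec.latents]
    li = np.array([pos[v] for v in lat])
    oi = ram.obs_idx
    return lat, ram.obs_names, V[np.ix_(li, oi)], V[np.ix_(oi, oi)], V[np.ix_(li, li)]


def factor_score_weights(fit, group: int = 0) -> pd.DataFrame:
    """Regression-method factor score weights (factor x indicator).

    Applied to a (standardized) indicator row vector these weights give
    the composite score for each factor.
    """
    if not fit.converged:
        raise ValueError("factor scores require a converged fit")
    lat, obs, C, Sigma, _ = _latent_observed_cov(fit, group)
    if not lat:
        raise ValueError("model has no latent factors")
    try:
        W = np.linalg.solve(Sigma, C.T).T  # C Sigma^-1
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("implied covariance is singular") from e
    return pd.DataFrame(W, index=lat, columns=obs)


def factor_determinacy(fit, group: int = 0) -> pd.Series:
    """Per-factor determinacy coefficient in [0, 1]."""
    if not fit.converged:
        raise ValueError("factor determinacy requires a converged fit")
    lat, obs, C, Sigma, Phi = _latent_observed_cov(fit, group)
    if not lat:
        raise ValueError("model has no latent factors")
    X = np.linalg.solve(Sigma, C.T)  # Sigma^-1 C'
    quad = np.einsum("ij,ji->i", C, X)  # diag(C Sigma^-1 C')
    var_f = np.diag(Phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt(np.clip(quad / var_f, 0.0, 1.0))
    return pd.Series(rho, index=lat, name="determinacy")
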