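"""Closed-form population moments of the structural twin model.

Every quantity the estimation pipeline produces — the three correlation
kinds, the Model 1-3 coefficients, the Pr decomposition — has an exact
population value obtainable by linear algebra on the model covariance.
Those exact values serve as the oracle for all estimation code: simulated
estimates at large n must converge to them.

On the standardized latent scale the within-individual trait covariance is
W = D R (S + U) R' D and the cross-twin covariance is C = D R S R' D, with
R = (I - B)^{-1} the reduced form, S the pair-shared shock covariance, U the
diagonal unique covariance and D the standardizing scale.  Model 1/2
coefficients are covariance ratios and Model 3 solves the 2x2 normal
equations of (X_self, X_cotwin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import SimulationConfig
from .falcon import Decomposition, IceFalconTriplet, decompose
from .simulate import reduced_form

__all__ = ["PopulationMoments", "latent_correlations", "population_moments", "theoretical_coefficients"]


@dataclass
class PopulationMoments:
    """Exact covariance of (X_self, X_cotwin, Y_self, Y_cotwin), standardized."""

    covariance: np.ndarray
    rho_x: float
    predictor: str
    outcome: str


def latent_correlations(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(W, C): within-individual and cross-twin trait correlation matrices."""
    R = reduced_form(config)
    S, U = config.shared_cov(), config.unique_cov()
    within = R @ (S + U) @ R.T
    cross = R @ S @ R.T
    d = 1.0 / np.sqrt(np.diag(within))
    W = within * np.outer(d, d)
    C = cross * np.outer(d, d)
    return W, C


def _adjusted_entries(
    W: np.ndarray, C: np.ndarray, ix: int, iy: int, iz: int
) -> tuple[float, float, float, float]:
    """Standardized (W_xy, C_xy, rho_x, rho_y) after residualizing each
    individual's X and Y on her own Z score."""
    g = {a: W[a, iz] for a in (ix, iy)}

    def within_adj(a: int, b: int) -> float:
        return W[a, b] - g[a] * W[iz, b] - g[b] * W[a, iz] + g[a] * g[b]

    def cross_adj(a: int, b: int) -> float:
        return C[a, b] - g[a] * C[iz, b] - g[b] * C[a, iz] + g[a] * g[b] * C[iz, iz]

    var_x = 1.0 - W[ix, iz] ** 2
    var_y = 1.0 - W[iy, iz] ** 2
    if var_x <= 0 or var_y <= 0:
        raise ValueError("third-score adjustment removes all variance")
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)
    w_xy = within_adj(ix, iy) / (sx * sy)
    c_xy = cross_adj(ix, iy) / (sx * sy)
    rho_x = cross_adj(ix, ix) / var_x
    rho_y = cross_adj(iy, iy) / var_y
    return w_xy, c_xy, rho_x, rho_y


def population_moments(
    config: SimulationConfig,
    predictor: str,
    outcome: str,
    adjust_for: Optional[str] = None,
) -> PopulationMoments:
    """Exact 4-variable covariance for one (predictor, outcome) assignment."""
    for t in (predictor, outcome, *( [adjust_for] if adjust_for else [])):
        if t not in config.traits:
            raise ValueError(f"trait {t!r} not in config")
    W, C = latent_correlations(config)
    ix, iy = config.traits.index(predictor), config.traits.index(outcome)
    if adjust_for is None:
        w_xy, c_xy = W[ix, iy], C[ix, iy]
        rho_x, rho_y = C[ix, ix], C[iy, iy]
    else:
        iz = config.traits.index(adjust_for)
        w_xy, c_xy, rho_x, rho_y = _adjusted_entries(W, C, ix, iy, iz)
    cov = np.array(
        [
            [1.0, rho_x, w_xy, c_xy],
            [rho_x, 1.0, c_xy, w_xy],
            [w_xy, c_xy, 1.0, rho_y],
            [c_xy, w_xy, rho_y, 1.0],
        ]
    )
    return PopulationMoments(covariance=cov, rho_x=float(rho_x), predictor=predictor, outcome=outcome)


def _gee_limit(w_xy: float, c_xy: float, rho_x: float, rho_y: float, model: int) -> float:
    """Population limit of the exchangeable-GEE slope for Model 1 or 2.

    Models 1 and 2 are deliberately misspecified marginal models (the true
    conditional mean involves both twins' predictors), so the estimating
    equations weighted by the working correlation alpha converge to
    (target - alpha * other) / (1 - alpha * rho_x), with alpha the residual
    within-pair correlation at the solution — a fixed point, not a plain
    covariance ratio.  Model 3 is correctly specified and has no such shift.
    """
    target, other = (w_xy, c_xy) if model == 1 else (c_xy, w_xy)
    beta, alpha = target, 0.0
    for _ in range(200):
        beta_new = (target - alpha * other) / (1.0 - alpha * rho_x)
        var_r = 1.0 + beta_new**2 - 2.0 * beta_new * target
        cov_r = rho_y + beta_new**2 * rho_x - 2.0 * beta_new * other
        alpha_new = cov_r / var_r
        if abs(beta_new - beta) < 1e-14 and abs(alpha_new - alpha) < 1e-14:
            beta, alpha = beta_new, alpha_new
            break
        beta, alpha = beta_new, alpha_new
    return beta


def theoretical_coefficients(
    config: SimulationConfig,
    predictor: str,
    outcome: str,
    adjust_for: Optional[str] = None,
    working: str = "independence",
) -> tuple[PopulationMoments, IceFalconTriplet, Decomposition]:
    """Exact Model 1-3 coefficients and Pr decomposition for one assignment.

    ``working`` selects the estimand and must match the fitting choice.
    "independence" (default, matching :func:`icefalcon.falcon.fit_models`)
    gives the covariance ratios of the path-tracing algebra, under which the
    pure-causation and pure-confounding Pr identities hold exactly.
    "exchangeable" gives the population limit of an exchangeable-weighted
    GEE, which differs for Models 1 and 2 because their mean models are
    misspecified by design — the shift grows with the residual within-pair
    correlation and can push the population Pr outside [0, 1].
    """
    mom = population_moments(config, predictor, outcome, adjust_for)
    cov = mom.covariance
    rho = mom.rho_x
    rho_y = cov[2, 3]
    if working == "independence":
        beta_self = cov[2, 0]  # cov(Y_self, X_self), unit predictor variance
        beta_cotwin = cov[2, 1]
    elif working == "exchangeable":
        beta_self = _gee_limit(cov[2, 0], cov[2, 1], rho, rho_y, model=1)
        beta_cotwin = _gee_limit(cov[2, 0], cov[2, 1], rho, rho_y, model=2)
    else:
        raise ValueError(f"unknown working correlation {working!r}")
    if np.isclose(abs(rho), 1.0):
        raise ValueError("|rho_x| = 1: Model 3 normal equations are singular")
    # Model 3 is correctly specified: its coefficients solve the normal
    # equations in the true covariances whatever the working correlation
    gram = np.array([[1.0, rho], [rho, 1.0]])
    prime = np.linalg.solve(gram, np.array([cov[2, 0], cov[2, 1]]))
    triplet = IceFalconTriplet(
        beta_self=float(beta_self),
        beta_cotwin=float(beta_cotwin),
        beta_self_prime=float(prime[0]),
        beta_cotwin_prime=float(prime[1]),
    )
    dec = decompose(triplet, rho)
    return mom, triplet, dec
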