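"""Parameter state and log-density kernels for the spatially varying mixture model.

The model for subject i at location s_i is

    logit p_i = beta_i0 + sum_j beta_ij * sum_k omega_jk q_ijk + sum_b theta_b x_ib
    Y_i ~ Bernoulli(p_i)

with spatial fields beta_0 and beta_j given mean-zero MVN priors with
covariance (1/tau) * Omega(rho) (Matérn-3/2 correlation), importance
weights omega_j ~ Dirichlet(alpha) on the simplex, covariate effects
theta_b ~ N(0, sigma_b^2) with sigma_b ~ Uniform(0, 10), and rho uniform
over the observed inter-point distance range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gammaln

from .data import QuantizedComponents
from .spatial import correlation_matrix

__all__ = [
    "Parameters",
    "PriorSpec",
    "group_index",
    "group_indices",
    "linear_predictor",
    "linear_predictors",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "mvn_field_logpdf",
    "dirichlet_logpdf",
]

_SIMPLEX_TOL = 1e-9


@dataclass
class Parameters:
    """One state of all model unknowns.

    ``beta0`` is the spatial intercept field (length n, or a scalar when the
    intercept is modelled as constant), ``beta`` the (n, C) matrix of mixture
    fields, ``omega`` the per-mixture weight simplices, ``theta`` the
    covariate effects, ``rho`` the shared spatial range, ``tau_beta`` the
    field precisions ordered (intercept, mixture 1, ..., mixture C), and
    ``sigma_theta`` the covariate prior scales.
    """

    beta0: np.ndarray
    beta: np.ndarray
    omega: dict[str, np.ndarray]
    theta: np.ndarray
    rho: float
    tau_beta: np.ndarray
    sigma_theta: np.ndarray

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.omega = {k: np.asarray(v, dtype=float) for k, v in self.omega.items()}
        for name, w in self.omega.items():
            if np.any(w <= 0) or np.any(w >= 1) or abs(w.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"omega[{name!r}] must lie in the open simplex")
        self.theta = np.asarray(self.theta, dtype=float)
        self.tau_beta = np.asarray(self.tau_beta, dtype=float)
        if np.any(self.tau_beta <= 0):
            raise ValueError("field precisions tau_beta must be > 0")
        self.sigma_theta = np.asarray(self.sigma_theta, dtype=float)
        if self.rho <= 0:
            raise ValueError("rho must be > 0")

    def copy(self) -> "Parameters":
        return Parameters(
            self.beta0.copy(),
            self.beta.copy(),
            {k: v.copy() for k, v in self.omega.items()},
            self.theta.copy(),
            self.rho,
            self.tau_beta.copy(),
            self.sigma_theta.copy(),
        )


@dataclass
class PriorSpec:
    """Hyperparameters: Dirichlet concentrations, scale bound, rho support, jitter."""

    alpha: dict[str, np.ndarray]
    rho_bounds: tuple[float, float]
    sigma_upper: float = 10.0
    jitter: float = 1e-6

    def __post_init__(self):
        self.alpha = {k: np.asarray(v, dtype=float) for k, v in self.alpha.items()}
        for name, a in self.alpha.items():
            if np.any(a <= 0):
                raise ValueError(f"Dirichlet alpha for {name!r} must be positive")
        lo, hi = self.rho_bounds
        if not (0 < lo <= hi):
            raise ValueError("rho_bounds must satisfy 0 < lo <= hi")
        if self.sigma_upper <= 0:
            raise ValueError("sigma_upper must be > 0")


def group_index(q_row, omega) -> float:
    """Weighted quantile-score index for one subject: sum_k omega_k q_k."""
    q_row = np.asarray(q_row, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if q_row.shape != omega.shape:
        raise ValueError("component scores and weights differ in length")
    return float(q_row @ omega)


def group_indices(quantized: QuantizedComponents, omega: dict[str, np.ndarray]) -> np.ndarray:
    """(n, C) matrix of group indices, one column per mixture (in score order)."""
    return np.column_stack([quantized[name].astype(float) @ omega[name] for name in quantized.names])


def linear_predictors(
    params: Parameters, quantized: QuantizedComponents, covariates: np.ndarray | None
) -> np.ndarray:
    """Vector of linear predictors eta_i for all subjects."""
    idx = group_indices(quantized, params.omega)
    eta = params.beta0 + np.einsum("ij,ij->i", params.beta, idx)
    if covariates is not None and params.theta.size:
        eta = eta + covariates @ params.theta
    return eta


def linear_predictor(
    params: Parameters, quantized: QuantizedComponents, covariates: np.ndarray | None, i: int
) -> float:
    """Linear predictor for subject ``i`` (per-subject form of the model equation)."""
    eta = np.asarray(params.beta0, dtype=float)
    eta_i = float(eta[i]) if eta.ndim else float(eta)
    for j, name in enumerate(quantized.names):
        eta_i += params.beta[i, j] * group_index(quantized[name][i], params.omega[name])
    if covariates is not None and params.theta.size:
        eta_i += float(covariates[i] @ params.theta)
    return eta_i


def bernoulli_loglik(outcome: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihood terms using the stable log-sigmoid form."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    y = np.asarray(outcome, dtype=float)
    # y*eta - log(1 + e^eta), with logaddexp for stability
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def log_likelihood(
    params: Parameters, outcome: np.ndarray, quantized: QuantizedComponents,
    covariates: np.ndarray | None = None,
) -> float:
    """Bernoulli log likelihood of the outcome under the current state."""
    return bernoulli_loglik(outcome, linear_predictors(params, quantized, covariates))


def mvn_field_logpdf(field: np.ndarray, chol_omega: np.ndarray, tau: float) -> float:
    """Log density of a mean-zero MVN field with covariance (1/tau) * Omega.

    ``chol_omega`` is the lower Cholesky factor of the (jittered) correlation
    matrix Omega.
    """
    f = np.asarray(field, dtype=float)
    n = f.size
    w = solve_triangular(chol_omega, f, lower=True)
    return float(
        -0.5 * n * np.log(2 * np.pi)
        + 0.5 * n * np.log(tau)
        - np.sum(np.log(np.diag(chol_omega)))
        - 0.5 * tau * (w @ w)
    )


def dirichlet_logpdf(omega: np.ndarray, alpha: np.ndarray) -> float:
    omega = np.asarray(omega, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(omega <= 0) or abs(omega.sum() - 1.0) > 1e-6:
        return -np.inf
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(omega)).sum())


def log_prior(
    params: Parameters, priors: PriorSpec, locations: np.ndarray,
    chol_omega: np.ndarray | None = None,
) -> float:
    """Joint log prior; returns -inf (never raises) on support violations.

    Field-precision and covariate-scale priors are evaluated on the sigma
    scale (sigma ~ Uniform(0, sigma_upper), tau = sigma^-2).
    """
    lo, hi = priors.rho_bounds
    if not (lo <= params.rho <= hi):
        return -np.inf
    sigma_beta = params.tau_beta ** -0.5
    if np.any(sigma_beta >= priors.sigma_upper):
        return -np.inf
    if params.sigma_theta.size and (
        np.any(params.sigma_theta <= 0) or np.any(params.sigma_theta >= priors.sigma_upper)
    ):
        return -np.inf

    if chol_omega is None:
        chol_omega = cholesky(correlation_matrix(locations, params.rho, priors.jitter), lower=True)

    lp = 0.0
    fields = [np.asarray(params.beta0, dtype=float)] if np.ndim(params.beta0) else []
    fields += [params.beta[:, j] for j in range(params.beta.shape[1])]
    if len(fields) != params.tau_beta.size:
        raise ValueError("tau_beta size must match the number of spatial fields")
    for f, tau in zip(fields, params.tau_beta):
        lp += mvn_field_logpdf(f, chol_omega, tau)
    for name, w in params.omega.items():
        lp += dirichlet_logpdf(w, priors.alpha[name])
    lp += -np.log(hi - lo) if hi > lo else 0.0
    # uniform densities for the scale parameters
    n_scales = params.tau_beta.size + params.sigma_theta.size
    lp += -n_scales * np.log(priors.sigma_upper)
    # covariate effects
    if params.theta.size:
        s = params.sigma_theta
        lp += float(
            np.sum(-0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (params.theta / s) ** 2)
        )
    return lp


def log_posterior(
    params: Parameters,
    outcome: np.ndarray,
    quantized: QuantizedComponents,
    priors: PriorSpec,
    locations: np.ndarray,
    covariates: np.ndarray | None = None,
    chol_omega: np.ndarray | None = None,
) -> float:
    """Unnormalised log posterior; -inf from the prior propagates."""
    lp = log_prior(params, priors, locations, chol_omega=chol_omega)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, outcome, quantized, covariates)
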