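"""Matérn-3/2 spatial correlation and Gaussian-field conditioning.

The coefficient fields in the spatially varying mixture model carry a
Gaussian-process prior with the Matérn correlation function of smoothness
3/2,

    corr(d) = (1 + d/rho) * exp(-d/rho),

where ``d`` is Euclidean distance and ``rho`` the spatial range. A field
``f`` with precision ``tau`` has covariance ``(1/tau) * Omega`` where
``Omega`` is the correlation matrix over the observation locations.
Prediction at unobserved locations (kriging) is multivariate-normal
conditioning on the observed field values.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, cholesky
from scipy.spatial.distance import cdist, pdist

DEFAULT_JITTER = 1e-6

__all__ = [
    "DEFAULT_JITTER",
    "MaternParams",
    "matern32_correlation",
    "correlation_matrix",
    "pairwise_distance_bounds",
    "conditional_field_draw",
    "ConditionalGaussianField",
]


class MaternParams:
    """Matérn parameters: free range ``rho``; smoothness 3/2 and unit scale are fixed."""

    smoothness = 1.5
    scale = 1.0

    def __init__(self, rho: float):
        if rho <= 0:
            raise ValueError(f"spatial range rho must be > 0, got {rho}")
        self.rho = float(rho)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MaternParams(rho={self.rho!r})"


def matern32_correlation(d, rho):
    """Matérn-3/2 correlation ``(1 + d/rho) exp(-d/rho)`` at distance(s) ``d``.

    Strictly decreasing in ``d`` and equal to 1 at ``d = 0``.
    """
    if rho <= 0:
        raise ValueError(f"spatial range rho must be > 0, got {rho}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    t = d / rho
    out = (1.0 + t) * np.exp(-t)
    return out if out.ndim else float(out)


def correlation_matrix(locations, rho, jitter: float = DEFAULT_JITTER) -> np.ndarray:
    """Matérn-3/2 correlation matrix over ``locations`` with ``jitter`` on the diagonal.

    ``locations`` is an (n, 2) array of planar coordinates (the caller is
    responsible for projecting geographic coordinates).
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if not np.all(np.isfinite(locations)):
        raise ValueError("locations must be finite")
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    n = locations.shape[0]
    d = cdist(locations, locations)
    if jitter == 0.0 and n > 1:
        off = d + np.eye(n)
        if np.any(off == 0.0):
            raise np.linalg.LinAlgError(
                "duplicate locations make the correlation matrix singular; "
                "use a nonzero diagonal jitter"
            )
    omega = matern32_correlation(d, rho)
    omega[np.diag_indices(n)] += jitter
    return omega


def pairwise_distance_bounds(locations) -> tuple[float, float]:
    """(min, max) Euclidean distance over distinct location pairs.

    Defines the support of the uniform prior on the spatial range ``rho``.
    Coincident pairs are ignored; fully coincident input is an error.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if locations.shape[0] < 2:
        raise ValueError("need at least two locations")
    d = pdist(locations)
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("all locations are identical: inter-point distances degenerate")
    return float(pos.min()), float(d.max())


def _chol_psd(mat: np.ndarray, base_jitter: float) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter on failure."""
    jit = base_jitter
    for _ in range(6):
        try:
            return cholesky(mat + jit * np.eye(mat.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jit = max(jit, 1e-12) * 10.0
    raise np.linalg.LinAlgError(
        f"covariance not positive definite even with jitter {jit:.1e}; "
        "check for duplicated locations or an extreme range parameter"
    )


class ConditionalGaussianField:
    """Kriging operator from observed to new locations for one range ``rho``.

    Precomputes the conditional mean map ``A = K_no K_oo^{-1}`` and the
    Cholesky factor of the correlation-scale conditional covariance
    ``K_nn - A K_on`` once, so several fields (sharing ``rho`` but with
    different precisions ``tau``) can be conditioned cheaply.
    """

    def __init__(self, obs_locs, new_locs, rho, jitter: float = DEFAULT_JITTER):
        obs_locs = np.atleast_2d(np.asarray(obs_locs, dtype=float))
        new_locs = np.atleast_2d(np.asarray(new_locs, dtype=float))
        k_oo = correlation_matrix(obs_locs, rho, jitter)
        lo = cholesky(k_oo, lower=True)
        k_no = matern32_correlation(cdist(new_locs, obs_locs), rho)
        self.mean_map = cho_solve((lo, True), k_no.T).T
        cond = correlation_matrix(new_locs, rho, jitter) - self.mean_map @ k_no.T
        cond = 0.5 * (cond + cond.T)
        # interpolation limit: conditional covariance numerically zero
        self._degenerate = float(np.max(np.diag(cond))) < 1e-10
        self.chol = None if self._degenerate else _chol_psd(cond, 0.0)

    def mean(self, field_obs: np.ndarray) -> np.ndarray:
        return self.mean_map @ np.asarray(field_obs, dtype=float)

    def draw(self, field_obs: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
        """One joint draw of the field at the new locations given ``field_obs``."""
        if tau <= 0:
            raise ValueError("field precision tau must be > 0")
        mu = self.mean(field_obs)
        if self._degenerate:
            return mu
        z = rng.standard_normal(self.chol.shape[0])
        return mu + (self.chol @ z) / np.sqrt(tau)


def conditional_field_draw(
    field_obs,
    obs_locs,
    new_locs,
    rho,
    tau,
    rng: np.random.Generator,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Draw the Gaussian field at ``new_locs`` conditional on its observed values.

    The joint field is mean-zero with covariance ``(1/tau) * Omega`` built from
    the Matérn-3/2 correlation at range ``rho``; the returned vector is one
    draw from the conditional MVN (mean ``S_no S_oo^-1 f``, covariance
    ``(1/tau)(S_nn - S_no S_oo^-1 S_on)``), reproducible for a given ``rng``.
    """
    cgf = ConditionalGaussianField(obs_locs, new_locs, rho, jitter=jitter)
    return cgf.draw(np.asarray(field_obs, dtype=float), tau, rng)
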