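"""Model front end: bundles data, design, priors, and log densities.

:class:`SpatialMixtureModel` is the user-facing entry point, in the style of
statsmodels model classes: construct it from a :class:`~svcmix.data.Dataset`
or a dataframe, then call :meth:`fit` to run the MCMC sampler and obtain a
:class:`~svcmix.results.SpatialMixtureResults` object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import likelihood as lk
from .data import Dataset, MixtureDesign, QuantizedComponents, quantize_components
from .spatial import pairwise_distance_bounds

__all__ = ["SpatialMixtureModel"]


class SpatialMixtureModel:
    """Bayesian spatially varying mixture (group index) logistic model.

    Parameters
    ----------
    dataset
        Case-control data: coordinates, binary outcome, raw component
        matrices per mixture, optional adjustment covariates.
    quantiles
        Number of quantile bins Q used to score components (4 = quartiles).
    alpha
        Dirichlet concentration per mixture (default: all-ones,
        non-informative). Either a single vector applied to every mixture or
        a dict keyed by mixture name.
    spatial_intercept
        If True (default) the intercept is a spatial field with the same
        Matérn GP prior family as the mixture fields; if False it is a
        constant effect treated like an adjustment covariate.
    sigma_upper, jitter
        Upper bound of the uniform priors on scale parameters, and the
        diagonal jitter used when factorising correlation matrices.
    """

    def __init__(
        self,
        dataset: Dataset,
        quantiles: int = 4,
        alpha=None,
        spatial_intercept: bool = True,
        sigma_upper: float = 10.0,
        jitter: float = 1e-6,
    ):
        self.dataset = dataset
        self.design = MixtureDesign(dict(dataset.component_names), quantiles)
        self.spatial_intercept = bool(spatial_intercept)
        self.quantized: QuantizedComponents = quantize_components(
            dataset.components, quantiles
        )
        self.mixture_names = list(dataset.components)

        names = list(dataset.covariate_names or ())
        x = dataset.covariates
        if not self.spatial_intercept:
            ones = np.ones((dataset.n, 1))
            x = ones if x is None else np.hstack([ones, x])
            names = ["intercept"] + names
        self.exog = x
        self.exog_names = tuple(names)

        if alpha is None:
            alpha = {m: np.ones(self.design.n_components(m)) for m in self.mixture_names}
        elif not isinstance(alpha, dict):
            alpha = {m: np.asarray(alpha, dtype=float) for m in self.mixture_names}
        self.priors = lk.PriorSpec(
            alpha=alpha,
            rho_bounds=pairwise_distance_bounds(dataset.locations),
            sigma_upper=sigma_upper,
            jitter=jitter,
        )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mixtures: dict[str, list[str]],
        outcome: str = "outcome",
        coords: tuple[str, str] = ("x", "y"),
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "SpatialMixtureModel":
        dataset = Dataset.from_dataframe(
            df, mixtures, outcome=outcome, coords=coords, covariates=covariates
        )
        return cls(dataset, **kwargs)

    # -- basic facts ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.dataset.n

    @property
    def locations(self) -> np.ndarray:
        return self.dataset.locations

    @property
    def outcome(self) -> np.ndarray:
        return self.dataset.outcome

    @property
    def n_exog(self) -> int:
        return 0 if self.exog is None else self.exog.shape[1]

    @property
    def n_fields(self) -> int:
        """Number of spatial fields (intercept, if spatial, plus one per mixture)."""
        return len(self.mixture_names) + (1 if self.spatial_intercept else 0)

    # -- densities --------------------------------------------------------
    def log_likelihood(self, params: lk.Parameters) -> float:
        return lk.log_likelihood(params, self.outcome, self.quantized, self.exog)

    def log_prior(self, params: lk.Parameters, chol_omega=None) -> float:
        return lk.log_prior(params, self.priors, self.locations, chol_omega=chol_omega)

    def log_posterior(self, params: lk.Parameters, chol_omega=None) -> float:
        return lk.log_posterior(
            params,
            self.outcome,
            self.quantized,
            self.priors,
            self.locations,
            covariates=self.exog,
            chol_omega=chol_omega,
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, config=None, init=None, progress: bool = False):
        """Run the MCMC sampler and return a results object.

        Parameters
        ----------
        config
            A :class:`~svcmix.sampler.SamplerConfig`; defaults are
            desk-scale (2 chains x 2000 burn-in + 2000 retained).
        init
            Optional dict of initial values (keys among ``beta0``, ``beta``,
            ``omega``, ``theta``, ``rho``, ``sigma_beta``, ``sigma_theta``)
            applied to every chain, overriding the overdispersed defaults.
        """
        from .results import SpatialMixtureResults
        from .sampler import SamplerConfig, run_mcmc

        if config is None:
            config = SamplerConfig()
        draws = run_mcmc(self, config, init=init, progress=progress)
        return SpatialMixtureResults(self, draws)
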