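"""Simulation-study pipeline: generate, fit, predict, evaluate, aggregate.

Runs the full loop for a named scenario — D synthetic datasets, an MCMC fit
per dataset, kriged 30x30 grid prediction with exceedance-based
significance, and per-dataset metrics aggregated into one summary row — the
package's analogue of the study summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from . import evaluate as ev
from .model import SpatialMixtureModel
from .results import SpatialMixtureResults
from .sampler import SamplerConfig
from .simulate import (
    ScenarioSpec,
    SimulatedDataset,
    dataset_seeds,
    generate_dataset,
    scenario_spec,
)

__all__ = ["fit_simulated", "evaluate_fit", "replicate_scenario", "StudyResult"]

UNIT_SQUARE = ((0.0, 1.0), (0.0, 1.0))


def fit_simulated(
    simdata: SimulatedDataset,
    config: SamplerConfig,
    spatial_intercept: bool = True,
    quantiles: int = 4,
) -> SpatialMixtureResults:
    """Fit the spatially varying mixture model to one simulated dataset."""
    model = SpatialMixtureModel(
        simdata.dataset, quantiles=quantiles, spatial_intercept=spatial_intercept
    )
    return model.fit(config)


def evaluate_fit(
    simdata: SimulatedDataset,
    results: SpatialMixtureResults,
    spec: ScenarioSpec | None = None,
    threshold: float = 0.95,
    grid_size: int = 30,
    grid_thin: int = 1,
    grid_seed: int = 0,
) -> ev.MetricsReport:
    """All study metrics for one fitted dataset against its ground truth."""
    if spec is None:
        spec = scenario_spec(simdata.scenario)
    mixes = list(simdata.true_effects)
    coef_mse, w_mse, w_mae, w_mae_med, prop = {}, {}, {}, {}, {}
    for m in mixes:
        post_mean = results.coefficient_means(m)
        coef_mse[m] = ev.coefficient_mse(simdata.true_means[m], post_mean)
        werr = ev.weights_error(simdata.true_weights[m], results.weights_[m])
        w_mse[m], w_mae[m], w_mae_med[m] = werr["mse"], werr["mae_mean"], werr["mae_median"]
        surface = spec.surfaces[m]
        summ = results.grid_summary(
            m,
            threshold=threshold,
            grid_size=grid_size,
            grid_thin=grid_thin,
            bounds=UNIT_SQUARE,
            seed=grid_seed,
        )
        masks = ev.stratum_masks(surface, summ.locations)
        two_sided = surface.pattern == "constant" and surface.constant_mean == 0.0
        prop[m] = ev.significant_proportion_by_stratum(summ.flags, masks, two_sided=two_sided)
    corr = None
    if len(mixes) >= 2:
        corr = ev.coefficient_correlation(
            results.coefficient_means(mixes[0]), results.coefficient_means(mixes[1])
        )
    return ev.MetricsReport(
        scenario=simdata.scenario,
        n_datasets=1,
        coefficient_mse=coef_mse,
        weights_mse=w_mse,
        weights_mae_mean=w_mae,
        weights_mae_median=w_mae_med,
        significant_proportion=prop,
        correlation=corr,
    )


@dataclass
class StudyResult:
    """Outcome of one scenario replication: per-dataset and aggregated metrics."""

    scenario: str
    reports: list[ev.MetricsReport]
    aggregate: ev.MetricsReport
    mean_grid: pd.DataFrame
    fits: list[SpatialMixtureResults] = dc_field(default_factory=list)
    simulated: list[SimulatedDataset] = dc_field(default_factory=list)


def replicate_scenario(
    name: str,
    n: int = 1000,
    n_datasets: int = 50,
    seed: int = 0,
    config: SamplerConfig | None = None,
    threshold: float = 0.95,
    grid_size: int = 30,
    grid_thin: int = 1,
    spatial_intercept: bool = True,
    keep_fits: bool = False,
) -> StudyResult:
    """Scaled-down replication of one simulation scenario.

    Generates ``n_datasets`` datasets of ``n`` subjects, fits each with the
    given sampler configuration (per-dataset sampler seeds derived from
    ``seed``), computes metrics, aggregates them, and averages the
    predicted-coefficient grid across datasets.
    """
    if config is None:
        config = SamplerConfig()
    spec = scenario_spec(name, n=n, n_datasets=n_datasets, seed=seed)
    seeds = dataset_seeds(spec)
    fit_seeds = np.random.default_rng(np.random.SeedSequence([seed, 1])).integers(
        2**31, size=n_datasets
    )
    reports, fits, sims = [], [], []
    grid_mean_acc: dict[str, np.ndarray] = {}
    grid_locs = None
    for d in range(n_datasets):
        simdata = generate_dataset(spec, int(seeds[d]))
        cfg = replace(config, seed=int(fit_seeds[d]))
        res = fit_simulated(simdata, cfg, spatial_intercept=spatial_intercept)
        rep = evaluate_fit(
            simdata,
            res,
            spec=spec,
            threshold=threshold,
            grid_size=grid_size,
            grid_thin=grid_thin,
            grid_seed=int(fit_seeds[d]),
        )
        reports.append(rep)
        for m in simdata.true_effects:
            summ = res.grid_summary(
                m, threshold=threshold, grid_size=grid_size, grid_thin=grid_thin,
                bounds=UNIT_SQUARE, seed=int(fit_seeds[d]),
            )
            grid_locs = summ.locations
            grid_mean_acc[m] = grid_mean_acc.get(m, 0.0) + summ.mean
        if keep_fits:
            fits.append(res)
            sims.append(simdata)
    frames = []
    for m, acc in grid_mean_acc.items():
        frames.append(
            pd.DataFrame(
                {
                    "field": m,
                    "x": grid_locs[:, 0],
                    "y": grid_locs[:, 1],
                    "mean": acc / n_datasets,
                }
            )
        )
    return StudyResult(
        scenario=name,
        reports=reports,
        aggregate=ev.aggregate_reports(reports),
        mean_grid=pd.concat(frames, ignore_index=True),
        fits=fits,
        simulated=sims,
    )
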