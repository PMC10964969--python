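"""Performance metrics for the simulation study.

Per fitted dataset: mean square error between the true mean effect surface
and the posterior-mean coefficients; MSE and absolute error (both the mean
and the median form are computed and labelled) between true and estimated
importance weights; the proportion of significant grid cells stratified by
the spatial process (vertical thirds for one-dimensional surfaces, nested
concentric sets where the true mean is at least 2 / 1 / 0.25 for radial
ones, the whole region for constant ones); and, for two-mixture fits, the
Pearson correlation between the two estimated coefficient fields.

Aggregation across the D datasets of a scenario uses the median for
coefficient MSE and the mean for everything else.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .simulate import SurfaceSpec, true_mean_surface

__all__ = [
    "coefficient_mse",
    "weights_error",
    "stratum_masks",
    "significant_proportion_by_stratum",
    "coefficient_correlation",
    "MetricsReport",
    "aggregate_reports",
]


def coefficient_mse(true_means, posterior_means) -> float:
    """Mean squared difference between true mean surface and posterior means."""
    t = np.asarray(true_means, dtype=float)
    e = np.asarray(posterior_means, dtype=float)
    if t.shape != e.shape:
        raise ValueError("true and estimated coefficient vectors differ in length")
    return float(np.mean((t - e) ** 2))


def weights_error(true_omega, est_omega) -> dict[str, float]:
    """MSE plus both absolute-error forms between true and estimated weights.

    Returns ``mse``, ``mae_mean`` (mean absolute error) and ``mae_median``
    (median absolute error).
    """
    t = np.asarray(true_omega, dtype=float)
    e = np.asarray(est_omega, dtype=float)
    if t.shape != e.shape:
        raise ValueError("weight vectors differ in length")
    abs_err = np.abs(t - e)
    return {
        "mse": float(np.mean((t - e) ** 2)),
        "mae_mean": float(abs_err.mean()),
        "mae_median": float(np.median(abs_err)),
    }


def stratum_masks(surface: SurfaceSpec, grid_locations) -> dict[str, np.ndarray]:
    """Ordered stratum masks over grid cells for one true surface.

    one_dim: disjoint vertical thirds (by cell-centre x); radial: nested
    sets where the true mean is >= 2, >= 1, >= 0.25; constant: one
    whole-region stratum labelled by its mean.
    """
    locs = np.atleast_2d(np.asarray(grid_locations, dtype=float))
    if surface.pattern == "one_dim":
        x = locs[:, 0]
        left, middle, right = surface.thirds_means
        return {
            f"mean_{left:g}": x < 1.0 / 3.0,
            f"mean_{middle:g}": (x >= 1.0 / 3.0) & (x < 2.0 / 3.0),
            f"mean_{right:g}": x >= 2.0 / 3.0,
        }
    if surface.pattern == "radial":
        mean = true_mean_surface(surface, locs)
        return {
            "mean_ge_2": mean >= 2.0,
            "mean_ge_1": mean >= 1.0,
            "mean_ge_0.25": mean >= 0.25,
        }
    return {f"mean_{surface.constant_mean:g}": np.ones(locs.shape[0], dtype=bool)}


def significant_proportion_by_stratum(
    flags, masks: dict[str, np.ndarray], two_sided: bool = False
) -> dict[str, float]:
    """Fraction of flagged grid cells per stratum.

    ``two_sided`` counts cells significant in either direction (used for
    the null surface); otherwise only positively flagged cells count.
    """
    flags = np.asarray(flags)
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError(f"stratum {name!r} contains no grid cells")
        sub = flags[mask]
        out[name] = float(np.mean(sub != 0) if two_sided else np.mean(sub == 1))
    return out


def coefficient_correlation(field1, field2) -> float:
    """Pearson correlation between two estimated coefficient fields."""
    f1 = np.asarray(field1, dtype=float)
    f2 = np.asarray(field2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("fields differ in length")
    if f1.std() == 0 or f2.std() == 0:
        raise ValueError("zero variance field; correlation undefined")
    return float(np.corrcoef(f1, f2)[0, 1])


@dataclass
class MetricsReport:
    """Metrics for one scenario, per dataset or aggregated over datasets."""

    scenario: str
    n_datasets: int
    coefficient_mse: dict[str, float]
    weights_mse: dict[str, float]
    weights_mae_mean: dict[str, float]
    weights_mae_median: dict[str, float]
    significant_proportion: dict[str, dict[str, float]]
    correlation: float | None = None
    aggregation: str = "single"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_row(self) -> pd.DataFrame:
        """Flat one-row table in the layout of the study summary table."""
        row: dict[str, object] = {
            "scenario": self.scenario,
            "n_datasets": self.n_datasets,
            "aggregation": self.aggregation,
        }
        for m, v in self.coefficient_mse.items():
            row[f"coef_mse[{m}]"] = v
        for m, v in self.weights_mse.items():
            row[f"weights_mse[{m}]"] = v
        for m, v in self.weights_mae_mean.items():
            row[f"weights_mae[{m}]"] = v
        for m, v in self.weights_mae_median.items():
            row[f"weights_mae_median[{m}]"] = v
        if self.correlation is not None:
            row["correlation"] = self.correlation
        for m, strata in self.significant_proportion.items():
            for s, v in strata.items():
                row[f"prop_sig[{m},{s}]"] = v
        return pd.DataFrame([row])


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Combine per-dataset reports: median for coefficient MSE, mean elsewhere."""
    if not reports:
        raise ValueError("no reports to aggregate")
    scenarios = {r.scenario for r in reports}
    if len(scenarios) != 1:
        raise ValueError(f"cannot aggregate across scenarios {sorted(scenarios)}")

    def _agg(getter, fn):
        keys = getter(reports[0]).keys()
        return {k: float(fn([getter(r)[k] for r in reports])) for k in keys}

    mixes = list(reports[0].significant_proportion)
    prop = {
        m: {
            s: float(np.mean([r.significant_proportion[m][s] for r in reports]))
            for s in reports[0].significant_proportion[m]
        }
        for m in mixes
    }
    corr = None
    if reports[0].correlation is not None:
        corr = float(np.mean([r.correlation for r in reports]))
    return MetricsReport(
        scenario=reports[0].scenario,
        n_datasets=sum(r.n_datasets for r in reports),
        coefficient_mse=_agg(lambda r: r.coefficient_mse, np.median),
        weights_mse=_agg(lambda r: r.weights_mse, np.mean),
        weights_mae_mean=_agg(lambda r: r.weights_mae_mean, np.mean),
        weights_mae_median=_agg(lambda r: r.weights_mae_median, np.mean),
        significant_proportion=prop,
        correlation=corr,
        aggregation="median coef MSE / mean otherwise",
    )
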