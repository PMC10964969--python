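"""Posterior summarisation: exceedance probabilities, significance maps,
odds ratios, and importance-weight summaries.

Significance of a spatially varying effect at a location follows the
exceedance-probability rule: the effect is flagged positive (negative) when
the share of posterior draws above (below) zero exceeds a threshold,
0.95 by default with 0.90 as the conventional alternative. Draws exactly
equal to zero count toward neither direction (a measure-zero event).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "exceedance_probability",
    "significance_flags",
    "odds_ratio_summary",
    "summarize_weights",
    "ExceedanceSummary",
    "summarize_field",
    "export_maps",
    "read_map_csv",
]


def exceedance_probability(samples, direction: str = "above") -> float:
    """Fraction of draws strictly above (or below) zero."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no posterior draws supplied")
    if direction == "above":
        return float(np.mean(samples > 0.0))
    if direction == "below":
        return float(np.mean(samples < 0.0))
    raise ValueError("direction must be 'above' or 'below'")


def significance_flags(p_above, p_below, threshold: float = 0.95) -> np.ndarray:
    """+1 / -1 / 0 flags from exceedance probabilities at ``threshold``.

    Both directions cannot fire for a threshold above one half.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1)")
    p_above = np.asarray(p_above, dtype=float)
    p_below = np.asarray(p_below, dtype=float)
    flags = np.zeros(p_above.shape, dtype=int)
    flags[p_above > threshold] = 1
    flags[p_below > threshold] = -1
    return flags


def odds_ratio_summary(samples) -> dict[str, float]:
    """Posterior summary of exp(coefficient): mean and percentile interval.

    The mean is the mean of the exponentiated draws (not the exponentiated
    mean); percentiles commute with the monotone exp transform.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no posterior draws supplied")
    ors = np.exp(samples)
    lo, med, hi = np.percentile(ors, [2.5, 50.0, 97.5])
    return {"mean": float(ors.mean()), "q2.5": float(lo), "median": float(med), "q97.5": float(hi)}


def summarize_weights(omega_draws, component_names=None) -> pd.DataFrame:
    """Componentwise posterior means and 95% intervals, ranked by mean.

    ``omega_draws`` is an (N, C) array of simplex draws (chains pooled);
    the posterior means themselves sum to one by linearity.
    """
    omega_draws = np.asarray(omega_draws, dtype=float)
    omega_draws = omega_draws.reshape(-1, omega_draws.shape[-1])
    c = omega_draws.shape[1]
    if component_names is None:
        component_names = [f"c{k + 1}" for k in range(c)]
    mean = omega_draws.mean(axis=0)
    lo, hi = np.percentile(omega_draws, [2.5, 97.5], axis=0)
    df = pd.DataFrame(
        {"component": list(component_names), "mean": mean, "q2.5": lo, "q97.5": hi}
    )
    df["rank"] = (-df["mean"]).rank(method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


@dataclass
class ExceedanceSummary:
    """Per-location posterior summary of one spatially varying effect."""

    locations: np.ndarray
    mean: np.ndarray
    q2_5: np.ndarray
    q97_5: np.ndarray
    p_above: np.ndarray
    p_below: np.ndarray
    flags: np.ndarray
    or_mean: np.ndarray
    threshold: float
    field: str = "beta"

    def reflag(self, threshold: float) -> "ExceedanceSummary":
        """Same summaries with significance flags at a different threshold."""
        return ExceedanceSummary(
            self.locations,
            self.mean,
            self.q2_5,
            self.q97_5,
            self.p_above,
            self.p_below,
            significance_flags(self.p_above, self.p_below, threshold),
            self.or_mean,
            threshold,
            self.field,
        )

    def to_dataframe(self, jitter_sd: float = 0.0, rng=None) -> pd.DataFrame:
        """Map-ready table; optional coordinate jitter for privacy (summaries untouched)."""
        locs = self.locations
        if jitter_sd > 0:
            rng = np.random.default_rng(rng)
            locs = locs + rng.normal(scale=jitter_sd, size=locs.shape)
        return pd.DataFrame(
            {
                "field": self.field,
                "x": locs[:, 0],
                "y": locs[:, 1],
                "mean": self.mean,
                "q2.5": self.q2_5,
                "q97.5": self.q97_5,
                "p_above": self.p_above,
                "p_below": self.p_below,
                "flag": self.flags,
                "or_mean": self.or_mean,
            }
        )


def summarize_field(
    draws, locations, threshold: float = 0.95, field: str = "beta"
) -> ExceedanceSummary:
    """Cellwise exceedance summary from pooled draws (N_draws, m) at m locations."""
    draws = np.asarray(draws, dtype=float)
    draws = draws.reshape(-1, draws.shape[-1])
    locations = np.asarray(locations, dtype=float)
    if draws.shape[1] != locations.shape[0]:
        raise ValueError("draw columns must match the number of locations")
    p_above = (draws > 0).mean(axis=0)
    p_below = (draws < 0).mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return ExceedanceSummary(
        locations=locations,
        mean=draws.mean(axis=0),
        q2_5=lo,
        q97_5=hi,
        p_above=p_above,
        p_below=p_below,
        flags=significance_flags(p_above, p_below, threshold),
        or_mean=np.exp(draws).mean(axis=0),
        threshold=threshold,
        field=field,
    )


def export_maps(
    summaries: list[ExceedanceSummary] | ExceedanceSummary,
    path,
    jitter_sd: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Write gridded/subject-level summaries to CSV, one row per location per field."""
    if isinstance(summaries, ExceedanceSummary):
        summaries = [summaries]
    df = pd.concat(
        [s.to_dataframe(jitter_sd=jitter_sd, rng=rng) for s in summaries], ignore_index=True
    )
    path = Path(path)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"could not write map export to {path}: {exc}") from exc
    return df


def read_map_csv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"field", "x", "y", "mean", "p_above", "p_below", "flag", "or_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"map CSV {path} missing columns {sorted(missing)}")
    return df
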