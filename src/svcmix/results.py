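"""Results object wrapping posterior draws with summaries and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference as inf
from .sampler import GridDraws, PosteriorDraws, gelman_rubin, make_grid, predict_grid

__all__ = ["SpatialMixtureResults"]


class SpatialMixtureResults:
    """Posterior of a fitted spatially varying mixture model.

    Carries the retained draws of every block; exposes pooled-chain point
    estimates, convergence diagnostics (Gelman-Rubin PSRF, converged when
    below 1.1), exceedance-probability significance summaries at subject
    locations and on a prediction grid, odds-ratio summaries, and ranked
    importance weights.
    """

    PSRF_LIMIT = 1.1

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._grid_cache: dict = {}

    # -- point estimates (chains pooled) ----------------------------------
    @property
    def weights_(self) -> dict[str, np.ndarray]:
        return {m: self.draws.omega[m].reshape(-1, self.draws.omega[m].shape[-1]).mean(axis=0)
                for m in self.draws.mixture_names}

    @property
    def theta_(self) -> np.ndarray:
        return self.draws.theta.reshape(-1, self.draws.theta.shape[-1]).mean(axis=0)

    @property
    def rho_(self) -> float:
        return float(self.draws.rho.mean())

    def coefficient_means(self, mixture: str) -> np.ndarray:
        """Posterior-mean spatially varying coefficient at each subject."""
        return self.draws.field_draws(mixture).reshape(-1, self.model.n).mean(axis=0)

    def coefficient_draws(self, mixture: str) -> np.ndarray:
        """(N_pooled, n) pooled draws of one coefficient field at subjects."""
        return self.draws.field_draws(mixture).reshape(-1, self.model.n)

    # -- inference ---------------------------------------------------------
    def weight_summary(self, mixture: str | None = None) -> pd.DataFrame:
        """Ranked posterior means and 95% intervals of the importance weights."""
        frames = []
        for m in [mixture] if mixture else self.draws.mixture_names:
            df = inf.summarize_weights(
                self.draws.omega[m], self.model.dataset.component_names[m]
            )
            df.insert(0, "mixture", m)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def subject_summary(self, mixture: str, threshold: float = 0.95) -> inf.ExceedanceSummary:
        """Exceedance summary of a mixture-effect field at the subject locations."""
        return inf.summarize_field(
            self.coefficient_draws(mixture), self.model.locations, threshold, field=mixture
        )

    def odds_ratios(self, mixture: str) -> pd.DataFrame:
        """Per-subject posterior summaries of the spatially varying odds ratio."""
        draws = self.coefficient_draws(mixture)
        rows = [inf.odds_ratio_summary(draws[:, i]) for i in range(draws.shape[1])]
        out = pd.DataFrame(rows)
        out.insert(0, "id", self.model.dataset.ids)
        return out

    def grid_draws(
        self,
        grid_size: int = 30,
        grid_thin: int | None = None,
        bounds=None,
        seed: int = 0,
    ) -> GridDraws:
        """Kriged posterior draws of every spatial field on a prediction grid."""
        key = (grid_size, grid_thin, bounds, seed)
        if key not in self._grid_cache:
            grid = make_grid(bounds, grid_size) if bounds is not None else None
            self._grid_cache[key] = predict_grid(
                self.draws,
                self.model.locations,
                grid_locations=grid,
                grid_size=grid_size,
                grid_thin=grid_thin or 1,
                jitter=self.model.priors.jitter,
                seed=seed,
            )
        return self._grid_cache[key]

    def grid_summary(
        self,
        mixture: str,
        threshold: float = 0.95,
        grid_size: int = 30,
        grid_thin: int | None = None,
        bounds=None,
        seed: int = 0,
    ) -> inf.ExceedanceSummary:
        gd = self.grid_draws(grid_size, grid_thin, bounds, seed)
        return inf.summarize_field(gd.pooled(mixture), gd.locations, threshold, field=mixture)

    # -- diagnostics -------------------------------------------------------
    def psrf(self) -> pd.DataFrame:
        """Gelman-Rubin PSRF per monitored scalar, with the < 1.1 convergence flag."""
        rows = []
        for name, arr in self.draws.scalar_draws().items():
            value = gelman_rubin(arr) if arr.shape[0] >= 2 else float("nan")
            rows.append(
                {
                    "parameter": name,
                    "psrf": value,
                    "converged": bool(value < self.PSRF_LIMIT) if np.isfinite(value) else False,
                    "defined": bool(np.isfinite(value)),
                }
            )
        return pd.DataFrame(rows)

    @property
    def converged(self) -> bool:
        tab = self.psrf()
        defined = tab[tab["defined"]]
        return bool(defined["converged"].all()) if len(defined) else False

    def acceptance_rates(self) -> list[dict[str, float]]:
        return self.draws.accept_rates

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary (weights, covariates, range, diagnostics)."""
        d = self.draws
        lines = []
        lines.append("Bayesian spatially varying mixture model")
        lines.append("=" * 56)
        lines.append(
            f"subjects: {self.model.n}    mixtures: {len(d.mixture_names)}"
            f"    chains: {d.n_chains}    retained/chain: {d.n_retained}"
        )
        lines.append(
            f"spatial intercept: {'yes' if d.spatial_intercept else 'no'}"
            f"    quantile bins: {self.model.design.quantiles}"
        )
        rho_draws = d.rho.ravel()
        lo, hi = np.percentile(rho_draws, [2.5, 97.5])
        lines.append(f"spatial range rho: {rho_draws.mean():.4f}  [{lo:.4f}, {hi:.4f}]")
        lines.append("")
        lines.append("Importance weights (posterior mean [95% CrI]):")
        ws = self.weight_summary()
        for _, r in ws.iterrows():
            lines.append(
                f"  {r['mixture']:>10s}  {r['component']:<16s}"
                f" {r['mean']:.3f} [{r['q2.5']:.3f}, {r['q97.5']:.3f}]  rank {int(r['rank'])}"
            )
        if self.model.n_exog:
            lines.append("")
            lines.append("Covariate effects (posterior mean [95% CrI]):")
            th = d.theta.reshape(-1, d.theta.shape[-1])
            for b, nm in enumerate(self.model.exog_names):
                lo, hi = np.percentile(th[:, b], [2.5, 97.5])
                lines.append(f"  {nm:<16s} {th[:, b].mean():+.3f} [{lo:+.3f}, {hi:+.3f}]")
        for m in d.mixture_names:
            cm = self.coefficient_means(m)
            lines.append("")
            lines.append(
                f"Field {m}: subject-level posterior mean coefficient"
                f" min {cm.min():+.3f} / median {np.median(cm):+.3f} / max {cm.max():+.3f}"
            )
        tab = self.psrf()
        n_bad = int((~tab.loc[tab["defined"], "converged"]).sum())
        worst = tab.loc[tab["defined"], "psrf"].max() if tab["defined"].any() else float("nan")
        lines.append("")
        lines.append(
            f"Gelman-Rubin: max PSRF {worst:.3f}; "
            f"{n_bad} monitored scalar(s) above {self.PSRF_LIMIT}"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SpatialMixtureResults: n={self.model.n}, "
            f"mixtures={self.draws.mixture_names}, chains={self.draws.n_chains}>"
        )

    # -- plotting ----------------------------------------------------------
    def plot_surface(self, mixture: str, grid_size: int = 30, grid_thin: int | None = None,
                     ax=None, **kwargs):
        """Heatmap of the posterior-mean coefficient surface on the grid."""
        import matplotlib.pyplot as plt

        summ = self.grid_summary(mixture, grid_size=grid_size, grid_thin=grid_thin)
        if ax is None:
            _, ax = plt.subplots()
        img = summ.mean.reshape(grid_size, grid_size)
        extent = [
            summ.locations[:, 0].min(), summ.locations[:, 0].max(),
            summ.locations[:, 1].min(), summ.locations[:, 1].max(),
        ]
        im = ax.imshow(img, origin="lower", extent=extent, **kwargs)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.set_title(f"posterior mean effect: {mixture}")
        ax.figure.colorbar(im, ax=ax)
        return ax
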