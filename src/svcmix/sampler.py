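"""MCMC for the spatially varying mixture model.

The posterior is simulated with a block sampler run over multiple
independent chains:

* each spatial field (intercept and one per mixture) is updated by
  elliptical slice sampling, which uses the MVN prior exactly and needs no
  tuning;
* each weight simplex is updated by an adaptive random-walk Metropolis step
  on the additive-log-ratio transform, with the Jacobian correction;
* covariate effects are adaptive scalar random walks;
* the spatial range ``rho`` is a reflective random walk within the
  inter-point distance bounds, re-factorising the correlation matrix on
  each proposal;
* scale parameters (field sigmas, covariate-prior sigmas) are reflective
  scalar random walks on (0, sigma_upper).

Proposal scales adapt toward target acceptance rates (0.234 for
multivariate blocks, 0.44 for scalars) during burn-in only, so the retained
chain is a valid Markov chain. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from . import likelihood as lk
from .spatial import ConditionalGaussianField, correlation_matrix

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "run_mcmc",
    "gelman_rubin",
    "make_grid",
    "predict_grid",
    "GridDraws",
]

logger = logging.getLogger("svcmix")


@dataclass(frozen=True)
class SamplerConfig:
    """Tuning knobs for :func:`run_mcmc`.

    ``grid_thin`` subsamples retained iterations for grid prediction only
    (1 = krige every retained draw). ``use_likelihood=False`` runs the
    prior-only chain, used for prior-recovery checks.
    """

    n_chains: int = 2
    burn_in: int = 2000
    retained: int = 2000
    thin: int = 1
    seed: int = 0
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.234
    adapt_window: int = 200
    adapt: bool = True
    jitter: float | None = None  # None -> use the model's prior jitter
    grid_size: int = 30
    grid_thin: int = 1
    use_likelihood: bool = True
    update_fields: bool = True
    update_omega: bool = True
    update_theta: bool = True
    update_rho: bool = True
    update_scales: bool = True
    progress_every: int = 1000

    def __post_init__(self):
        if self.burn_in < 0 or self.retained < 1 or self.thin < 1:
            raise ValueError("burn_in >= 0, retained >= 1, thin >= 1 required")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Retained draws per chain for every parameter block.

    Shapes: ``beta0`` (K, T, n) — or (K, T) when the intercept is constant
    and folded into ``theta``; ``beta`` (K, T, n, C); ``omega[name]``
    (K, T, C_j); ``theta`` (K, T, B); ``rho`` (K, T); ``sigma_beta``
    (K, T, F); ``sigma_theta`` (K, T, B).
    """

    beta0: np.ndarray
    beta: np.ndarray
    omega: dict[str, np.ndarray]
    theta: np.ndarray
    rho: np.ndarray
    sigma_beta: np.ndarray
    sigma_theta: np.ndarray
    mixture_names: list[str]
    spatial_intercept: bool
    seed: int
    accept_rates: list[dict[str, float]] = dc_field(default_factory=list)
    exog_names: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.rho.shape[0]

    @property
    def n_retained(self) -> int:
        return self.rho.shape[1]

    def field_names(self) -> list[str]:
        return (["beta0"] if self.spatial_intercept else []) + list(self.mixture_names)

    def field_draws(self, name: str) -> np.ndarray:
        """(K, T, n) draws of one spatial field by name."""
        if name == "beta0":
            if not self.spatial_intercept:
                raise KeyError("intercept is constant in this fit")
            return self.beta0
        j = self.mixture_names.index(name)
        return self.beta[..., j]

    def field_tau(self, name: str) -> np.ndarray:
        """(K, T) precision draws for one spatial field."""
        idx = self.field_names().index(name)
        return self.sigma_beta[..., idx] ** -2.0

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """All monitored scalar parameters as name -> (K, T) arrays."""
        out: dict[str, np.ndarray] = {"rho": self.rho}
        for name in self.mixture_names:
            for k in range(self.omega[name].shape[-1]):
                out[f"omega[{name},{k + 1}]"] = self.omega[name][..., k]
        for b, nm in enumerate(self.exog_names or [f"x{b+1}" for b in range(self.theta.shape[-1])]):
            out[f"theta[{nm}]"] = self.theta[..., b]
        for i, nm in enumerate(self.field_names()):
            out[f"sigma_beta[{nm}]"] = self.sigma_beta[..., i]
        for b, nm in enumerate(self.exog_names or [f"x{b+1}" for b in range(self.theta.shape[-1])]):
            out[f"sigma_theta[{nm}]"] = self.sigma_theta[..., b]
        return out

    # -- persistence ------------------------------------------------------
    def to_long_dataframe(self, include_fields: bool = False) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        frames = []
        scalars = self.scalar_draws()
        if include_fields:
            for nm in self.field_names():
                arr = self.field_draws(nm)
                for i in range(arr.shape[-1]):
                    scalars[f"{nm}[{i + 1}]"] = arr[..., i]
        for name, arr in scalars.items():
            for k in range(arr.shape[0]):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": k + 1,
                            "iteration": np.arange(1, arr.shape[1] + 1),
                            "parameter": name,
                            "value": arr[k],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def save_npz(self, path) -> None:
        payload = {
            "beta0": self.beta0,
            "beta": self.beta,
            "theta": self.theta,
            "rho": self.rho,
            "sigma_beta": self.sigma_beta,
            "sigma_theta": self.sigma_theta,
            "seed": np.asarray(self.seed),
            "spatial_intercept": np.asarray(self.spatial_intercept),
            "mixture_names": np.asarray(self.mixture_names),
            "exog_names": np.asarray(list(self.exog_names)),
        }
        for name, arr in self.omega.items():
            payload[f"omega__{name}"] = arr
        np.savez_compressed(path, **payload)

    @classmethod
    def load_npz(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            omega = {
                k.removeprefix("omega__"): z[k] for k in z.files if k.startswith("omega__")
            }
            return cls(
                beta0=z["beta0"],
                beta=z["beta"],
                omega=omega,
                theta=z["theta"],
                rho=z["rho"],
                sigma_beta=z["sigma_beta"],
                sigma_theta=z["sigma_theta"],
                mixture_names=[str(s) for s in z["mixture_names"]],
                spatial_intercept=bool(z["spatial_intercept"]),
                seed=int(z["seed"]),
                exog_names=tuple(str(s) for s in z["exog_names"]),
            )


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` is a (K, T) array of draws, K >= 2 chains of T >= 10 draws.
    PSRF = sqrt((T-1)/T + B/(T W)) with B the between- and W the
    within-chain variance. Returns NaN (undefined) when W = 0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (K, T) array with at least two chains")
    k, t = chains.shape
    if t < 10:
        raise ValueError("need at least 10 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b = t * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    return float(np.sqrt((t - 1) / t + b / (t * w)))


# ---------------------------------------------------------------------------
# internal chain machinery


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect ``x`` into the interval [lo, hi]."""
    width = hi - lo
    if width <= 0:
        return lo
    t = (x - lo) % (2.0 * width)
    return lo + (t if t <= width else 2.0 * width - t)


def _alr(omega: np.ndarray) -> np.ndarray:
    return np.log(omega[:-1]) - np.log(omega[-1])


def _alr_inv(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]) - max(0.0, np.max(z)))
    return e / e.sum()


class _Adaptive:
    """Robbins-Monro log-scale adaptation toward a target acceptance rate."""

    def __init__(self, target: float, scale: float = 0.1):
        self.target = target
        self.log_scale = np.log(scale)
        self.n_acc = 0
        self.n_try = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accept_prob: float, iteration: int, adapting: bool) -> None:
        self.n_try += 1
        if adapting:
            gamma = (iteration + 1.0) ** -0.6
            self.log_scale += gamma * (accept_prob - self.target)

    def record(self, accepted: bool) -> None:
        self.n_acc += bool(accepted)

    def rate(self) -> float:
        return self.n_acc / self.n_try if self.n_try else float("nan")


class _ChainState:
    """Mutable state for one chain, with cached Cholesky and linear predictor."""

    def __init__(self, model, config: SamplerConfig, rng: np.random.Generator):
        self.model = model
        self.config = config
        self.rng = rng
        self.jitter = model.priors.jitter if config.jitter is None else config.jitter
        n = model.n
        self.mix = model.mixture_names
        self.ncomp = {m: model.design.n_components(m) for m in self.mix}
        lo, hi = model.priors.rho_bounds

        # overdispersed initial state
        self.rho = float(rng.uniform(lo, hi))
        self.chol = cholesky(
            correlation_matrix(model.locations, self.rho, self.jitter), lower=True
        )
        self.sigma_beta = np.ones(model.n_fields)
        self.sigma_theta = np.ones(model.n_exog)
        self.omega = {
            m: rng.dirichlet(model.priors.alpha[m]) for m in self.mix
        }
        self.theta = rng.standard_normal(model.n_exog)
        if model.spatial_intercept:
            self.beta0 = self._field_prior_draw(tau=1.0)
        else:
            self.beta0 = 0.0
        self.beta = np.column_stack([self._field_prior_draw(tau=1.0) for _ in self.mix])

        # caches
        self.idx = np.column_stack(
            [model.quantized[m].astype(float) @ self.omega[m] for m in self.mix]
        )
        self._refresh_eta()

        # adaptation state
        tb, ts = config.target_accept_block, config.target_accept_scalar
        self.ad_omega = {
            m: _Adaptive(tb if self.ncomp[m] > 2 else ts) for m in self.mix if self.ncomp[m] > 1
        }
        self.ad_theta = [_Adaptive(ts, 0.5) for _ in range(model.n_exog)]
        self.ad_rho = _Adaptive(ts, 0.1 * (hi - lo))
        self.ad_sigma_beta = [_Adaptive(ts, 0.5) for _ in range(model.n_fields)]
        self.ad_sigma_theta = [_Adaptive(ts, 0.5) for _ in range(model.n_exog)]

    # -- helpers ----------------------------------------------------------
    def _field_prior_draw(self, tau: float) -> np.ndarray:
        z = self.rng.standard_normal(self.model.n)
        return (self.chol @ z) / np.sqrt(tau)

    def _refresh_eta(self) -> None:
        eta = np.broadcast_to(np.asarray(self.beta0, dtype=float), (self.model.n,)).copy()
        eta += np.einsum("ij,ij->i", self.beta, self.idx)
        if self.model.exog is not None and self.theta.size:
            eta += self.model.exog @ self.theta
        self.eta = eta

    def _loglik(self, eta: np.ndarray) -> float:
        if not self.config.use_likelihood:
            return 0.0
        return lk.bernoulli_loglik(self.model.outcome, eta)

    def _tau(self, f: int) -> float:
        return float(self.sigma_beta[f] ** -2.0)

    def _field_quad(self, values: np.ndarray) -> float:
        w = solve_triangular(self.chol, values, lower=True)
        return float(w @ w)

    def _fields(self) -> list[np.ndarray]:
        out = [self.beta0] if self.model.spatial_intercept else []
        return out + [self.beta[:, j] for j in range(len(self.mix))]

    # -- block updates ----------------------------------------------------
    def _ess_field(self, values: np.ndarray, tau: float, eta_rest: np.ndarray, mult):
        """Elliptical slice sampling for one field under its MVN prior.

        ``mult`` is the per-subject multiplier of the field in the linear
        predictor (1 for the intercept field, the group index otherwise).
        """
        rng = self.rng
        nu = self._field_prior_draw(tau)
        logy = self._loglik(eta_rest + mult * values) + np.log(rng.uniform())
        angle = rng.uniform(0.0, 2.0 * np.pi)
        lo, hi = angle - 2.0 * np.pi, angle
        while True:
            prop = values * np.cos(angle) + nu * np.sin(angle)
            if self._loglik(eta_rest + mult * prop) > logy:
                return prop
            if angle < 0:
                lo = angle
            else:
                hi = angle
            angle = rng.uniform(lo, hi)

    def update_fields(self) -> None:
        model = self.model
        f_off = 0
        if model.spatial_intercept:
            eta_rest = self.eta - self.beta0
            self.beta0 = self._ess_field(self.beta0, self._tau(0), eta_rest, 1.0)
            self.eta = eta_rest + self.beta0
            f_off = 1
        for j in range(len(self.mix)):
            mult = self.idx[:, j]
            eta_rest = self.eta - self.beta[:, j] * mult
            self.beta[:, j] = self._ess_field(self.beta[:, j], self._tau(f_off + j), eta_rest, mult)
            self.eta = eta_rest + self.beta[:, j] * mult

    def update_omega(self, iteration: int, adapting: bool) -> None:
        model = self.model
        for j, m in enumerate(self.mix):
            if self.ncomp[m] == 1:
                continue
            ad = self.ad_omega[m]
            alpha = model.priors.alpha[m]
            w = self.omega[m]
            z = _alr(w)
            z_prop = z + ad.scale * self.rng.standard_normal(z.size)
            w_prop = _alr_inv(z_prop)
            mult = self.beta[:, j]
            q = model.quantized[m].astype(float)
            idx_prop = q @ w_prop
            eta_prop = self.eta + mult * (idx_prop - self.idx[:, j])
            # Dirichlet density + ALR Jacobian (prod of all components)
            def _logtarget(wv, eta):
                return self._loglik(eta) + float(((alpha - 1.0) * np.log(wv)).sum()) + float(
                    np.log(wv).sum()
                )
            delta = _logtarget(w_prop, eta_prop) - _logtarget(w, self.eta)
            acc_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
            accepted = self.rng.uniform() < acc_prob
            if accepted:
                self.omega[m] = w_prop
                self.idx[:, j] = idx_prop
                self.eta = eta_prop
            ad.update(acc_prob, iteration, adapting)
            ad.record(accepted)

    def update_theta(self, iteration: int, adapting: bool) -> None:
        model = self.model
        for b in range(self.theta.size):
            ad = self.ad_theta[b]
            prop = self.theta[b] + ad.scale * self.rng.standard_normal()
            eta_prop = self.eta + (prop - self.theta[b]) * model.exog[:, b]
            s = self.sigma_theta[b]
            delta = (
                self._loglik(eta_prop)
                - self._loglik(self.eta)
                - 0.5 * (prop**2 - self.theta[b] ** 2) / s**2
            )
            acc_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
            accepted = self.rng.uniform() < acc_prob
            if accepted:
                self.theta[b] = prop
                self.eta = eta_prop
            ad.update(acc_prob, iteration, adapting)
            ad.record(accepted)

    def update_rho(self, iteration: int, adapting: bool) -> None:
        model = self.model
        lo, hi = model.priors.rho_bounds
        ad = self.ad_rho
        prop = _reflect(self.rho + ad.scale * self.rng.standard_normal(), lo, hi)
        chol_prop = None
        try:
            chol_prop = cholesky(
                correlation_matrix(model.locations, prop, self.jitter), lower=True
            )
        except np.linalg.LinAlgError:
            pass
        if chol_prop is None:
            acc_prob, accepted = 0.0, False
        else:
            fields = self._fields()
            taus = [self._tau(f) for f in range(len(fields))]
            logdet_old = np.sum(np.log(np.diag(self.chol)))
            logdet_new = np.sum(np.log(np.diag(chol_prop)))
            delta = 0.0
            for fvals, tau in zip(fields, taus):
                w_new = solve_triangular(chol_prop, fvals, lower=True)
                w_old = solve_triangular(self.chol, fvals, lower=True)
                delta += -logdet_new - 0.5 * tau * (w_new @ w_new)
                delta -= -logdet_old - 0.5 * tau * (w_old @ w_old)
            acc_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
            accepted = self.rng.uniform() < acc_prob
            if accepted:
                self.rho = prop
                self.chol = chol_prop
        ad.update(acc_prob, iteration, adapting)
        ad.record(accepted)

    def update_scales(self, iteration: int, adapting: bool) -> None:
        model = self.model
        upper = model.priors.sigma_upper
        n = model.n
        fields = self._fields()
        for f, fvals in enumerate(fields):
            ad = self.ad_sigma_beta[f]
            cur = self.sigma_beta[f]
            prop = _reflect(cur + ad.scale * self.rng.standard_normal(), 1e-12, upper)
            quad = self._field_quad(np.asarray(fvals, dtype=float))
            tau_cur, tau_prop = cur**-2.0, prop**-2.0
            delta = (
                0.5 * n * (np.log(tau_prop) - np.log(tau_cur))
                - 0.5 * (tau_prop - tau_cur) * quad
            )
            acc_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
            accepted = self.rng.uniform() < acc_prob
            if accepted:
                self.sigma_beta[f] = prop
            ad.update(acc_prob, iteration, adapting)
            ad.record(accepted)
        for b in range(self.sigma_theta.size):
            ad = self.ad_sigma_theta[b]
            cur = self.sigma_theta[b]
            prop = _reflect(cur + ad.scale * self.rng.standard_normal(), 1e-12, upper)
            th2 = self.theta[b] ** 2
            delta = (np.log(cur) - np.log(prop)) - 0.5 * th2 * (prop**-2.0 - cur**-2.0)
            acc_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
            accepted = self.rng.uniform() < acc_prob
            if accepted:
                self.sigma_theta[b] = prop
            ad.update(acc_prob, iteration, adapting)
            ad.record(accepted)

    def accept_rates(self) -> dict[str, float]:
        out = {}
        for m, ad in self.ad_omega.items():
            out[f"omega[{m}]"] = ad.rate()
        for b, ad in enumerate(self.ad_theta):
            out[f"theta[{b}]"] = ad.rate()
        out["rho"] = self.ad_rho.rate()
        for f, ad in enumerate(self.ad_sigma_beta):
            out[f"sigma_beta[{f}]"] = ad.rate()
        for b, ad in enumerate(self.ad_sigma_theta):
            out[f"sigma_theta[{b}]"] = ad.rate()
        return out

    def apply_init(self, init: dict) -> None:
        if "rho" in init:
            self.rho = float(init["rho"])
            self.chol = cholesky(
                correlation_matrix(self.model.locations, self.rho, self.jitter), lower=True
            )
        if "sigma_beta" in init:
            self.sigma_beta = np.broadcast_to(
                np.asarray(init["sigma_beta"], dtype=float), (self.model.n_fields,)
            ).copy()
        if "sigma_theta" in init:
            self.sigma_theta = np.broadcast_to(
                np.asarray(init["sigma_theta"], dtype=float), (self.model.n_exog,)
            ).copy()
        if "omega" in init:
            self.omega = {m: np.asarray(v, dtype=float) for m, v in init["omega"].items()}
            self.idx = np.column_stack(
                [self.model.quantized[m].astype(float) @ self.omega[m] for m in self.mix]
            )
        if "theta" in init:
            self.theta = np.asarray(init["theta"], dtype=float).copy()
        if "beta0" in init:
            self.beta0 = (
                np.asarray(init["beta0"], dtype=float).copy()
                if self.model.spatial_intercept
                else float(init["beta0"])
            )
        if "beta" in init:
            self.beta = np.atleast_2d(np.asarray(init["beta"], dtype=float)).copy()
        self._refresh_eta()


def _run_chain(model, config: SamplerConfig, seed_seq, init, chain_id: int):
    rng = np.random.default_rng(seed_seq)
    state = _ChainState(model, config, rng)
    if init:
        state.apply_init(init)

    t_keep = config.retained
    n = model.n
    c = len(model.mixture_names)
    store = {
        "beta0": np.zeros((t_keep, n)) if model.spatial_intercept else np.zeros(t_keep),
        "beta": np.zeros((t_keep, n, c)),
        "omega": {m: np.zeros((t_keep, model.design.n_components(m))) for m in model.mixture_names},
        "theta": np.zeros((t_keep, model.n_exog)),
        "rho": np.zeros(t_keep),
        "sigma_beta": np.zeros((t_keep, model.n_fields)),
        "sigma_theta": np.zeros((t_keep, model.n_exog)),
    }
    total = config.burn_in + config.retained * config.thin
    kept = 0
    for it in range(total):
        adapting = config.adapt and it < config.burn_in
        if config.update_fields:
            state.update_fields()
        if config.update_omega:
            state.update_omega(it, adapting)
        if config.update_theta and model.n_exog:
            state.update_theta(it, adapting)
        if config.update_rho:
            state.update_rho(it, adapting)
        if config.update_scales:
            state.update_scales(it, adapting)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            store["beta0"][kept] = state.beta0
            store["beta"][kept] = state.beta
            for m in model.mixture_names:
                store["omega"][m][kept] = state.omega[m]
            store["theta"][kept] = state.theta
            store["rho"][kept] = state.rho
            store["sigma_beta"][kept] = state.sigma_beta
            store["sigma_theta"][kept] = state.sigma_theta
            kept += 1
        if config.progress_every and (it + 1) % config.progress_every == 0:
            logger.info("chain %d: iteration %d/%d", chain_id + 1, it + 1, total)
    return store, state.accept_rates()


def run_mcmc(model, config: SamplerConfig, init: dict | None = None, progress: bool = False):
    """Run ``config.n_chains`` independent chains and collect retained draws."""
    if progress:
        logging.basicConfig(level=logging.INFO)
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    stores, rates = [], []
    for k, sq in enumerate(seqs):
        store, rate = _run_chain(model, config, sq, init, k)
        stores.append(store)
        rates.append(rate)
        logger.info("chain %d finished; acceptance rates: %s", k + 1, rate)
    draws = PosteriorDraws(
        beta0=np.stack([s["beta0"] for s in stores]),
        beta=np.stack([s["beta"] for s in stores]),
        omega={
            m: np.stack([s["omega"][m] for s in stores]) for m in model.mixture_names
        },
        theta=np.stack([s["theta"] for s in stores]),
        rho=np.stack([s["rho"] for s in stores]),
        sigma_beta=np.stack([s["sigma_beta"] for s in stores]),
        sigma_theta=np.stack([s["sigma_theta"] for s in stores]),
        mixture_names=list(model.mixture_names),
        spatial_intercept=model.spatial_intercept,
        seed=config.seed,
        accept_rates=rates,
        exog_names=tuple(model.exog_names),
    )
    return draws


# ---------------------------------------------------------------------------
# grid prediction


def make_grid(bounds=None, size: int = 30) -> np.ndarray:
    """Cell centers of a ``size x size`` grid over a bounding box.

    ``bounds`` is ((x_lo, x_hi), (y_lo, y_hi)); default is the unit square.
    """
    if bounds is None:
        bounds = ((0.0, 1.0), (0.0, 1.0))
    (x0, x1), (y0, y1) = bounds
    cx = x0 + (np.arange(size) + 0.5) * (x1 - x0) / size
    cy = y0 + (np.arange(size) + 0.5) * (y1 - y0) / size
    gx, gy = np.meshgrid(cx, cy, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class GridDraws:
    """Kriged field draws at grid locations: name -> (K, T_grid, m)."""

    locations: np.ndarray
    draws: dict[str, np.ndarray]
    iterations: np.ndarray

    def pooled(self, name: str) -> np.ndarray:
        """(K * T_grid, m) pooled-chain draws for one field."""
        arr = self.draws[name]
        return arr.reshape(-1, arr.shape[-1])


def predict_grid(
    draws: PosteriorDraws,
    obs_locations: np.ndarray,
    grid_locations: np.ndarray | None = None,
    grid_size: int = 30,
    grid_thin: int = 1,
    jitter: float = 1e-6,
    seed: int = 0,
    fields: list[str] | None = None,
) -> GridDraws:
    """Joint conditional (kriging) draws of each spatial field at grid cells.

    For every retained iteration used (every ``grid_thin``-th), the field
    values, range and precision of that iteration condition one joint MVN
    draw over the grid, so posterior uncertainty propagates into grid-cell
    exceedance probabilities.
    """
    obs_locations = np.asarray(obs_locations, dtype=float)
    if grid_locations is None:
        mins, maxs = obs_locations.min(axis=0), obs_locations.max(axis=0)
        grid_locations = make_grid(((mins[0], maxs[0]), (mins[1], maxs[1])), grid_size)
    grid_locations = np.asarray(grid_locations, dtype=float)
    names = fields if fields is not None else draws.field_names()
    its = np.arange(0, draws.n_retained, grid_thin)
    k_chains = draws.n_chains
    out = {nm: np.zeros((k_chains, its.size, grid_locations.shape[0])) for nm in names}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    field_arrs = {nm: draws.field_draws(nm) for nm in names}
    taus = {nm: draws.field_tau(nm) for nm in names}
    for k in range(k_chains):
        for ti, t in enumerate(its):
            cgf = ConditionalGaussianField(
                obs_locations, grid_locations, draws.rho[k, t], jitter=jitter
            )
            for nm in names:
                out[nm][k, ti] = cgf.draw(field_arrs[nm][k, t], taus[nm][k, t], rng)
    return GridDraws(locations=grid_locations, draws=out, iterations=its)
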