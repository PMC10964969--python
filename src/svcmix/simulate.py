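"""Synthetic case-control data with spatially varying mixture effects.

The generator reproduces the structure of the model's simulation study:
subjects placed uniformly on the unit square; one or two six-component
exposure mixtures drawn from multivariate normals with fixed correlation
structure; true importance weights on the simplex; a spatial effect surface
per mixture (constant, one-dimensional thirds, or radial decay from the
centre), perturbed location-wise with SD 0.1; and Bernoulli outcomes whose
intercept is calibrated by bisection to an approximately 1:1 case:control
ratio.

Five named scenarios are built in, keyed by their spatial pattern:
``constant-null``, ``one_dim``, ``radial``, ``two_mix_one_dim``,
``two_mix_radial``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, quantize_components

__all__ = [
    "SurfaceSpec",
    "ScenarioSpec",
    "SimulatedDataset",
    "OMEGA_MIX1",
    "OMEGA_MIX2",
    "CORR_MIX1",
    "CORR_MIX2",
    "SCENARIO_NAMES",
    "scenario_spec",
    "true_mean_surface",
    "sample_locations",
    "sample_components",
    "sample_effects",
    "calibrate_intercept",
    "simulate_outcomes",
    "generate_dataset",
    "generate_scenario",
    "dataset_seeds",
]

# true importance weights of the two study mixtures
OMEGA_MIX1 = np.array([0.30, 0.20, 0.20, 0.13, 0.10, 0.07])
OMEGA_MIX2 = np.array([0.45, 0.15, 0.15, 0.15, 0.05, 0.05])

# component correlation structure: blocks of mildly correlated components
# plus two independent ones
CORR_MIX1 = np.array(
    [
        [1.0, 0.3, 0.2, 0.1, 0.0, 0.0],
        [0.3, 1.0, 0.2, 0.1, 0.0, 0.0],
        [0.2, 0.2, 1.0, 0.1, 0.0, 0.0],
        [0.1, 0.1, 0.1, 1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ]
)
CORR_MIX2 = np.array(
    [
        [1.0, 0.2, 0.1, 0.1, 0.0, 0.0],
        [0.2, 1.0, 0.2, 0.1, 0.0, 0.0],
        [0.1, 0.2, 1.0, 0.1, 0.0, 0.0],
        [0.1, 0.1, 0.1, 1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ]
)

DEFAULT_PERTURB_SD = 0.1


@dataclass(frozen=True)
class SurfaceSpec:
    """True mean surface of one mixture-effect field on the unit square.

    Patterns: ``constant`` (one global mean); ``one_dim`` (means by vertical
    thirds at x = 1/3 and 2/3); ``radial`` (linear decay from the centre
    value at (0.5, 0.5) to the boundary value at radius 0.5, clamped
    beyond). Location-wise effects add N(0, sd^2) perturbation.
    """

    pattern: str = "constant"
    constant_mean: float = 0.0
    thirds_means: tuple[float, float, float] = (3.0, 1.5, 0.0)
    radial_center: float = 3.0
    radial_boundary: float = 0.0
    radial_radius: float = 0.5
    sd: float = DEFAULT_PERTURB_SD

    def __post_init__(self):
        if self.pattern not in {"constant", "one_dim", "radial"}:
            raise ValueError(f"unknown surface pattern {self.pattern!r}")
        if self.sd < 0:
            raise ValueError("perturbation sd must be nonnegative")


def true_mean_surface(spec: SurfaceSpec, locations) -> np.ndarray:
    """True mean effect value(s) at one or many unit-square locations."""
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    if spec.pattern == "constant":
        out = np.full(locs.shape[0], spec.constant_mean)
    elif spec.pattern == "one_dim":
        x = locs[:, 0]
        left, middle, right = spec.thirds_means
        out = np.where(x < 1.0 / 3.0, left, np.where(x < 2.0 / 3.0, middle, right))
    else:  # radial
        r = np.hypot(locs[:, 0] - 0.5, locs[:, 1] - 0.5)
        frac = np.clip(1.0 - r / spec.radial_radius, 0.0, 1.0)
        out = spec.radial_boundary + (spec.radial_center - spec.radial_boundary) * frac
    return out if np.asarray(locations).ndim == 2 else float(out[0])


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation scenario: per-mixture surface, weights, correlation."""

    name: str
    surfaces: dict[str, SurfaceSpec]
    weights: dict[str, np.ndarray]
    correlations: dict[str, np.ndarray]
    n: int = 1000
    n_datasets: int = 50
    quantiles: int = 4
    seed: int = 0

    def __post_init__(self):
        for m, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights for {m!r} must lie on the simplex")
            object.__getattribute__(self, "weights")[m] = w
        for m, c in self.correlations.items():
            c = np.asarray(c, dtype=float)
            if not np.allclose(c, c.T):
                raise ValueError(f"correlation matrix for {m!r} not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"correlation matrix for {m!r} not positive definite")

    @property
    def mixture_names(self) -> list[str]:
        return list(self.surfaces)


SCENARIO_NAMES = ["constant-null", "one_dim", "radial", "two_mix_one_dim", "two_mix_radial"]

_SURFACES = {
    "constant-null": {"mix1": SurfaceSpec("constant", constant_mean=0.0)},
    "one_dim": {"mix1": SurfaceSpec("one_dim")},
    "radial": {"mix1": SurfaceSpec("radial")},
    "two_mix_one_dim": {
        "mix1": SurfaceSpec("one_dim"),
        "mix2": SurfaceSpec("constant", constant_mean=1.0),
    },
    "two_mix_radial": {
        "mix1": SurfaceSpec("radial"),
        "mix2": SurfaceSpec("constant", constant_mean=1.0),
    },
}


def scenario_spec(name: str, n: int = 1000, n_datasets: int = 50, seed: int = 0) -> ScenarioSpec:
    """Built-in scenario preset by name (see :data:`SCENARIO_NAMES`)."""
    if name not in _SURFACES:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    surfaces = _SURFACES[name]
    weights = {"mix1": OMEGA_MIX1.copy()}
    correlations = {"mix1": CORR_MIX1.copy()}
    if "mix2" in surfaces:
        weights["mix2"] = OMEGA_MIX2.copy()
        correlations["mix2"] = CORR_MIX2.copy()
    return ScenarioSpec(
        name=name,
        surfaces=dict(surfaces),
        weights=weights,
        correlations=correlations,
        n=n,
        n_datasets=n_datasets,
        seed=seed,
    )


def sample_locations(n: int, seed) -> np.ndarray:
    """n iid uniform locations on the open unit square."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, 2))


def sample_components(n: int, correlation, seed) -> np.ndarray:
    """MVN component concentrations: zero mean, unit variance, given correlation."""
    corr = np.asarray(correlation, dtype=float)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("correlation matrix must be positive definite")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n, corr.shape[0])) @ chol.T


def sample_effects(spec: SurfaceSpec, locations, seed) -> np.ndarray:
    """Per-location true effect: the mean surface plus N(0, sd^2) perturbation."""
    rng = np.random.default_rng(seed)
    mean = true_mean_surface(spec, locations)
    return mean + spec.sd * rng.standard_normal(np.shape(mean))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def calibrate_intercept(linear_term, lo: float = -20.0, hi: float = 20.0, tol: float = 1e-8) -> float:
    """Intercept b0 with mean sigmoid(b0 + linear_term) = 1/2, by bisection.

    Yields the approximately 1:1 case:control ratio of the study design.
    """
    linear_term = np.asarray(linear_term, dtype=float)

    def f(b0):
        return float(np.mean(_sigmoid(b0 + linear_term)) - 0.5)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError("bisection bracket [-20, 20] does not straddle a 1:1 ratio")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_outcomes(linear_term, b0: float, seed) -> np.ndarray:
    """Bernoulli outcomes at probability sigmoid(b0 + linear_term)."""
    rng = np.random.default_rng(seed)
    p = _sigmoid(b0 + np.asarray(linear_term, dtype=float))
    return (rng.uniform(size=p.shape) < p).astype(int)


@dataclass
class SimulatedDataset:
    """A generated dataset together with its ground truth."""

    dataset: Dataset
    true_effects: dict[str, np.ndarray]
    true_means: dict[str, np.ndarray]
    true_weights: dict[str, np.ndarray]
    intercept: float
    scenario: str
    seed: int

    def truth_dataframe(self):
        import pandas as pd

        cols = {
            "id": self.dataset.ids,
            "x": self.dataset.locations[:, 0],
            "y": self.dataset.locations[:, 1],
        }
        for m in self.true_effects:
            cols[f"true_beta_{m}"] = self.true_effects[m]
            cols[f"true_mean_{m}"] = self.true_means[m]
        return pd.DataFrame(cols)


def generate_dataset(spec: ScenarioSpec, seed: int) -> SimulatedDataset:
    """One simulated dataset for a scenario, reproducible from integer ``seed``."""
    ss = np.random.SeedSequence(int(seed))
    mixes = spec.mixture_names
    child = ss.spawn(2 + 2 * len(mixes) + 1)
    locations = sample_locations(spec.n, child[0])

    components, effects, means = {}, {}, {}
    for i, m in enumerate(mixes):
        components[m] = sample_components(spec.n, spec.correlations[m], child[1 + i])
        effects[m] = sample_effects(spec.surfaces[m], locations, child[1 + len(mixes) + i])
        means[m] = true_mean_surface(spec.surfaces[m], locations)

    quantized = quantize_components(components, spec.quantiles)
    linear = np.zeros(spec.n)
    for m in mixes:
        linear += effects[m] * (quantized[m].astype(float) @ spec.weights[m])
    b0 = calibrate_intercept(linear)
    outcome = simulate_outcomes(linear, b0, child[-1])

    dataset = Dataset(
        locations=locations,
        outcome=outcome,
        components=components,
        component_names={m: tuple(f"{m}_c{k+1}" for k in range(components[m].shape[1])) for m in mixes},
    )
    return SimulatedDataset(
        dataset=dataset,
        true_effects=effects,
        true_means=means,
        true_weights={m: spec.weights[m].copy() for m in mixes},
        intercept=b0,
        scenario=spec.name,
        seed=int(seed),
    )


def dataset_seeds(spec: ScenarioSpec) -> np.ndarray:
    """The D integer per-dataset seeds derived from the scenario seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return rng.integers(2**31, size=spec.n_datasets)


def generate_scenario(spec: ScenarioSpec) -> list[SimulatedDataset]:
    """All D datasets of a scenario, with distinct per-dataset derived seeds."""
    return [generate_dataset(spec, int(s)) for s in dataset_seeds(spec)]
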