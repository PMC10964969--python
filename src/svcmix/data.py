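"""Case-control dataset container, mixture design, and quantile scoring.

A :class:`Dataset` holds, for n subjects: planar coordinates, a binary
outcome, one raw concentration matrix per exposure mixture, and an optional
adjustment-covariate matrix. Components are scored into quantiles
(``q = 0..Q-1``, quartiles by default) before entering the group index,
which tames collinearity between correlated exposures and puts components
on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MixtureDesign",
    "Dataset",
    "QuantizedComponents",
    "quantize_column",
    "quantize_components",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class MixtureDesign:
    """Mixture structure: component column names per mixture and quantile count.

    ``mixtures`` maps a mixture name to its ordered component column names;
    ``quantiles`` is the number of scoring bins Q (4 for quartiles).
    """

    mixtures: dict[str, tuple[str, ...]]
    quantiles: int = 4

    def __post_init__(self):
        if len(self.mixtures) < 1:
            raise ValueError("need at least one mixture")
        object.__setattr__(
            self,
            "mixtures",
            {str(k): tuple(v) for k, v in self.mixtures.items()},
        )
        for name, cols in self.mixtures.items():
            if len(cols) < 1:
                raise ValueError(f"mixture {name!r} has no components")
        if self.quantiles < 2:
            raise ValueError("quantile count Q must be >= 2")

    @property
    def names(self) -> list[str]:
        return list(self.mixtures)

    @property
    def n_mixtures(self) -> int:
        return len(self.mixtures)

    def n_components(self, name: str) -> int:
        return len(self.mixtures[name])


def _as_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class Dataset:
    """Subjects with coordinates, binary outcome, raw mixtures, covariates.

    Missing values are rejected outright: the model is a complete-case
    analysis and silent imputation would change its meaning.
    """

    locations: np.ndarray
    outcome: np.ndarray
    components: dict[str, np.ndarray]
    covariates: np.ndarray | None = None
    ids: np.ndarray | None = None
    component_names: dict[str, tuple[str, ...]] | None = None
    covariate_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.locations = _as_matrix(self.locations, "locations")
        if self.locations.shape[1] != 2:
            raise ValueError("locations must have two columns (x, y)")
        n = self.locations.shape[0]
        self.outcome = np.asarray(self.outcome)
        if self.outcome.shape != (n,):
            raise ValueError("outcome length does not match locations")
        vals = np.unique(self.outcome)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"outcome must be binary 0/1, saw values {vals}")
        self.outcome = self.outcome.astype(int)
        self.components = {k: _as_matrix(v, f"components[{k}]") for k, v in self.components.items()}
        for name, mat in self.components.items():
            if mat.shape[0] != n:
                raise ValueError(f"component block {name!r} row count mismatch")
            if np.isnan(mat).any():
                raise ValueError(f"missing values in component block {name!r}; complete cases only")
        if self.covariates is not None:
            self.covariates = _as_matrix(self.covariates, "covariates")
            if self.covariates.shape[0] != n:
                raise ValueError("covariate row count mismatch")
            if np.isnan(self.covariates).any():
                raise ValueError("missing values in covariates; complete cases only")
        if not np.all(np.isfinite(self.locations)):
            raise ValueError("locations must be finite")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape != (n,):
                raise ValueError("ids length mismatch")
        if self.component_names is None:
            self.component_names = {
                name: tuple(f"{name}_c{k+1}" for k in range(mat.shape[1]))
                for name, mat in self.components.items()
            }
        if self.covariate_names is None and self.covariates is not None:
            self.covariate_names = tuple(f"x{b+1}" for b in range(self.covariates.shape[1]))

    @property
    def n(self) -> int:
        return self.locations.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def design(self, quantiles: int = 4) -> MixtureDesign:
        return MixtureDesign(dict(self.component_names), quantiles)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "id": self.ids,
            "x": self.locations[:, 0],
            "y": self.locations[:, 1],
            "outcome": self.outcome,
        }
        for name, mat in self.components.items():
            for k, col in enumerate(self.component_names[name]):
                cols[col] = mat[:, k]
        if self.covariates is not None:
            for b, col in enumerate(self.covariate_names):
                cols[col] = self.covariates[:, b]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mixtures: dict[str, list[str]],
        outcome: str = "outcome",
        coords: tuple[str, str] = ("x", "y"),
        covariates: list[str] | None = None,
        id_col: str = "id",
    ) -> "Dataset":
        missing = [
            c
            for c in ([outcome, *coords, *(covariates or [])] + [c for v in mixtures.values() for c in v])
            if c not in df.columns
        ]
        if missing:
            raise KeyError(f"columns not found in dataframe: {missing}")
        return cls(
            locations=df[list(coords)].to_numpy(float),
            outcome=df[outcome].to_numpy(),
            components={m: df[list(cols)].to_numpy(float) for m, cols in mixtures.items()},
            covariates=df[list(covariates)].to_numpy(float) if covariates else None,
            ids=df[id_col].to_numpy() if id_col in df.columns else None,
            component_names={m: tuple(cols) for m, cols in mixtures.items()},
            covariate_names=tuple(covariates) if covariates else None,
        )


def read_dataset_csv(
    path,
    mixtures: dict[str, list[str]],
    covariates: list[str] | None = None,
    **kwargs,
) -> Dataset:
    """Read the dataset CSV schema: ``id, x, y, outcome``, components, covariates."""
    df = pd.read_csv(Path(path))
    return Dataset.from_dataframe(df, mixtures, covariates=covariates, **kwargs)


def quantize_column(col: np.ndarray, quantiles: int, name: str = "column") -> np.ndarray:
    """Score one column into ``0..Q-1`` by right-closed sample-quantile bins.

    Breaks are the Q-1 interior sample quantiles; a value equal to a break
    falls in the lower (right-closed) interval, so ties share a score.
    """
    col = np.asarray(col, dtype=float)
    if col.ndim != 1:
        raise ValueError("quantize_column expects a 1-D column")
    if col.size < quantiles:
        raise ValueError(f"need at least Q={quantiles} observations to form quantiles")
    if np.nanmax(col) == np.nanmin(col):
        raise ValueError(f"constant column {name!r} cannot be scored into quantiles")
    breaks = np.quantile(col, np.arange(1, quantiles) / quantiles)
    return (col[:, None] > breaks[None, :]).sum(axis=1).astype(np.int64)


@dataclass
class QuantizedComponents:
    """Quantile scores per mixture: integer (n, C_j) matrices with values in 0..Q-1."""

    scores: dict[str, np.ndarray]
    quantiles: int

    def __post_init__(self):
        for name, mat in self.scores.items():
            mat = np.asarray(mat)
            if not np.issubdtype(mat.dtype, np.integer):
                raise ValueError(f"scores for {name!r} must be integers")
            if mat.min() < 0 or mat.max() > self.quantiles - 1:
                raise ValueError(f"scores for {name!r} outside 0..{self.quantiles - 1}")
            self.scores[name] = mat

    def __getitem__(self, name: str) -> np.ndarray:
        return self.scores[name]

    @property
    def names(self) -> list[str]:
        return list(self.scores)


def quantize_components(
    components: dict[str, np.ndarray] | np.ndarray, quantiles: int = 4
) -> QuantizedComponents:
    """Quantile-score every component column of every mixture block."""
    if not isinstance(components, dict):
        components = {"mix1": components}
    scores = {}
    for name, mat in components.items():
        mat = _as_matrix(mat, f"components[{name}]")
        scores[name] = np.column_stack(
            [
                quantize_column(mat[:, k], quantiles, name=f"{name}[{k}]")
                for k in range(mat.shape[1])
            ]
        )
    return QuantizedComponents(scores, quantiles)
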