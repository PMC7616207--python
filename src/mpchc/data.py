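"""Dataset containers, two-state k-means discretization, KDE augmentation
and train/test splitting.

Continuous cohort tables are carried as pandas DataFrames wrapped in
:class:`ContinuousDataset`; discrete tables store integer state codes plus
per-variable state labels in :class:`DiscreteDataset`.  Discretization maps
each continuous variable to ``Low``/``High`` by a single cutoff (the
midpoint of the two 1-D k-means centroids), and kernel density estimation
with a likelihood-cross-validated bandwidth supplies the augmentation
distribution from which bootstrap samples are drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.model_selection import KFold

__all__ = [
    "ContinuousDataset",
    "DiscreteDataset",
    "DiscretizationMap",
    "KDEModel",
    "discretize_kmeans",
    "fit_kde",
    "sample_kde",
    "split_train_test",
]

STATE_LOW = "Low"
STATE_HIGH = "High"


@dataclass
class ContinuousDataset:
    """Named real-valued variables observed row-wise; no missing values."""

    variables: tuple[str, ...]
    values: np.ndarray  # shape (n, p), float

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise ValueError("values must be (n_rows, n_variables)")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, var: str) -> np.ndarray:
        return self.values[:, self.variables.index(var)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.variables))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContinuousDataset":
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ContinuousDataset":
        return cls.from_frame(pd.read_csv(path))

    def take(self, idx: np.ndarray) -> "ContinuousDataset":
        return ContinuousDataset(self.variables, self.values[idx])


@dataclass
class DiscreteDataset:
    """Named variables with finite state sets; rows are state indices.

    ``state_names[i]`` lists the labels of variable ``variables[i]`` in
    declared order; ``codes`` holds the corresponding integer indices.
    """

    variables: tuple[str, ...]
    state_names: tuple[tuple[str, ...], ...]
    codes: np.ndarray  # shape (M, p), int

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.state_names = tuple(tuple(s) for s in self.state_names)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if len(self.state_names) != len(self.variables):
            raise ValueError("one state list per variable required")
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.variables):
            raise ValueError("codes must be (M, n_variables)")
        for j, states in enumerate(self.state_names):
            if self.codes.shape[0] and self.codes[:, j].max(initial=0) >= len(states):
                raise ValueError(f"code out of range for variable {self.variables[j]!r}")

    @property
    def M(self) -> int:
        """Sample count."""
        return self.codes.shape[0]

    def cardinality(self, var: str) -> int:
        return len(self.state_names[self.variables.index(var)])

    def states_of(self, var: str) -> tuple[str, ...]:
        return self.state_names[self.variables.index(var)]

    def column(self, var: str) -> np.ndarray:
        return self.codes[:, self.variables.index(var)]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, var in enumerate(self.variables):
            labels = np.asarray(self.state_names[j], dtype=object)
            cols[var] = labels[self.codes[:, j]]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        state_names: dict[str, tuple[str, ...]] | None = None,
    ) -> "DiscreteDataset":
        variables = tuple(df.columns)
        states: list[tuple[str, ...]] = []
        codes = np.empty((len(df), len(variables)), dtype=np.int64)
        for j, var in enumerate(variables):
            col = df[var].astype(str)
            labels = (
                tuple(state_names[var])
                if state_names is not None
                else tuple(sorted(col.unique()))
            )
            lut = {s: i for i, s in enumerate(labels)}
            try:
                codes[:, j] = col.map(lut).to_numpy(dtype=np.int64)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unknown state label in column {var!r}") from exc
            states.append(labels)
        return cls(variables, tuple(states), codes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, state_names=None) -> "DiscreteDataset":
        return cls.from_frame(pd.read_csv(path, dtype=str), state_names)

    def take(self, idx: np.ndarray) -> "DiscreteDataset":
        return DiscreteDataset(self.variables, self.state_names, self.codes[idx])


@dataclass
class DiscretizationMap:
    """Per-variable single cutoff: value < cutoff -> Low, value >= cutoff -> High."""

    cutoffs: dict[str, float]
    states: tuple[str, str] = (STATE_LOW, STATE_HIGH)

    def apply(self, data: ContinuousDataset) -> DiscreteDataset:
        codes = np.empty_like(data.values, dtype=np.int64)
        for j, var in enumerate(data.variables):
            if var not in self.cutoffs:
                raise ValueError(f"no cutoff fitted for variable {var!r}")
            codes[:, j] = (data.values[:, j] >= self.cutoffs[var]).astype(np.int64)
        states = tuple(self.states for _ in data.variables)
        return DiscreteDataset(data.variables, states, codes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"states": list(self.states), "cutoffs": self.cutoffs}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiscretizationMap":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(cutoffs={k: float(v) for k, v in obj["cutoffs"].items()},
                   states=tuple(obj["states"]))


def _kmeans_1d_two(x: np.ndarray) -> tuple[float, float]:
    """Deterministic 1-D two-means: centroids initialised at the observed
    extremes, Lloyd iteration to convergence.  Returns sorted centroids."""
    c_lo, c_hi = float(x.min()), float(x.max())
    for _ in range(1000):
        mid = 0.5 * (c_lo + c_hi)
        lo = x[x < mid]
        hi = x[x >= mid]
        if lo.size == 0 or hi.size == 0:  # all mass on one side of the midpoint
            break
        new_lo, new_hi = float(lo.mean()), float(hi.mean())
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    return c_lo, c_hi


def discretize_kmeans(
    data: ContinuousDataset, k: int = 2
) -> tuple[DiscreteDataset, DiscretizationMap]:
    """Two-state discretization of every column by 1-D k-means.

    The cutoff is the midpoint of the two cluster centroids; values below
    it are labelled ``Low``, values at or above it ``High``.  The returned
    map can be re-applied to held-out data so train and test share label
    semantics.
    """
    if k != 2:
        raise ValueError("only k=2 (two-state) discretization is supported")
    cutoffs: dict[str, float] = {}
    for var in data.variables:
        x = data.column(var)
        if np.unique(x).size < 2:
            raise ValueError(f"column {var!r} is constant; cannot discretize")
        c_lo, c_hi = _kmeans_1d_two(x)
        cutoffs[var] = 0.5 * (c_lo + c_hi)
    dmap = DiscretizationMap(cutoffs)
    return dmap.apply(data), dmap


@dataclass
class KDEModel:
    """Product-Gaussian kernel density on standardised coordinates.

    The density is a uniform mixture over training rows, each smoothed by
    an isotropic Gaussian of scale ``bandwidth`` in standardised units
    (``bandwidth * scale[j]`` in original units of coordinate ``j``).
    """

    variables: tuple[str, ...]
    training: np.ndarray  # standardised, shape (n, p)
    bandwidth: float
    mean: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)

    def log_density(self, x_std: np.ndarray) -> np.ndarray:
        """Log density of standardised points, up to the Jacobian of the
        standardisation (constant, so irrelevant to bandwidth selection)."""
        n, p = self.training.shape
        d2 = ((x_std[:, None, :] - self.training[None, :, :]) ** 2).sum(axis=2)
        log_kernel = -0.5 * d2 / self.bandwidth**2 - p * np.log(
            self.bandwidth * np.sqrt(2 * np.pi)
        )
        return logsumexp(log_kernel, axis=1) - np.log(n)


def _silverman_bandwidth(n: int, p: int) -> float:
    """Rule-of-thumb scale for unit-variance data in p dimensions."""
    return float((4.0 / ((p + 2.0) * n)) ** (1.0 / (p + 4.0)))


def default_bandwidth_grid(n: int, p: int, size: int = 20) -> np.ndarray:
    """Log-spaced grid spanning 0.1x to 10x the rule-of-thumb bandwidth."""
    h0 = _silverman_bandwidth(n, p)
    return np.geomspace(0.1 * h0, 10.0 * h0, size)


def fit_kde(
    data: ContinuousDataset,
    bandwidth_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> KDEModel:
    """Gaussian-kernel density with bandwidth chosen by likelihood
    cross-validation.

    Columns are standardised and a single shared bandwidth is selected as
    the grid value maximising the mean held-out log-likelihood; ties break
    toward the smaller bandwidth.
    """
    x = data.values
    n, p = x.shape
    if n < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} rows, got {n}")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    bad = [data.variables[j] for j in range(p) if scale[j] == 0.0]
    if bad:
        raise ValueError(f"constant column(s) {bad}; KDE undefined")
    z = (x - mean) / scale
    if bandwidth_grid is None:
        bandwidth_grid = default_bandwidth_grid(n, p)
    grid = np.asarray(bandwidth_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty bandwidth grid")
    if (grid <= 0).any():
        raise ValueError("bandwidths must be positive")
    grid = np.sort(grid)
    if grid.size == 1:
        return KDEModel(data.variables, z, float(grid[0]), mean, scale)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_h, best_ll = None, -np.inf
    for h in grid:
        total = 0.0
        for train_idx, test_idx in kf.split(z):
            model = KDEModel(data.variables, z[train_idx], float(h))
            total += float(model.log_density(z[test_idx]).sum())
        mean_ll = total / n
        if mean_ll > best_ll:  # strict: ties keep the smaller bandwidth
            best_ll, best_h = mean_ll, float(h)
    if not np.isfinite(best_ll):
        raise ValueError("cross-validated likelihood degenerate for all bandwidths")
    return KDEModel(data.variables, z, best_h, mean, scale)


def sample_kde(model: KDEModel, n: int, seed: int) -> ContinuousDataset:
    """Draw ``n`` rows: pick a training row uniformly, add Gaussian noise of
    scale ``bandwidth`` per (standardised) coordinate, map back to the
    original units.  Deterministic given ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ntrain, p = model.training.shape
    idx = rng.integers(0, ntrain, size=n)
    z = model.training[idx] + rng.normal(scale=model.bandwidth, size=(n, p))
    values = z * model.scale + model.mean
    return ContinuousDataset(model.variables, values)


def split_train_test(data, fraction: float = 0.8, seed: int = 0):
    """Disjoint row partition of sizes ``floor(fraction*n)`` and the rest,
    after a seeded shuffle.  Works for both dataset types."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = data.values.shape[0] if isinstance(data, ContinuousDataset) else data.M
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    return data.take(perm[:n_train]), data.take(perm[n_train:])
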