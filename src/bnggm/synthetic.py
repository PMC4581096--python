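"""Synthetic benchmark data: linear-Gaussian sampling from a DAG and
rank-based quantile normalization.

The generator draws each node, in topological order, from a Normal whose
mean is the weighted sum of its parents' values::

    X_i ~ N( sum_k w_ik x_k , sigma^2 )

with every present edge carrying the same weight ``w`` (default 1) and
dynamic-noise variance ``sigma^2`` (default 0.01).  Root nodes have an empty
parent sum and are therefore drawn from ``N(0, sigma^2)``.  This is exactly
a draw from the multivariate Gaussian implied by the DAG, the model family
the BGe score assumes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import DAG

__all__ = [
    "Dataset",
    "GaussianSimConfig",
    "simulate_gaussian",
    "quantile_normalize",
    "read_dataset",
    "write_dataset",
]


@dataclass
class Dataset:
    """An n-observations x N-variables numeric data matrix with column labels."""

    values: np.ndarray
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix (observations x variables)")
        if not np.isfinite(vals).all():
            raise ValueError("dataset contains non-finite entries")
        self.values = vals
        if self.node_labels is None:
            self.node_labels = [f"X{i + 1}" for i in range(vals.shape[1])]
        elif len(self.node_labels) != vals.shape[1]:
            raise ValueError("node_labels length does not match number of columns")
        else:
            self.node_labels = list(self.node_labels)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.node_labels)


@dataclass
class GaussianSimConfig:
    """Parameters of the linear-Gaussian generator.

    ``edge_weight`` is the interaction strength applied to every present
    edge; ``noise_variance`` is the dynamic noise sigma^2 (low values give a
    near-deterministic system); ``n_samples`` is the number of observations
    per data set.
    """

    edge_weight: float = 1.0
    noise_variance: float = 0.01
    n_samples: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")


def simulate_gaussian(
    dag: DAG,
    config: GaussianSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Draw a data set from the linear-Gaussian model defined by ``dag``.

    Nodes are sampled in topological order; each value is the sum of the
    node's parent values times ``edge_weight`` plus ``N(0, sigma^2)`` noise.
    Deterministic for a fixed ``config.seed`` (or an explicitly passed
    generator, which takes precedence).
    """
    config = config or GaussianSimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, N = config.n_samples, dag.n_nodes
    sigma = float(np.sqrt(config.noise_variance))
    values = np.empty((n, N))
    order = dag.topological_order()
    for node in order:
        parents = np.flatnonzero(dag.adjacency[:, node])
        mean = config.edge_weight * values[:, parents].sum(axis=1) if len(parents) else 0.0
        values[:, node] = mean + rng.normal(0.0, sigma, size=n)
    return Dataset(values, list(dag.node_labels))


def implied_covariance(dag: DAG, config: GaussianSimConfig | None = None) -> np.ndarray:
    """Closed-form covariance of the linear-Gaussian model.

    With weight matrix ``W[i, k] = w * adjacency[k, i]`` (row i collects the
    parents of node i) the stationary draw is ``x = (I - W)^-1 eps`` and the
    covariance is ``sigma^2 (I - W)^-1 (I - W)^-T``.
    """
    config = config or GaussianSimConfig()
    N = dag.n_nodes
    W = config.edge_weight * dag.adjacency.T.astype(float)
    A = np.linalg.inv(np.eye(N) - W)
    return config.noise_variance * A @ A.T


def quantile_normalize(dataset: Dataset) -> Dataset:
    """Replace each variable's values by standard-normal quantiles of rank.

    Per column independently, the value of rank ``r`` (smallest = 1, tied
    values receive the average of their ranks) is mapped to
    ``Phi^-1((r - 0.5) / n)``.  The transform preserves rank order, yields
    finite values at both extremes, and gives columns mean ~0, variance ~1.
    A constant column carries no rank information: every entry maps to the
    median quantile 0 and a warning is emitted.
    """
    vals = dataset.values
    n = vals.shape[0]
    if n < 2:
        raise ValueError("quantile normalization needs at least 2 observations")
    out = np.empty_like(vals, dtype=float)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.all(col == col[0]):
            warnings.warn(
                f"column '{dataset.node_labels[j]}' is constant; "
                "all values mapped to the median quantile 0",
                UserWarning,
                stacklevel=2,
            )
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.5) / n)
    return Dataset(out, list(dataset.node_labels))


def write_dataset(dataset: Dataset, path: str | Path, sep: str = "\t") -> None:
    dataset.to_dataframe().to_csv(path, sep=sep, index=False)


def read_dataset(path: str | Path) -> Dataset:
    df = pd.read_csv(path, sep=None, engine="python")
    return Dataset(df.to_numpy(dtype=float), [str(c) for c in df.columns])
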