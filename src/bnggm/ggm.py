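"""Graphical Gaussian model: shrinkage covariance, partial correlations and
the rescaled guidance matrix tau.

The pipeline is ``shrinkage_covariance -> partial_correlations ->
rescale_tau``.  Partial correlations measure direct pairwise association
conditional on all remaining variables; min-max rescaling of their absolute
values produces the matrix ``tau`` in [0, 1] that the guided sampler uses as
soft prior evidence for (tau > 0.5) or against (tau < 0.5) each edge.
Because a GGM is undirected, tau is symmetric: both edge directions receive
identical guidance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .synthetic import Dataset

__all__ = [
    "CovarianceEstimate",
    "shrinkage_covariance",
    "partial_correlations",
    "rescale_tau",
    "compute_tau",
]


@dataclass
class CovarianceEstimate:
    """A symmetric covariance matrix plus the shrinkage intensity used."""

    matrix: np.ndarray
    shrinkage_intensity: float


def _as_matrix(data: Dataset | np.ndarray) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.values
    return np.asarray(data, dtype=float)


def shrinkage_covariance(dataset: Dataset | np.ndarray) -> CovarianceEstimate:
    """Schafer-Strimmer shrinkage covariance (diagonal, unit-correlation target).

    Empirical correlations are shrunk linearly toward zero off-diagonal with
    the analytically optimal intensity from the Ledoit-Wolf lemma,

        lambda* = sum_{i != k} Var(r_ik) / sum_{i != k} r_ik^2,

    clamped to [0, 1], then recombined with the (untouched) empirical
    variances.  Any positive intensity guarantees an invertible estimate
    even when variables outnumber observations.
    """
    X = _as_matrix(dataset)
    n, N = X.shape
    if n < 3:
        raise ValueError("shrinkage covariance needs at least 3 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        labels = (
            dataset.node_labels
            if isinstance(dataset, Dataset)
            else [f"X{i + 1}" for i in range(N)]
        )
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance variable(s): {', '.join(bad)}")
    Xs = (X - X.mean(axis=0)) / sd
    # unbiased correlations r_ik = sum_j w_jik / (n - 1), w_jik = xs_ji * xs_jk
    R = Xs.T @ Xs / (n - 1)
    # Var(r_ik) estimated from the scatter of the products w_jik
    W_mean = R * (n - 1) / n
    var_w = (Xs**2).T @ (Xs**2) / n - W_mean**2
    var_r = n / (n - 1) ** 3 * n * var_w
    off = ~np.eye(N, dtype=bool)
    denom = float((R[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_shrunk = (1.0 - lam) * R
    np.fill_diagonal(R_shrunk, 1.0)
    C = R_shrunk * np.outer(sd, sd)
    C = (C + C.T) / 2.0
    return CovarianceEstimate(C, lam)


def partial_correlations(cov: CovarianceEstimate | np.ndarray) -> np.ndarray:
    """Partial correlation matrix from a covariance matrix.

    ``rho_ik = -P_ik / sqrt(P_ii P_kk)`` with ``P = C^-1``; the diagonal is
    set to 1 by convention.  Raises if the covariance is singular (apply
    shrinkage first).
    """
    C = cov.matrix if isinstance(cov, CovarianceEstimate) else np.asarray(cov, dtype=float)
    try:
        cho = linalg.cho_factor(C)
        P = linalg.cho_solve(cho, np.eye(C.shape[0]))
    except linalg.LinAlgError as err:
        raise ValueError(
            "covariance matrix is singular or not positive definite; "
            "use shrinkage_covariance to regularize it"
        ) from err
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def rescale_tau(rho: np.ndarray) -> np.ndarray:
    """Min-max rescale |rho| over off-diagonal entries into tau in [0, 1].

    ``tau_ik = (|rho_ik| - min|rho|) / (max|rho| - min|rho|)`` with the
    minimum and maximum taken over off-diagonal entries only; the diagonal
    is fixed at 0 and excluded from all downstream energy sums (the
    diagonal of rho is an artifact and self-edges are forbidden anyway).
    """
    rho = np.asarray(rho, dtype=float)
    N = rho.shape[0]
    a = np.abs(rho)
    off = ~np.eye(N, dtype=bool)
    lo, hi = a[off].min(), a[off].max()
    if hi - lo < 1e-12:
        raise ValueError(
            "all off-diagonal |rho| are equal; the rescaling is undefined. "
            "Use a constant uninformative matrix tau = 0.5 instead."
        )
    tau = (a - lo) / (hi - lo)
    np.fill_diagonal(tau, 0.0)
    return tau


def compute_tau(dataset: Dataset | np.ndarray) -> np.ndarray:
    """Convenience pipeline: data -> shrinkage covariance -> rho -> tau."""
    return rescale_tau(partial_correlations(shrinkage_covariance(dataset)))
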