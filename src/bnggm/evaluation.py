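"""Evaluation of sampled traces: edge posteriors, ROC/AUC accuracy against a
gold-standard network, and the two-chain convergence diagnostic c_rms.

Edges are classified per ordered off-diagonal pair by thresholding the
posterior matrix ``R`` at ``epsilon`` against the true network ``T``
(TP/FP/TN/FN); sweeping the threshold yields the ROC curve and its area.
Convergence of two independently initialized chains is quantified by the
root-mean-square perpendicular spread of paired edge posteriors around the
line y = x.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .sampler import ChainTrace

__all__ = [
    "EdgeCounts",
    "edge_posterior",
    "classify_edges",
    "roc_auc",
    "auc_trajectory",
    "c_rms",
    "crms_trajectory",
    "ConvergenceReport",
    "convergence_report",
]


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _check_square_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrices must be square and of equal shape, got {a.shape} and {b.shape}")


def edge_posterior(trace: ChainTrace, burn_in_fraction: float | None = None) -> np.ndarray:
    """Marginal posterior edge probabilities: mean post-burn-in adjacency.

    ``burn_in_fraction`` defaults to the fraction stored in the trace's
    configuration (0.5): the first half of the recorded samples is dropped
    and the remainder averaged element-wise.
    """
    if burn_in_fraction is None:
        burn_in_fraction = (
            trace.config.burn_in_fraction if trace.config is not None else 0.5
        )
    start = int(len(trace) * burn_in_fraction)
    if start >= len(trace):
        raise ValueError("no samples remain after burn-in")
    return trace.adjacencies[start:].mean(axis=0)


class EdgeCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


def classify_edges(posterior: np.ndarray, truth: np.ndarray, epsilon: float) -> EdgeCounts:
    """Confusion counts of thresholded edges against the true network.

    An ordered off-diagonal pair is predicted present when its posterior is
    at least ``epsilon``; counts always total N(N-1).
    """
    posterior = np.asarray(posterior, dtype=float)
    truth = np.asarray(truth)
    _check_square_pair(posterior, truth)
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    off = _offdiag_mask(truth.shape[0])
    t = truth[off].astype(bool)
    a = posterior[off] >= epsilon
    return EdgeCounts(
        tp=int((t & a).sum()),
        fp=int((~t & a).sum()),
        tn=int((~t & ~a).sum()),
        fn=int((t & ~a).sum()),
    )


def roc_auc(posterior: np.ndarray, truth: np.ndarray, undirected: bool = False) -> float:
    """Area under the ROC curve of the edge posteriors against the truth.

    Off-diagonal ordered pairs are the classification instances.  With
    ``undirected=True`` the gold standard is symmetrized first, treating an
    undirected edge as the superposition of both directed edges.  Tied
    scores are grouped into single threshold steps (exact trapezoid).
    """
    posterior = np.asarray(posterior, dtype=float)
    truth = np.asarray(truth)
    _check_square_pair(posterior, truth)
    if undirected:
        truth = np.maximum(truth, truth.T)
    off = _offdiag_mask(truth.shape[0])
    y = truth[off].astype(int)
    if y.min() == y.max():
        raise ValueError("degenerate truth: needs at least one present and one absent edge")
    return float(roc_auc_score(y, posterior[off]))


def auc_trajectory(
    trace: ChainTrace, truth: np.ndarray, undirected: bool = False
) -> pd.DataFrame:
    """AUC as a function of simulation length.

    For every thinned step the posterior is computed as if the run had ended
    there: the first half of the samples available up to that step is
    discarded as burn-in and the rest averaged.  The final row therefore
    equals ``roc_auc(edge_posterior(trace), truth)``.
    """
    truth = np.asarray(truth)
    if undirected:
        truth = np.maximum(truth, truth.T)
    S = len(trace)
    if S == 0:
        raise ValueError("empty trace")
    off = _offdiag_mask(trace.n_nodes)
    y = truth[off].astype(int)
    if y.min() == y.max():
        raise ValueError("degenerate truth: needs at least one present and one absent edge")
    frac = trace.config.burn_in_fraction if trace.config is not None else 0.5
    flat = trace.adjacencies.reshape(S, -1)[:, off.ravel()].astype(float)
    csum = np.cumsum(flat, axis=0)
    aucs = np.empty(S)
    for s in range(1, S + 1):
        start = int(s * frac)  # number of leading samples discarded
        if start >= s:
            start = s - 1
        total = csum[s - 1] - (csum[start - 1] if start > 0 else 0.0)
        scores = total / (s - start)
        aucs[s - 1] = roc_auc_score(y, scores)
    return pd.DataFrame({"step": trace.steps, "auc": aucs})


def c_rms(posterior_a: np.ndarray, posterior_b: np.ndarray) -> float:
    """Two-chain convergence diagnostic.

    Root-mean-square perpendicular distance of the paired edge posteriors
    ``(r_a, r_b)`` from the line y = x, over ordered off-diagonal pairs:

        c_rms = sqrt( mean( (r_a - r_b)^2 / 2 ) ).

    Zero iff the two posteriors agree exactly; bounded above by 1/sqrt(2);
    symmetric in its arguments.
    """
    a = np.asarray(posterior_a, dtype=float)
    b = np.asarray(posterior_b, dtype=float)
    _check_square_pair(a, b)
    off = _offdiag_mask(a.shape[0])
    return float(np.sqrt(np.mean((a[off] - b[off]) ** 2 / 2.0)))


def crms_trajectory(trace_a: ChainTrace, trace_b: ChainTrace) -> pd.DataFrame:
    """c_rms between two chains as a function of simulation length.

    Prefix-wise, with the same leading-half burn-in rule as
    :func:`auc_trajectory` applied to both chains.
    """
    if len(trace_a) != len(trace_b) or trace_a.n_nodes != trace_b.n_nodes:
        raise ValueError("traces have mismatched shapes")
    S = len(trace_a)
    off = _offdiag_mask(trace_a.n_nodes)
    frac_a = trace_a.config.burn_in_fraction if trace_a.config is not None else 0.5
    flat_a = trace_a.adjacencies.reshape(S, -1)[:, off.ravel()].astype(float)
    flat_b = trace_b.adjacencies.reshape(S, -1)[:, off.ravel()].astype(float)
    ca, cb = np.cumsum(flat_a, axis=0), np.cumsum(flat_b, axis=0)
    vals = np.empty(S)
    for s in range(1, S + 1):
        start = min(int(s * frac_a), s - 1)
        pa = (ca[s - 1] - (ca[start - 1] if start > 0 else 0.0)) / (s - start)
        pb = (cb[s - 1] - (cb[start - 1] if start > 0 else 0.0)) / (s - start)
        vals[s - 1] = np.sqrt(np.mean((pa - pb) ** 2 / 2.0))
    return pd.DataFrame({"step": trace_a.steps, "c_rms": vals})


@dataclass
class ConvergenceReport:
    """Per-mode convergence and accuracy curves for paired chains.

    ``table`` has one row per thinned step and mode with columns
    (mode, step, auc_a, auc_b, c_rms); ``scatter`` maps each mode to the
    paired final edge posteriors of its two chains (flattened off-diagonal).
    """

    table: pd.DataFrame
    scatter: dict[str, tuple[np.ndarray, np.ndarray]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, directory) -> list[str]:
        """Write c_rms / AUC curves and posterior scatter plots as PNG files."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for mode, sub in self.table.groupby("mode"):
            axes[0].plot(sub["step"], sub["c_rms"], label=mode)
            axes[1].plot(sub["step"], (sub["auc_a"] + sub["auc_b"]) / 2, label=mode)
        axes[0].set(xlabel="MCMC step", ylabel="c_rms")
        axes[1].set(xlabel="MCMC step", ylabel="mean AUC")
        for ax in axes:
            ax.legend()
        out = directory / "convergence.png"
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(out))
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for mode, (pa, pb) in self.scatter.items():
            ax.scatter(pa, pb, s=12, alpha=0.6, label=mode)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.set(xlabel="edge posterior, chain A", ylabel="edge posterior, chain B")
        ax.legend()
        out = directory / "posterior_scatter.png"
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(out))
        return written


def convergence_report(
    trace_pairs: dict[str, tuple[ChainTrace, ChainTrace]],
    truth: np.ndarray,
) -> ConvergenceReport:
    """Build the paired-chain convergence report across sampler modes.

    For each mode the two chains must share the same schedule; the report
    contains prefix-wise AUC curves for both chains, the prefix-wise c_rms
    curve, and the final paired posteriors for scatter inspection.
    """
    rows = []
    scatter: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for mode, (ta, tb) in trace_pairs.items():
        if len(ta) != len(tb) or ta.n_nodes != tb.n_nodes:
            raise ValueError(f"mode {mode!r}: mismatched chain configurations")
        if ta.config is not None and tb.config is not None:
            if (ta.config.n_steps, ta.config.thin) != (tb.config.n_steps, tb.config.thin):
                raise ValueError(f"mode {mode!r}: mismatched chain configurations")
        auc_a = auc_trajectory(ta, truth)
        auc_b = auc_trajectory(tb, truth)
        cr = crms_trajectory(ta, tb)
        rows.append(
            pd.DataFrame(
                {
                    "mode": mode,
                    "step": auc_a["step"],
                    "auc_a": auc_a["auc"],
                    "auc_b": auc_b["auc"],
                    "c_rms": cr["c_rms"],
                }
            )
        )
        off = _offdiag_mask(ta.n_nodes)
        scatter[mode] = (edge_posterior(ta)[off], edge_posterior(tb)[off])
    return ConvergenceReport(pd.concat(rows, ignore_index=True), scatter)
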