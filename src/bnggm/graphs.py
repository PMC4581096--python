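"""Directed acyclic graphs: the structures sampled by the MCMC.

A network structure is held as a binary adjacency matrix where entry
``(i, k) == 1`` encodes a directed edge ``i -> k`` (node ``i`` is a parent
of node ``k``).  Self-loops are forbidden and the graph must admit a
topological order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DAG",
    "is_acyclic",
    "random_dag",
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "write_edge_list",
]


def is_acyclic(adjacency: np.ndarray) -> bool:
    """True if the 0/1 adjacency matrix describes a DAG (Kahn's algorithm)."""
    adj = np.asarray(adjacency) != 0
    n = adj.shape[0]
    indeg = adj.sum(axis=0).astype(int)
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    adj_lists = [np.flatnonzero(adj[i]) for i in range(n)]
    while stack:
        u = stack.pop()
        seen += 1
        for v in adj_lists[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == n


def _default_labels(n: int) -> list[str]:
    return [f"X{i + 1}" for i in range(n)]


@dataclass
class DAG:
    """A labelled directed acyclic graph.

    Parameters
    ----------
    adjacency
        Square binary matrix; ``adjacency[i, k] == 1`` means edge ``i -> k``.
    node_labels
        One identifier per node.  Defaults to ``X1 .. XN``.
    """

    adjacency: np.ndarray
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diag(adj).any():
            raise ValueError("self-loops are not allowed (non-zero diagonal)")
        if not is_acyclic(adj):
            raise ValueError("adjacency matrix contains a directed cycle")
        self.adjacency = adj.astype(np.int8)
        if self.node_labels is None:
            self.node_labels = _default_labels(adj.shape[0])
        elif len(self.node_labels) != adj.shape[0]:
            raise ValueError("node_labels length does not match adjacency size")
        else:
            self.node_labels = list(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Edge list as (parent_label, child_label) pairs."""
        ii, kk = np.nonzero(self.adjacency)
        return [(self.node_labels[i], self.node_labels[k]) for i, k in zip(ii, kk)]

    def parents(self, node: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.adjacency[:, node]))

    def topological_order(self) -> list[int]:
        return list(nx.topological_sort(self.to_networkx(labels=False)))

    def to_networkx(self, labels: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        names = self.node_labels if labels else list(range(self.n_nodes))
        g.add_nodes_from(names)
        ii, kk = np.nonzero(self.adjacency)
        g.add_edges_from((names[i], names[k]) for i, k in zip(ii, kk))
        return g

    def copy(self) -> "DAG":
        return DAG(self.adjacency.copy(), list(self.node_labels))


def random_dag(
    n_nodes: int,
    n_edges: int,
    seed: int | np.random.Generator | None = None,
) -> DAG:
    """Sample a random labelled DAG with exactly ``n_edges`` edges.

    A uniformly random topological order is drawn first; the requested number
    of edges is then chosen uniformly among the ``n(n-1)/2`` ordered pairs
    consistent with that order, which guarantees acyclicity by construction.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for {n_nodes} nodes "
            f"(must be between 0 and {max_edges})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(n_nodes)
    pairs = [(order[a], order[b]) for a in range(n_nodes) for b in range(a + 1, n_nodes)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for idx in chosen:
        i, k = pairs[int(idx)]
        adj[i, k] = 1
    return DAG(adj)


# ---------------------------------------------------------------------------
# Plain-text I/O: labelled delimited matrices and two-column edge lists.

def write_adjacency(dag: DAG, path: str | Path, sep: str = "\t") -> None:
    import pandas as pd

    pd.DataFrame(dag.adjacency, index=dag.node_labels, columns=dag.node_labels).to_csv(
        path, sep=sep, index_label=""
    )


def read_adjacency(path: str | Path) -> DAG:
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return DAG(df.to_numpy(dtype=np.int8), [str(c) for c in df.columns])


def write_edge_list(dag: DAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, dst in dag.edges():
            fh.write(f"{src}\t{dst}\n")


def read_edge_list(path: str | Path, node_labels: list[str] | None = None) -> DAG:
    """Read a tab-separated ``source<TAB>target`` edge list.

    Node labels default to the sorted set of labels appearing in the file;
    pass ``node_labels`` explicitly to include isolated nodes.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            src, dst = line.split("\t")[:2]
            edges.append((src, dst))
    if node_labels is None:
        node_labels = sorted({v for e in edges for v in e})
    index = {lab: i for i, lab in enumerate(node_labels)}
    adj = np.zeros((len(node_labels), len(node_labels)), dtype=np.int8)
    for src, dst in edges:
        adj[index[src], index[dst]] = 1
    return DAG(adj, node_labels)
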