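"""Benchmark network topologies used as gold standards in the experiments."""
from __future__ import annotations

import numpy as np

from .graphs import DAG

__all__ = ["benchmark_dag", "raf_pathway"]


_BENCHMARK_EDGES = [
    ("G1", "G2"),
    ("G1", "G3"),
    ("G2", "G4"),
    ("G3", "G4"),
    ("G3", "G5"),
    ("G4", "G6"),
    ("G5", "G7"),
    ("G6", "G8"),
    ("G7", "G8"),
    ("G2", "G9"),
    ("G9", "G10"),
    ("G5", "G10"),
]

# Consensus Raf/MAPK signalling topology, reconstructed from the flow-cytometry
# literature (11 phosphoproteins/phospholipids, 20 directed interactions).
_RAF_EDGES = [
    ("PKC", "PKA"),
    ("PKC", "Raf"),
    ("PKC", "Mek"),
    ("PKC", "Jnk"),
    ("PKC", "P38"),
    ("PKA", "Raf"),
    ("PKA", "Mek"),
    ("PKA", "Erk"),
    ("PKA", "Akt"),
    ("PKA", "Jnk"),
    ("PKA", "P38"),
    ("Raf", "Mek"),
    ("Mek", "Erk"),
    ("Erk", "Akt"),
    ("Plcg", "PIP2"),
    ("Plcg", "PIP3"),
    ("Plcg", "PKC"),
    ("PIP3", "PIP2"),
    ("PIP3", "Akt"),
    ("PIP2", "PKC"),
]


def _from_edges(labels: list[str], edges: list[tuple[str, str]]) -> DAG:
    index = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for src, dst in edges:
        adj[index[src], index[dst]] = 1
    return DAG(adj, labels)


def benchmark_dag() -> DAG:
    """Default 10-gene synthetic benchmark cascade (12 edges).

    A fixed, hand-designed regulatory cascade with branching and
    convergence, used as the default gold standard for the simulation
    experiments.  It is a synthetic topology, not taken from any organism.
    """
    labels = [f"G{i}" for i in range(1, 11)]
    return _from_edges(labels, _BENCHMARK_EDGES)


def raf_pathway() -> DAG:
    """Consensus Raf signalling pathway (11 nodes, 20 edges).

    Reconstructed from the published flow-cytometry signalling literature as
    the commonly used gold standard for that data; an approximation of the
    accepted pathway, shipped for evaluating externally produced data sets.
    """
    labels = ["Raf", "Mek", "Plcg", "PIP2", "PIP3", "Erk", "Akt", "PKA", "PKC", "P38", "Jnk"]
    return _from_edges(labels, _RAF_EDGES)
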