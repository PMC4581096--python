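"""Shared test helper: Markov-equivalence grouping of small DAG spaces."""
import itertools

import numpy as np

from bnggm.exact import enumerate_dags


def equivalence_key(adj):
    """(skeleton, v-structures) — the graphical criterion for Markov
    equivalence of DAGs."""
    n = adj.shape[0]
    skeleton = frozenset(frozenset((int(i), int(k))) for i, k in zip(*np.nonzero(adj)))
    v_structures = set()
    for k in range(n):
        pa = np.flatnonzero(adj[:, k])
        for a, b in itertools.combinations(pa, 2):
            if adj[a, b] == 0 and adj[b, a] == 0:
                v_structures.add((int(min(a, b)), int(max(a, b)), int(k)))
    return skeleton, frozenset(v_structures)


def equivalence_classes(n_nodes):
    """All labelled DAGs on ``n_nodes`` grouped into equivalence classes."""
    groups = {}
    for adj in enumerate_dags(n_nodes):
        groups.setdefault(equivalence_key(adj), []).append(adj)
    return list(groups.values())
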