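"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: DAG
enumeration is by brute force over ordered-pair assignments, densities and
entropies come from explicit joint-table sums, and 1-D k-means is solved
by exhaustive split search.  Tests compare the library against these.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mpchc import DAG, forward_sample
from mpchc.synthetic import chain_network, collider_network, fork_network, mixed8_network


def all_dags(nodes: tuple[str, ...]) -> list[DAG]:
    """Every labelled DAG on the given nodes, by exhaustive assignment of
    {absent, a->b, b->a} to each unordered pair and an independent
    cycle-check (Kahn's algorithm, not the library's)."""
    pairs = list(itertools.combinations(nodes, 2))
    out = []
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        if _kahn_acyclic(nodes, edges):
            out.append(DAG(nodes, edges))
    return out


def _kahn_acyclic(nodes, edges) -> bool:
    indeg = {n: 0 for n in nodes}
    succ = {n: [] for n in nodes}
    for a, b in edges:
        indeg[b] += 1
        succ[a].append(b)
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for m in succ[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    return seen == len(nodes)


def joint_from_bn(bn) -> tuple[tuple[str, ...], np.ndarray]:
    """Full joint table by direct product over all state combinations —
    independent of the library's factor code."""
    order = tuple(bn.dag.nodes)
    cards = [bn.cardinality(v) for v in order]
    joint = np.zeros(cards)
    for assignment in itertools.product(*[range(c) for c in cards]):
        state = dict(zip(order, assignment))
        p = 1.0
        for node in order:
            cpt = bn.cpts[node]
            if cpt.parents:
                pcards = [bn.cardinality(q) for q in cpt.parents]
                idx = np.ravel_multi_index([[state[q]] for q in cpt.parents], pcards)[0]
            else:
                idx = 0
            p *= cpt.table[idx, state[node]]
        joint[assignment] = p
    return order, joint


def kmeans_1d_oracle(x: np.ndarray) -> tuple[float, float]:
    """Optimal two-cluster 1-D split by exhaustive search over the sorted
    sample; returns the two centroids."""
    xs = np.sort(x)
    best = None
    for i in range(1, len(xs)):
        lo, hi = xs[:i], xs[i:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, float(lo.mean()), float(hi.mean()))
    return best[1], best[2]


@pytest.fixture(scope="session")
def chain_bn():
    return chain_network()


@pytest.fixture(scope="session")
def fork_bn():
    return fork_network()


@pytest.fixture(scope="session")
def collider_bn():
    return collider_network()


@pytest.fixture(scope="session")
def mixed8_bn():
    return mixed8_network()


@pytest.fixture(scope="session")
def chain_sample(chain_bn):
    return forward_sample(chain_bn, 3000, seed=11)


@pytest.fixture(scope="session")
def collider_sample(collider_bn):
    return forward_sample(collider_bn, 3000, seed=12)
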