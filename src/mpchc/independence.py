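"""Chi-square conditional-independence testing and skeleton estimation.

The skeleton learner starts from the complete undirected graph and, for a
growing conditioning-set size, removes an edge X–Y as soon as some
conditioning set U drawn from the current neighbours of X or of Y renders
them conditionally independent at the chosen significance level.
Adjacency sets are refreshed only between levels (the "stable" refresh
policy), which makes the result invariant to the order in which variables
are listed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import DiscreteDataset
from .graph import Skeleton

__all__ = ["CITestResult", "chi_square_ci_test", "learn_skeleton", "ci_log_frame"]


@dataclass
class CITestResult:
    """One conditional-independence decision: X independent of Y given U?"""

    pair: tuple[str, str]
    conditioning_set: tuple[str, ...]
    statistic: float
    dof: int
    p_value: float
    alpha: float
    independent: bool


def chi_square_ci_test(
    data: DiscreteDataset,
    x: str,
    y: str,
    u: tuple[str, ...] = (),
    alpha: float = 0.01,
) -> CITestResult:
    """Pearson chi-square test of X independent of Y within each stratum of U.

    Within each conditioning configuration u the expected cell count under
    the null is N(x,u)*N(y,u)/N(u); the statistic sums (O-E)^2/E over cells
    with E > 0, pooled across strata.  Degrees of freedom are
    (|X|-1)(|Y|-1) per stratum actually observed (empty strata contribute
    neither statistic nor dof).  Independence is accepted when the upper-tail
    p-value exceeds ``alpha``.
    """
    u = tuple(u)
    if x == y:
        raise ValueError("x and y must differ")
    if x in u or y in u:
        raise ValueError("conditioning set must not contain the tested pair")
    if data.M == 0:
        raise ValueError("empty dataset")
    rx, ry = data.cardinality(x), data.cardinality(y)
    xcol, ycol = data.column(x), data.column(y)
    if u:
        cards = [data.cardinality(v) for v in u]
        strata = np.ravel_multi_index([data.column(v) for v in u], cards)
        n_strata_total = int(np.prod(cards))
    else:
        strata = np.zeros(data.M, dtype=np.int64)
        n_strata_total = 1
    # joint counts: stratum x X-state x Y-state
    flat = (strata * rx + xcol) * ry + ycol
    counts = np.bincount(flat, minlength=n_strata_total * rx * ry).reshape(
        n_strata_total, rx, ry
    )
    n_u = counts.sum(axis=(1, 2))
    nonempty = n_u > 0
    stat = 0.0
    for s in np.flatnonzero(nonempty):
        obs = counts[s]
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n_u[s]
        mask = expected > 0
        stat += float((((obs - expected) ** 2)[mask] / expected[mask]).sum())
    dof = max(1, (rx - 1) * (ry - 1) * int(nonempty.sum()))
    p = float(chi2.sf(stat, dof))
    return CITestResult(
        pair=(x, y) if x < y else (y, x),
        conditioning_set=tuple(sorted(u)),
        statistic=stat,
        dof=dof,
        p_value=p,
        alpha=alpha,
        independent=p > alpha,
    )


def learn_skeleton(
    data: DiscreteDataset,
    alpha: float = 0.01,
    max_cond_size: int = 3,
) -> tuple[Skeleton, list[CITestResult]]:
    """Constraint-based skeleton estimation with a growing conditioning set.

    Starting from the complete graph, level l = 0..max_cond_size tests each
    surviving edge X–Y against every size-l subset of the level-start
    neighbours of X (excluding Y) and of Y (excluding X); the edge is
    deleted on the first accepted independence.  The full test log is
    returned for audit.
    """
    if len(data.variables) < 2:
        raise ValueError("need at least two variables")
    if max_cond_size < 0:
        raise ValueError("max_cond_size must be >= 0")
    skel = Skeleton.complete(data.variables)
    log: list[CITestResult] = []
    for level in range(max_cond_size + 1):
        # snapshot of adjacency: deletions inside a level never influence it
        adj = {v: set(skel.neighbors(v)) for v in skel.nodes}
        if all(len(adj[v]) <= level for v in skel.nodes):
            break
        for x, y in sorted(skel.edges):
            cond_sets: list[tuple[str, ...]] = []
            seen: set[frozenset[str]] = set()
            for side, other in ((x, y), (y, x)):
                pool = sorted(adj[side] - {other})
                for u in itertools.combinations(pool, level):
                    key = frozenset(u)
                    if key not in seen:
                        seen.add(key)
                        cond_sets.append(u)
            for u in cond_sets:
                res = chi_square_ci_test(data, x, y, u, alpha)
                log.append(res)
                if res.independent:
                    skel.remove_edge(x, y)
                    break
    return skel, log


def ci_log_frame(log: list[CITestResult]) -> pd.DataFrame:
    """Audit table of a skeleton run: one row per CI decision."""
    return pd.DataFrame(
        {
            "x": [r.pair[0] for r in log],
            "y": [r.pair[1] for r in log],
            "conditioning_set": [";".join(r.conditioning_set) for r in log],
            "statistic": [r.statistic for r in log],
            "dof": [r.dof for r in log],
            "p_value": [r.p_value for r in log],
            "independent": [r.independent for r in log],
        }
    )
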