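"""BIC scoring and structure search over immorality configurations.

The structure learner proceeds in three stages.  A constraint-learned
skeleton fixes the candidate adjacencies.  Every subset of the skeleton's
candidate colliders whose induced arcs are mutually consistent and acyclic
defines an *immorality configuration*; each configuration seeds a partially
directed graph whose collider arcs are fixed.  A greedy hill-climb then
orients, deletes or reverses the remaining skeleton edges — never adding an
edge outside the skeleton and never changing the set of unshielded
colliders — accepting at each step the legal single-edge move with the
highest BIC improvement.  The best-scoring directed graph across all
configurations is returned; because BIC is score-equivalent, this amounts
to evaluating one representative per Markov-equivalence class reachable in
the skeleton.

score_BIC(G:D) = l(theta_hat : D) - (ln M / 2) * Dim[G], with
Dim[G] = sum_i (r_i - 1) * q_i (r_i = state count of node i, q_i = product
of its parents' state counts) and l the maximised multinomial
log-likelihood in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import DiscreteDataset
from .graph import (
    DAG,
    Immorality,
    Skeleton,
    find_candidate_immoralities,
    is_acyclic,
    v_structures,
)

__all__ = [
    "ScoreReport",
    "ImmoralityConfiguration",
    "SearchStep",
    "SearchTrace",
    "BicCache",
    "bic_score",
    "enumerate_immorality_configs",
    "orient_edges",
    "mpc_hc",
    "hc_search",
]

_EPS = 1e-10  # strict-improvement margin for the greedy loops


@dataclass
class ScoreReport:
    """Decomposed BIC score of a structure against a dataset."""

    loglik: float
    dim: int
    M: int
    score_bic: float


@dataclass(frozen=True)
class ImmoralityConfiguration:
    """A chosen collider subset and the directed arcs it pins down."""

    immoralities: frozenset[Immorality]
    fixed_edges: frozenset[tuple[str, str]]


@dataclass
class SearchStep:
    operator: str  # "orient" | "delete" | "reverse" | "add"
    edge: tuple[str, str]
    score_before: float
    score_after: float


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)

    def strictly_increasing(self) -> bool:
        return all(s.score_after > s.score_before for s in self.steps)


class BicCache:
    """Per-dataset cache of family scores.

    The BIC score decomposes over nodes into family terms depending only on
    (node, parent set); caching them makes greedy search cheap because a
    single-edge move touches at most two families.
    """

    def __init__(self, data: DiscreteDataset):
        self.data = data
        self.M = data.M
        self._ll: dict[tuple[str, frozenset[str]], float] = {}
        self._cards = {v: data.cardinality(v) for v in data.variables}
        self._cols = {v: data.column(v) for v in data.variables}

    def family_loglik(self, node: str, parents: tuple[str, ...]) -> float:
        key = (node, frozenset(parents))
        if key in self._ll:
            return self._ll[key]
        k = self._cards[node]
        if parents:
            cards = [self._cards[p] for p in parents]
            cfg = np.ravel_multi_index([self._cols[p] for p in parents], cards)
        else:
            cfg = np.zeros(self.M, dtype=np.int64)
        q = int(np.prod([self._cards[p] for p in parents])) if parents else 1
        counts = np.bincount(cfg * k + self._cols[node], minlength=q * k).reshape(q, k)
        n_cfg = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * (np.log(counts) - np.log(n_cfg))
        ll = float(np.nansum(np.where(counts > 0, terms, 0.0)))
        self._ll[key] = ll
        return ll

    def family_dim(self, node: str, parents: tuple[str, ...]) -> int:
        q = int(np.prod([self._cards[p] for p in parents])) if parents else 1
        return (self._cards[node] - 1) * q

    def family_score(self, node: str, parents: tuple[str, ...]) -> float:
        return self.family_loglik(node, parents) - 0.5 * math.log(self.M) * self.family_dim(
            node, parents
        )

    def score_parent_map(self, parent_map: dict[str, tuple[str, ...]]) -> ScoreReport:
        """Score a structure given its node -> parents mapping; data
        variables absent from the mapping count as parentless."""
        loglik = 0.0
        dim = 0
        for node in self.data.variables:
            parents = parent_map.get(node, ())
            loglik += self.family_loglik(node, parents)
            dim += self.family_dim(node, parents)
        return ScoreReport(loglik, dim, self.M, loglik - 0.5 * math.log(self.M) * dim)

    def score_dag(self, g: DAG) -> ScoreReport:
        return self.score_parent_map({node: g.parents(node) for node in g.nodes})


def bic_score(g: DAG, data: DiscreteDataset) -> ScoreReport:
    """BIC score of a DAG: maximised log-likelihood (natural log, MLE
    conditional relative frequencies) minus (ln M / 2) * Dim[G].  Data
    variables not covered by the DAG are scored as parentless nodes."""
    if data.M == 0:
        raise ValueError("empty dataset")
    if not set(g.nodes) <= set(data.variables):
        raise ValueError("DAG nodes must be covered by the dataset")
    return BicCache(data).score_dag(
        DAG(data.variables, g.edges)
    )


def _edges_of(immoralities) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for imm in immoralities:
        out |= imm.edges
    return out


def enumerate_immorality_configs(s: Skeleton) -> list[ImmoralityConfiguration]:
    """All collider-subset configurations of a skeleton.

    A subset of the candidate immoralities is admissible when its induced
    arcs never direct a pair both ways and stay acyclic.  The list always
    contains the empty configuration; its length is bounded by 2^r for r
    candidates, with equality exactly when no subset conflicts (e.g. a
    star, where every arc points into the hub).
    """
    candidates = sorted(find_candidate_immoralities(s))
    configs: list[ImmoralityConfiguration] = []

    def extend(idx: int, chosen: list[Immorality], edges: set[tuple[str, str]]) -> None:
        if idx == len(candidates):
            configs.append(
                ImmoralityConfiguration(frozenset(chosen), frozenset(edges))
            )
            return
        extend(idx + 1, chosen, edges)  # skip candidate
        imm = candidates[idx]
        new_edges = imm.edges - edges
        if any((b, a) in edges for a, b in new_edges):
            return  # conflicting direction; prune this branch
        trial = edges | new_edges
        if is_acyclic(DAG(s.nodes, trial)):
            chosen.append(imm)
            extend(idx + 1, chosen, trial)
            chosen.pop()

    extend(0, [], set())
    configs.sort(key=lambda c: (len(c.immoralities), sorted(c.immoralities)))
    return configs


def _graph_key(edges: set[tuple[str, str]]) -> tuple[int, list[tuple[str, str]]]:
    """Deterministic tie-break key: fewer edges first, then lexicographic."""
    return (len(edges), sorted(edges))


def orient_edges(
    s: Skeleton,
    config: ImmoralityConfiguration,
    data: DiscreteDataset,
    cache: BicCache | None = None,
) -> tuple[DAG, ScoreReport, SearchTrace]:
    """Greedy BIC orientation of a skeleton under a fixed collider set.

    The start state directs only the configuration's arcs; the remaining
    skeleton edges are undirected and contribute no parents until oriented.
    Legal single-edge moves are: orient an undirected skeleton edge in
    either direction, or delete/reverse a currently-directed non-fixed
    edge.  A move is admissible only if the resulting directed graph is
    acyclic and its unshielded-collider set is unchanged from the start
    state (no immorality may be created or destroyed).  The best strictly
    improving move is applied until none remains.
    """
    if cache is None:
        cache = BicCache(data)
    nodes = tuple(data.variables)
    if not set(s.nodes) <= set(nodes):
        raise ValueError("skeleton nodes must be covered by the dataset")
    fixed = set(config.fixed_edges)
    covered = {tuple(sorted(e)) for e in fixed}
    undirected = {e for e in s.edges if e not in covered}
    directed = set(fixed)
    start = DAG(nodes, directed)
    if not is_acyclic(start):
        raise ValueError("configuration induces a cyclic fixed-edge graph")
    target_vs = v_structures(start)

    def score_of(edges: set[tuple[str, str]]) -> float:
        pm: dict[str, list[str]] = {}
        for a, b in edges:
            pm.setdefault(b, []).append(a)
        return cache.score_parent_map(
            {n: tuple(sorted(ps)) for n, ps in pm.items()}
        ).score_bic

    def legal(edges: set[tuple[str, str]]) -> bool:
        g = DAG(nodes, edges)
        return is_acyclic(g) and v_structures(g) == target_vs

    current = set(directed)
    score = score_of(current)
    trace = SearchTrace()
    while True:
        best: tuple[float, tuple[int, list], str, tuple[str, str], set] | None = None
        moves: list[tuple[str, tuple[str, str], set[tuple[str, str]], object]] = []
        for a, b in sorted(undirected):
            moves.append(("orient", (a, b), current | {(a, b)}, (a, b)))
            moves.append(("orient", (b, a), current | {(b, a)}, (a, b)))
        for e in sorted(current - fixed):
            moves.append(("delete", e, current - {e}, e))
            moves.append(("reverse", e, (current - {e}) | {(e[1], e[0])}, e))
        for op, edge, new_edges, pool_key in moves:
            if not legal(new_edges):
                continue
            sc = score_of(new_edges)
            cand = (sc, _graph_key(new_edges), op, edge, new_edges, pool_key)
            if best is None or _better(cand, best):
                best = cand
        if best is None or best[0] <= score + _EPS:
            break
        sc, _, op, edge, new_edges, pool_key = best
        trace.steps.append(SearchStep(op, edge, score, sc))
        current = new_edges
        score = sc
        if op == "orient":
            undirected.discard(pool_key)
        elif op == "delete":
            pass  # deleted edges leave the graph permanently
        # reverse keeps the edge directed; nothing to update in the pools
    g = DAG(nodes, current)
    return g, cache.score_dag(g), trace


def _better(cand, best) -> bool:
    """Higher score wins; ties prefer fewer edges, then the
    lexicographically smallest edge list."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return cand[1] < best[1]


def mpc_hc(
    data: DiscreteDataset,
    alpha: float = 0.01,
    max_cond_size: int = 3,
) -> tuple[DAG, ScoreReport, dict]:
    """Full hybrid structure learner.

    Constraint-learn the skeleton, enumerate every admissible immorality
    configuration, greedily orient each, and return the highest-BIC
    directed graph (ties: fewer edges, then lexicographic edge list).
    Diagnostics carry the skeleton, the CI-test log and per-configuration
    scores.
    """
    from .independence import learn_skeleton

    if len(data.variables) == 0:
        raise ValueError("dataset has no variables")
    if len(data.variables) == 1:  # degenerate: nothing to orient
        g = DAG(data.variables)
        return g, BicCache(data).score_dag(g), {
            "skeleton": Skeleton(data.variables),
            "ci_tests": [],
            "n_configurations": 1,
            "per_config": [],
        }
    skel, log = learn_skeleton(data, alpha=alpha, max_cond_size=max_cond_size)
    cache = BicCache(data)
    configs = enumerate_immorality_configs(skel)
    best: tuple[DAG, ScoreReport] | None = None
    per_config: list[dict] = []
    for config in configs:
        g, report, trace = orient_edges(skel, config, data, cache)
        per_config.append(
            {
                "immoralities": sorted(config.immoralities),
                "score_bic": report.score_bic,
                "n_edges": len(g.edges),
                "n_steps": len(trace.steps),
            }
        )
        if best is None or _dag_better(g, report, best):
            best = (g, report)
    assert best is not None  # the empty configuration always exists
    diagnostics = {
        "skeleton": skel,
        "ci_tests": log,
        "n_configurations": len(configs),
        "per_config": per_config,
    }
    return best[0], best[1], diagnostics


def _dag_better(g: DAG, report: ScoreReport, best: tuple[DAG, ScoreReport]) -> bool:
    cur_g, cur_r = best
    if report.score_bic != cur_r.score_bic:
        return report.score_bic > cur_r.score_bic
    return _graph_key(set(g.edges)) < _graph_key(set(cur_g.edges))


def hc_search(
    data: DiscreteDataset,
    seed_graph: DAG | None = None,
) -> tuple[DAG, ScoreReport, SearchTrace]:
    """Unconstrained greedy hill-climbing baseline.

    Single-edge moves (add, delete, reverse) over all node pairs with
    acyclicity enforced; at each step the highest-scoring strictly
    improving move is applied, stopping at the first local optimum.
    """
    cache = BicCache(data)
    nodes = tuple(data.variables)
    current: set[tuple[str, str]] = set(seed_graph.edges) if seed_graph is not None else set()

    def score_of(edges: set[tuple[str, str]]) -> float:
        pm: dict[str, list[str]] = {}
        for a, b in edges:
            pm.setdefault(b, []).append(a)
        return cache.score_parent_map({n: tuple(sorted(p)) for n, p in pm.items()}).score_bic

    score = score_of(current)
    trace = SearchTrace()
    while True:
        best = None
        moves: list[tuple[str, tuple[str, str], set]] = []
        for a in nodes:
            for b in nodes:
                if a == b:
                    continue
                if (a, b) in current:
                    moves.append(("delete", (a, b), current - {(a, b)}))
                    if (b, a) not in current:
                        moves.append(
                            ("reverse", (a, b), (current - {(a, b)}) | {(b, a)})
                        )
                elif (b, a) not in current:
                    moves.append(("add", (a, b), current | {(a, b)}))
        for op, edge, new_edges in moves:
            if not is_acyclic(DAG(nodes, new_edges)):
                continue
            sc = score_of(new_edges)
            cand = (sc, _graph_key(new_edges), op, edge, new_edges)
            if best is None or _better(cand, best):
                best = cand
        if best is None or best[0] <= score + _EPS:
            break
        sc, _, op, edge, new_edges = best
        trace.steps.append(SearchStep(op, edge, score, sc))
        current, score = new_edges, sc
    g = DAG(nodes, current)
    return g, cache.score_dag(g), trace
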