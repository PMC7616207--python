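"""Graph data model for Bayesian-network structure learning.

Three graph stages appear in the learning pipeline: an undirected
:class:`Skeleton` produced by conditional-independence testing, a
:class:`PDAG` in which a chosen set of colliders has been directed, and a
fully directed acyclic :class:`DAG`.  The module also provides the
v-structure (immorality) machinery and the I-equivalence predicate on
which score-based search over equivalence classes rests.

Node identity is by string name; a fixed total (lexicographic) order on
names resolves all canonical forms and iteration orders, so every
operation here is deterministic.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import networkx as nx

__all__ = [
    "Immorality",
    "Skeleton",
    "PDAG",
    "DAG",
    "is_acyclic",
    "find_candidate_immoralities",
    "v_structures",
    "is_i_equivalent",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair."""
    if a == b:
        raise ValueError(f"self-loop on node {a!r}")
    return (a, b) if a < b else (b, a)


class Immorality(NamedTuple):
    """A collider ``left -> center <- right`` whose tails are nonadjacent.

    Canonical ordering ``left < right`` so that (A, C, B) and (B, C, A)
    compare equal.
    """

    left: str
    center: str
    right: str

    @classmethod
    def make(cls, tail1: str, center: str, tail2: str) -> "Immorality":
        if tail1 == tail2 or tail1 == center or tail2 == center:
            raise ValueError("immorality nodes must be distinct")
        a, b = sorted((tail1, tail2))
        return cls(a, center, b)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """The two directed edges the collider induces."""
        return frozenset({(self.left, self.center), (self.right, self.center)})


class Skeleton:
    """Undirected graph over named variables: the output of constraint testing."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        node_set = set(self.nodes)
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            self._edges.add(_pair(a, b))

    @classmethod
    def complete(cls, nodes: Iterable[str]) -> "Skeleton":
        nodes = tuple(sorted(set(nodes)))
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        return cls(nodes, edges)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self._edges

    def add_edge(self, a: str, b: str) -> None:
        if a not in self.nodes or b not in self.nodes:
            raise ValueError("unknown node")
        self._edges.add(_pair(a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self._edges.discard(_pair(a, b))

    def neighbors(self, x: str) -> tuple[str, ...]:
        out = {b if a == x else a for (a, b) in self._edges if x in (a, b)}
        return tuple(sorted(out))

    def copy(self) -> "Skeleton":
        return Skeleton(self.nodes, self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Skeleton):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self._edges)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Skeleton(nodes={list(self.nodes)}, edges={sorted(self._edges)})"


class DAG:
    """Directed graph over named variables; acyclicity checked via :func:`is_acyclic`."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        node_set = set(self.nodes)
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            if (b, a) in self._edges:
                raise ValueError(f"edge between {a!r} and {b!r} present in both directions")
            self._edges.add((a, b))

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self._edges)

    def parents(self, x: str) -> tuple[str, ...]:
        return tuple(sorted(a for (a, b) in self._edges if b == x))

    def children(self, x: str) -> tuple[str, ...]:
        return tuple(sorted(b for (a, b) in self._edges if a == x))

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self._edges or (b, a) in self._edges

    def skeleton(self) -> Skeleton:
        return Skeleton(self.nodes, self._edges)

    def topological_order(self) -> list[str]:
        g = self.to_networkx()
        return list(nx.lexicographical_topological_sort(g))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self._edges)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DAG(nodes={list(self.nodes)}, edges={self.sorted_edges()})"


class PDAG:
    """Partially directed graph: directed and undirected edges in separate sets.

    A node pair may appear as directed or undirected, never both; the
    directed part must stay acyclic for the object to be well-formed.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        directed_edges: Iterable[tuple[str, str]] = (),
        undirected_edges: Iterable[tuple[str, str]] = (),
    ):
        self.nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        self.directed_edges: frozenset[tuple[str, str]] = frozenset(directed_edges)
        self.undirected_edges: frozenset[tuple[str, str]] = frozenset(
            _pair(a, b) for a, b in undirected_edges
        )
        for a, b in self.directed_edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if (b, a) in self.directed_edges:
                raise ValueError(f"edge between {a!r} and {b!r} directed both ways")
            if _pair(a, b) in self.undirected_edges:
                raise ValueError(f"pair ({a!r}, {b!r}) both directed and undirected")

    def skeleton(self) -> Skeleton:
        pairs = [_pair(a, b) for a, b in self.directed_edges]
        return Skeleton(self.nodes, list(self.undirected_edges) + pairs)

    def directed_part(self) -> DAG:
        return DAG(self.nodes, self.directed_edges)


def is_acyclic(g: "DAG | PDAG") -> bool:
    """True iff the directed part of ``g`` admits a topological order."""
    edges = g.directed_edges if isinstance(g, PDAG) else g.edges
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(h)


def find_candidate_immoralities(s: Skeleton) -> frozenset[Immorality]:
    """Every triple X–Z–Y in the skeleton with X and Y nonadjacent.

    These are exactly the triples that a structure in the skeleton's
    equivalence-class family *could* turn into a collider.
    """
    out: set[Immorality] = set()
    for z in s.nodes:
        nb = s.neighbors(z)
        for i, x in enumerate(nb):
            for y in nb[i + 1 :]:
                if not s.has_edge(x, y):
                    out.add(Immorality.make(x, z, y))
    return frozenset(out)


def v_structures(g: DAG) -> frozenset[Immorality]:
    """All unshielded colliders X -> Z <- Y of a directed graph."""
    out: set[Immorality] = set()
    for z in g.nodes:
        pa = g.parents(z)
        for i, x in enumerate(pa):
            for y in pa[i + 1 :]:
                if not g.adjacent(x, y):
                    out.add(Immorality.make(x, z, y))
    return frozenset(out)


def is_i_equivalent(g1: DAG, g2: DAG) -> bool:
    """Same skeleton and same immorality set: the graphs encode identical
    conditional-independence statements, and any score-consistent criterion
    assigns them equal scores."""
    if g1.nodes != g2.nodes:
        raise ValueError("DAGs must share a node set")
    return g1.skeleton() == g2.skeleton() and v_structures(g1) == v_structures(g2)
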