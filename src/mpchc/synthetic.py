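"""Synthetic ground truths: random discrete networks, small hand-built
benchmark networks with fully documented CPTs, and a continuous 10-marker
cohort generator.

No real cohort ships with the package, so these generators define the test
surface: the hand-built networks exercise structure recovery (their
equivalence classes are known exactly), and the marker cohort emulates a
table of ten continuous markers drawn from three correlated sources —
four psychological scores (VWM, VSM, VCI, PRI), three functional-imaging
summaries (PRF, DGM, SMA) and three neural-density summaries (PDN, PSN,
DSN) — with strong within-block and weak cross-block dependence.
"""

from __future__ import annotations

import numpy as np

from .data import ContinuousDataset
from .graph import DAG
from .inference import CPT, BayesianNetwork

__all__ = [
    "make_random_bn",
    "make_marker_cohort",
    "chain_network",
    "fork_network",
    "collider_network",
    "mixed8_network",
    "MARKER_VARIABLES",
    "MARKER_BLOCKS",
    "default_marker_effects",
]

_TWO = ("Low", "High")


def make_random_bn(
    n_nodes: int,
    max_parents: int = 2,
    cardinality: int = 2,
    seed: int = 0,
) -> BayesianNetwork:
    """Random DAG with <= ``max_parents`` parents per node and CPT rows
    drawn from a flat Dirichlet; reproducible under ``seed``."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    names = tuple(f"X{i:02d}" for i in range(n_nodes))
    order = list(rng.permutation(n_nodes))
    edges: list[tuple[str, str]] = []
    for pos, i in enumerate(order):
        pool = [names[j] for j in order[:pos]]
        k = int(rng.integers(0, min(max_parents, len(pool)) + 1))
        parents = sorted(rng.choice(len(pool), size=k, replace=False)) if k else []
        edges.extend((pool[j], names[i]) for j in parents)
    dag = DAG(names, edges)
    states = tuple(f"s{i}" for i in range(cardinality))
    cpts: dict[str, CPT] = {}
    for node in names:
        parents = dag.parents(node)
        q = int(np.prod([cardinality] * len(parents))) if parents else 1
        table = rng.dirichlet(np.ones(cardinality), size=q)
        cpts[node] = CPT(node, parents, table, np.ones(cardinality))
    return BayesianNetwork(dag, cpts, {n: states for n in names})


def _bn(edges: list[tuple[str, str]], tables: dict[str, np.ndarray], nodes=None) -> BayesianNetwork:
    names = tuple(sorted(tables)) if nodes is None else tuple(sorted(nodes))
    dag = DAG(names, edges)
    cpts = {
        node: CPT(node, dag.parents(node), np.asarray(tab, dtype=float), np.ones(2))
        for node, tab in tables.items()
    }
    return BayesianNetwork(dag, cpts, {n: _TWO for n in names})


def chain_network(strength: float = 0.9) -> BayesianNetwork:
    """A -> B -> C with P(child = parent's state) = ``strength`` and a
    uniform root.  Its equivalence class contains three members (chain in
    both directions and the common-cause fork)."""
    s = strength
    return _bn(
        [("A", "B"), ("B", "C")],
        {
            "A": [[0.5, 0.5]],
            "B": [[s, 1 - s], [1 - s, s]],
            "C": [[s, 1 - s], [1 - s, s]],
        },
    )


def fork_network(strength: float = 0.9) -> BayesianNetwork:
    """Common cause B -> A, B -> C; I-equivalent to the chain."""
    s = strength
    return _bn(
        [("B", "A"), ("B", "C")],
        {
            "B": [[0.5, 0.5]],
            "A": [[s, 1 - s], [1 - s, s]],
            "C": [[s, 1 - s], [1 - s, s]],
        },
    )


def collider_network() -> BayesianNetwork:
    """A -> C <- B with independent uniform tails.

    The child's distribution responds monotonically to each parent
    separately (no parity cancellation), so both adjacencies are
    marginally detectable while the tails stay marginally independent:
    the collider is the unique member of its equivalence class."""
    return _bn(
        [("A", "C"), ("B", "C")],
        {
            "A": [[0.5, 0.5]],
            "B": [[0.5, 0.5]],
            # rows: (A,B) = (Low,Low), (Low,High), (High,Low), (High,High)
            "C": [[0.90, 0.10], [0.40, 0.60], [0.30, 0.70], [0.05, 0.95]],
        },
    )


def mixed8_network() -> BayesianNetwork:
    """Eight binary nodes mixing chains and two colliders.

        A -> B -> C <- D,  C -> E -> F <- G,  D -> H

    Unshielded colliders: (B, C, D) and (E, F, G).  All CPTs are strong
    enough that n = 3000 identifies the equivalence class reliably."""
    s = 0.85
    flip = [[s, 1 - s], [1 - s, s]]
    return _bn(
        [
            ("A", "B"),
            ("B", "C"),
            ("D", "C"),
            ("C", "E"),
            ("E", "F"),
            ("G", "F"),
            ("D", "H"),
        ],
        {
            "A": [[0.6, 0.4]],
            "B": flip,
            "D": [[0.35, 0.65]],
            # rows: (B,D) = (L,L), (L,H), (H,L), (H,H)
            "C": [[0.90, 0.10], [0.45, 0.55], [0.30, 0.70], [0.05, 0.95]],
            "E": flip,
            "G": [[0.55, 0.45]],
            # rows: (E,G) = (L,L), (L,H), (H,L), (H,H)
            "F": [[0.85, 0.15], [0.40, 0.60], [0.35, 0.65], [0.10, 0.90]],
            "H": flip,
        },
    )


MARKER_VARIABLES = ("VWM", "VSM", "VCI", "PRI", "PRF", "DGM", "SMA", "PDN", "PSN", "DSN")

MARKER_BLOCKS = {
    "psychology": ("VWM", "VSM", "VCI", "PRI"),
    "fmri": ("PRF", "DGM", "SMA"),
    "neural_density": ("PDN", "PSN", "DSN"),
}


def default_marker_effects() -> np.ndarray:
    """Structural coefficients of the default cohort model.

    Entry (i, j) is the coefficient of variable j (parent) in the
    equation of variable i (child); strictly lower-triangular in the
    MARKER_VARIABLES order.  Within-block chains use weight 0.9 and
    cross-block couplings 0.15, giving within-block correlations well
    above every cross-block one."""
    w = np.zeros((10, 10))
    idx = {v: i for i, v in enumerate(MARKER_VARIABLES)}

    def set_(child: str, parent: str, coef: float) -> None:
        w[idx[child], idx[parent]] = coef

    # psychology chain
    set_("VSM", "VWM", 0.9)
    set_("VCI", "VSM", 0.9)
    set_("PRI", "VCI", 0.9)
    # fMRI block
    set_("DGM", "PRF", 0.9)
    set_("SMA", "DGM", 0.9)
    # neural-density chain
    set_("PSN", "PDN", 0.9)
    set_("DSN", "PSN", 0.9)
    # weak cross-block couplings
    set_("PRF", "PRI", 0.15)
    set_("PDN", "SMA", 0.15)
    return w


def marker_covariance(effects: np.ndarray, noise_scale: float = 1.0) -> np.ndarray:
    """Implied covariance of the linear-Gaussian cohort model,
    Sigma = (I - W)^-1 D (I - W)^-T; the closed-form oracle used by the
    correlation tests."""
    w = np.asarray(effects, dtype=float)
    a = np.linalg.inv(np.eye(10) - w)
    return noise_scale**2 * a @ a.T


def make_marker_cohort(
    n: int,
    effects: np.ndarray | None = None,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> ContinuousDataset:
    """Sample ``n`` rows of the 10-marker linear-Gaussian cohort model.

    Each variable equals the weighted sum of its parents (per ``effects``,
    strictly lower-triangular in MARKER_VARIABLES order) plus independent
    Gaussian noise of scale ``noise_scale``."""
    w = default_marker_effects() if effects is None else np.asarray(effects, dtype=float)
    if w.shape != (10, 10):
        raise ValueError("effects must be a 10x10 matrix")
    if np.triu(w).any():
        raise ValueError("effects must be strictly lower-triangular in variable order")
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=noise_scale, size=(n, 10))
    x = np.zeros((n, 10))
    for i in range(10):
        x[:, i] = x @ w[i] + noise[:, i]
    return ContinuousDataset(MARKER_VARIABLES, x)
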