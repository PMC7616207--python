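"""Dirichlet-multinomial parameter learning, exact inference and prediction.

Each node of a discrete Bayesian network carries a conditional probability
table (CPT).  Given counts M[k] of the node's states within a parent
configuration and a Dirichlet(alpha_1..alpha_K) prior, the
posterior-predictive parameter estimate is (M[k] + alpha_k) / (M + alpha);
unit pseudo-counts (alpha_k = 1) are the default, which keeps every CPT
entry strictly positive so downstream inference never conditions on an
impossible event by accident.

Posterior queries are answered exactly by variable elimination; predictions
binarise the posterior at a 0.5 decision threshold and their certainty is
summarised by the posterior-probability certainty index (PPCI), a
normalised negentropy ranging from 0 (uniform posterior) to 100
(degenerate posterior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import DiscreteDataset
from .graph import DAG

__all__ = [
    "CPT",
    "BayesianNetwork",
    "PosteriorPrediction",
    "ZeroProbabilityEvidence",
    "fit_parameters",
    "posterior",
    "ppci",
    "prediction_report",
    "PredictionSummary",
]


class ZeroProbabilityEvidence(ValueError):
    """Raised when the supplied evidence has probability zero under the joint."""


@dataclass
class CPT:
    """Conditional probability table of one node.

    ``table`` has one row per parent configuration and one column per
    state.  Rows are ordered with the LAST parent varying fastest (C
    order over the parent cardinalities in ``parents`` order).
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray  # shape (q, K)
    alphas: np.ndarray  # shape (K,), Dirichlet hyperparameters

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.table.ndim != 2:
            raise ValueError("CPT table must be 2-D (configs x states)")
        if (self.alphas < 0).any():
            raise ValueError("Dirichlet hyperparameters must be non-negative")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"CPT rows of {self.node!r} must sum to 1")

    @property
    def n_states(self) -> int:
        return self.table.shape[1]


@dataclass
class BayesianNetwork:
    """A DAG plus one CPT per node; factorises the joint distribution."""

    dag: DAG
    cpts: dict[str, CPT]
    state_names: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node!r}")
            cpt = self.cpts[node]
            if cpt.parents != self.dag.parents(node):
                raise ValueError(
                    f"CPT parents of {node!r} do not match DAG parents"
                )
            k = len(self.state_names[node])
            q = int(np.prod([len(self.state_names[p]) for p in cpt.parents])) if cpt.parents else 1
            if cpt.table.shape != (q, k):
                raise ValueError(f"CPT of {node!r} has wrong shape {cpt.table.shape}")

    def cardinality(self, node: str) -> int:
        return len(self.state_names[node])

    def cpt_factor(self, node: str) -> tuple[tuple[str, ...], np.ndarray]:
        """The CPT as a factor over (parents..., node) with one axis each."""
        cpt = self.cpts[node]
        shape = tuple(self.cardinality(p) for p in cpt.parents) + (self.cardinality(node),)
        return cpt.parents + (node,), cpt.table.reshape(shape)

    def joint_table(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Full joint by enumeration (exponential; test/oracle use only)."""
        order = tuple(self.dag.nodes)
        shape = tuple(self.cardinality(v) for v in order)
        joint = np.ones(shape)
        for node in order:
            fvars, ftab = self.cpt_factor(node)
            joint = joint * _broadcast_to(fvars, ftab, order, shape)
        return order, joint

    def log_likelihood(self, data: DiscreteDataset) -> float:
        """Sum of log joint probabilities of the rows."""
        total = 0.0
        col = {v: data.column(v) for v in self.dag.nodes}
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            cfg = _config_codes(data, cpt.parents)
            p = cpt.table[cfg, col[node]]
            if (p == 0).any():
                return -math.inf
            total += float(np.log(p).sum())
        return total


def _broadcast_to(fvars, ftab, order, shape):
    """Expand a factor to the full variable order for joint enumeration."""
    view = ftab.reshape(ftab.shape + (1,) * (len(order) - ftab.ndim))
    current = list(fvars) + [v for v in order if v not in fvars]
    view = view.transpose([current.index(v) for v in order])
    return np.broadcast_to(view, shape)


def _config_codes(data: DiscreteDataset, parents: tuple[str, ...]) -> np.ndarray:
    """Row-wise parent-configuration index, last parent varying fastest."""
    if not parents:
        return np.zeros(data.M, dtype=np.int64)
    cards = [data.cardinality(p) for p in parents]
    cols = [data.column(p) for p in parents]
    return np.ravel_multi_index(cols, cards).astype(np.int64)


def fit_parameters(
    g: DAG, data: DiscreteDataset, alpha_k: float = 1.0
) -> BayesianNetwork:
    """Dirichlet posterior-predictive CPTs from counts.

    Within each parent configuration the estimate of state k is
    (M[k] + alpha_k) / (M + K*alpha_k); parent configurations never
    observed fall back to the prior mean (uniform for symmetric alphas).
    ``alpha_k = 0`` yields the plain maximum-likelihood relative
    frequencies (with a uniform fallback for unobserved configurations).
    """
    if alpha_k < 0:
        raise ValueError("alpha_k must be non-negative")
    missing = set(g.nodes) - set(data.variables)
    if missing:
        raise ValueError(f"data does not cover nodes {sorted(missing)}")
    cpts: dict[str, CPT] = {}
    state_names: dict[str, tuple[str, ...]] = {}
    for node in g.nodes:
        parents = g.parents(node)
        k = data.cardinality(node)
        q = int(np.prod([data.cardinality(p) for p in parents])) if parents else 1
        cfg = _config_codes(data, parents)
        counts = np.zeros((q, k))
        np.add.at(counts, (cfg, data.column(node)), 1.0)
        alphas = np.full(k, float(alpha_k))
        denom = counts.sum(axis=1, keepdims=True) + alphas.sum()
        table = np.where(
            denom > 0, (counts + alphas) / np.where(denom > 0, denom, 1.0), 1.0 / k
        )
        cpts[node] = CPT(node, parents, table, alphas)
        state_names[node] = data.states_of(node)
    return BayesianNetwork(g, cpts, state_names)


# ---------------------------------------------------------------------------
# Exact inference: variable elimination over numpy factors.

class _Factor:
    __slots__ = ("vars", "tab")

    def __init__(self, vars: tuple[str, ...], tab: np.ndarray):
        self.vars = vars
        self.tab = tab

    def reduce(self, var: str, state: int) -> "_Factor":
        axis = self.vars.index(var)
        tab = np.take(self.tab, state, axis=axis)
        return _Factor(self.vars[:axis] + self.vars[axis + 1 :], tab)

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = _expand(self, out_vars)
        b = _expand(other, out_vars)
        return _Factor(out_vars, a * b)

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(self.vars[:axis] + self.vars[axis + 1 :], self.tab.sum(axis=axis))


def _expand(f: _Factor, out_vars: tuple[str, ...]) -> np.ndarray:
    tab = f.tab.reshape(f.tab.shape + (1,) * (len(out_vars) - f.tab.ndim))
    current = list(f.vars) + [v for v in out_vars if v not in f.vars]
    return tab.transpose([current.index(v) for v in out_vars])


def _eliminate(factors: list[_Factor], keep: set[str]) -> _Factor:
    """Sum out all variables not in ``keep``, min-degree elimination order."""
    factors = list(factors)
    while True:
        hidden = sorted({v for f in factors for v in f.vars} - keep)
        if not hidden:
            break
        # min-degree: eliminate the variable whose product factor is smallest
        def degree(v: str) -> tuple[int, str]:
            involved = {u for f in factors if v in f.vars for u in f.vars}
            return (len(involved), v)

        var = min(hidden, key=degree)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    return result


@dataclass
class PosteriorPrediction:
    """Posterior over one target plus its thresholded state and PPCI."""

    target: str
    probabilities: np.ndarray
    state_names: tuple[str, ...]
    predicted_state: str
    ppci: float
    tie_at_threshold: bool = field(default=False)


def posterior(
    bn: BayesianNetwork, target: str, evidence: dict[str, str]
) -> PosteriorPrediction:
    """Exact posterior P(target | evidence) by variable elimination.

    Prediction rule: with two states, the state whose posterior reaches
    the 0.5 decision threshold is returned; an exact tie resolves to the
    first state in declared order (and is flagged).  With more states the
    argmax is used with the same first-state tie-break.
    """
    if target in evidence:
        raise ValueError("target cannot appear in the evidence")
    ev_codes: dict[str, int] = {}
    for var, state in evidence.items():
        states = bn.state_names[var]
        if state not in states:
            raise ValueError(f"unknown state {state!r} for variable {var!r}")
        ev_codes[var] = states.index(state)
    factors = []
    for node in bn.dag.nodes:
        fvars, ftab = bn.cpt_factor(node)
        f = _Factor(fvars, ftab)
        for var in fvars:
            if var in ev_codes:
                f = f.reduce(var, ev_codes[var])
        factors.append(f)
    result = _eliminate([f for f in factors if f.vars] + [f for f in factors if not f.vars], {target})
    tab = result.tab
    if not result.vars:  # target itself observed away — cannot happen, guarded above
        raise RuntimeError("elimination lost the target variable")
    z = float(tab.sum())
    if z <= 0.0:
        raise ZeroProbabilityEvidence(
            f"evidence {evidence} has probability zero under the network"
        )
    p = tab / z
    states = bn.state_names[target]
    tie = False
    if len(states) == 2:
        if p[0] == p[1]:
            idx, tie = 0, True
        else:
            idx = 0 if p[0] >= 0.5 else 1
    else:
        idx = int(np.argmax(p))
    return PosteriorPrediction(target, p, states, states[idx], ppci(p), tie)


def ppci(probabilities: np.ndarray) -> float:
    """Posterior-probability certainty index.

    ``100 * (1 + sum_k p_k ln p_k / ln K)`` with zero-probability terms
    contributing 0.  Equals 0 at the uniform posterior and 100 when all
    mass sits on one state.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a probability vector with K >= 2")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("input must be a normalised probability vector")
    nz = p[p > 0]
    value = 100.0 * (1.0 + float((nz * np.log(nz)).sum()) / math.log(p.size))
    return float(min(100.0, max(0.0, value)))


@dataclass
class PredictionSummary:
    target: str
    accuracy: float
    mean_ppci: float
    n: int
    disconnected: bool


def prediction_report(
    bn: BayesianNetwork, test: DiscreteDataset, targets: list[str]
) -> dict[str, PredictionSummary]:
    """Per-target accuracy and arithmetic-mean PPCI on a held-out set.

    Each test row supplies every other variable as evidence.  A target
    with no neighbours in the DAG can only be predicted from its marginal;
    such targets are flagged ``disconnected``.
    """
    if test.M == 0:
        raise ValueError("empty test set")
    out: dict[str, PredictionSummary] = {}
    frame = test.to_frame()
    for target in targets:
        disconnected = not bn.dag.parents(target) and not bn.dag.children(target)
        correct = 0
        ppci_sum = 0.0
        for _, row in frame.iterrows():
            evidence = {v: row[v] for v in test.variables if v != target}
            pred = posterior(bn, target, evidence)
            if pred.predicted_state == row[target]:
                correct += 1
            ppci_sum += pred.ppci
        out[target] = PredictionSummary(
            target=target,
            accuracy=correct / test.M,
            mean_ppci=ppci_sum / test.M,
            n=test.M,
            disconnected=disconnected,
        )
    return out
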