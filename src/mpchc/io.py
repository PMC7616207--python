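"""Serialization: the network JSON dialect and a reader for the classic
BIF format.

JSON dialect::

    {"nodes": [{"name": ..., "states": [...], "parents": [...],
                "cpt": [[...], ...]}, ...]}

CPT rows are listed in parent-configuration order with the LAST parent
varying fastest (row index = C-order ravel of the parent states in the
declared parent order); each row is the probability vector over the node's
states in declared order.  The BIF reader accepts the discrete-variable
subset of the format only, enough to load published benchmark networks.
"""

from __future__ import annotations

import json
import re

import numpy as np

from .graph import DAG
from .inference import CPT, BayesianNetwork

__all__ = ["network_to_json", "network_from_json", "read_bif", "dag_to_json", "dag_from_json"]


def network_to_json(bn: BayesianNetwork, path=None) -> dict:
    """Serialize a network to the JSON dialect; write to ``path`` if given."""
    nodes = []
    for name in bn.dag.nodes:
        cpt = bn.cpts[name]
        nodes.append(
            {
                "name": name,
                "states": list(bn.state_names[name]),
                "parents": list(cpt.parents),
                "cpt": [[float(v) for v in row] for row in cpt.table],
            }
        )
    obj = {"nodes": nodes}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    return obj


def network_from_json(source) -> BayesianNetwork:
    """Load a network from a dict, a JSON string, or a file path."""
    if isinstance(source, dict):
        obj = source
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        obj = json.loads(source)
    else:
        with open(source) as fh:
            obj = json.load(fh)
    names = [n["name"] for n in obj["nodes"]]
    edges = [(p, n["name"]) for n in obj["nodes"] for p in n.get("parents", [])]
    dag = DAG(names, edges)
    cpts: dict[str, CPT] = {}
    state_names: dict[str, tuple[str, ...]] = {}
    spec_parents = {n["name"]: tuple(n.get("parents", [])) for n in obj["nodes"]}
    for n in obj["nodes"]:
        name = n["name"]
        states = tuple(n["states"])
        state_names[name] = states
        table = np.asarray(n["cpt"], dtype=float)
        parents = spec_parents[name]
        canonical = dag.parents(name)
        if tuple(sorted(parents)) != tuple(sorted(canonical)):
            raise ValueError(f"inconsistent parents for node {name!r}")
        if parents != canonical:
            table = _reorder_parent_axes(table, parents, canonical, state_names, len(states))
        cpts[name] = CPT(name, canonical, table, np.ones(len(states)))
    return BayesianNetwork(dag, cpts, state_names)


def _reorder_parent_axes(table, parents, canonical, state_names, k):
    """Re-index CPT rows from one parent order to another (both C-order,
    last parent fastest)."""
    cards = [len(state_names[p]) for p in parents]
    shaped = table.reshape(tuple(cards) + (k,))
    perm = [parents.index(p) for p in canonical]
    shaped = shaped.transpose(perm + [len(parents)])
    return shaped.reshape(-1, k)


def dag_to_json(g: DAG, path=None) -> dict:
    obj = {"nodes": list(g.nodes), "edges": [list(e) for e in g.sorted_edges()]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    return obj


def dag_from_json(source) -> DAG:
    if isinstance(source, dict):
        obj = source
    else:
        with open(source) as fh:
            obj = json.load(fh)
    return DAG(obj["nodes"], [tuple(e) for e in obj["edges"]])


# ---------------------------------------------------------------------------
# BIF reader (discrete networks only, tolerant of whitespace/comments)

_BIF_VARIABLE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*?type\s+discrete\s*\[\s*\d+\s*\]\s*\{([^}]*)\}\s*;",
    re.DOTALL,
)
_BIF_PROB = re.compile(
    r"probability\s*\(\s*(\S+)\s*(?:\|\s*([^)]*))?\)\s*\{(.*?)\}",
    re.DOTALL,
)


def read_bif(path) -> BayesianNetwork:
    """Parse a discrete-network BIF file into a BayesianNetwork.

    Supports ``table`` blocks for root nodes and per-configuration
    ``(state, ...)`` rows for conditioned nodes."""
    with open(path) as fh:
        text = fh.read()
    text = re.sub(r"//[^\n]*", "", text)
    state_names: dict[str, tuple[str, ...]] = {}
    for m in _BIF_VARIABLE.finditer(text):
        name = m.group(1)
        states = tuple(s.strip() for s in m.group(2).split(",") if s.strip())
        state_names[name] = states
    if not state_names:
        raise ValueError("no discrete variables found in BIF file")
    edges: list[tuple[str, str]] = []
    raw_cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for m in _BIF_PROB.finditer(text):
        node = m.group(1)
        parents = tuple(
            p.strip() for p in (m.group(2) or "").split(",") if p.strip()
        )
        body = m.group(3)
        k = len(state_names[node])
        if parents:
            cards = [len(state_names[p]) for p in parents]
            q = int(np.prod(cards))
            table = np.full((q, k), np.nan)
            for row in re.finditer(r"\(([^)]*)\)\s*([^;]*);", body):
                cfg_states = [s.strip() for s in row.group(1).split(",")]
                idx = np.ravel_multi_index(
                    [[state_names[p].index(s)] for p, s in zip(parents, cfg_states)],
                    cards,
                )[0]
                table[idx] = [float(v) for v in row.group(2).split(",")]
            if np.isnan(table).any():
                raise ValueError(f"incomplete CPT for node {node!r}")
        else:
            tm = re.search(r"table\s+([^;]*);", body)
            if tm is None:
                raise ValueError(f"missing table for root node {node!r}")
            table = np.asarray([[float(v) for v in tm.group(1).split(",")]])
        edges.extend((p, node) for p in parents)
        raw_cpts[node] = (parents, table)
    dag = DAG(list(state_names), edges)
    cpts: dict[str, CPT] = {}
    for node, (parents, table) in raw_cpts.items():
        canonical = dag.parents(node)
        k = len(state_names[node])
        if parents != canonical:
            table = _reorder_parent_axes(table, parents, canonical, state_names, k)
        cpts[node] = CPT(node, canonical, table, np.ones(k))
    missing = set(state_names) - set(cpts)
    if missing:
        raise ValueError(f"variables without probability blocks: {sorted(missing)}")
    return BayesianNetwork(dag, cpts, state_names)
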