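"""Directed metabolite-metabolite (MMN) and reaction-reaction (RRN) networks.

Both are simple directed graphs derived from a (context) model's active
reactions, with currency metabolites excluded throughout: they neither become
MMN nodes nor mediate RRN edges.  MMN edges run substrate -> product within a
reaction (both orientations for reversible reactions); RRN edges run producer
reaction -> consumer reaction whenever a non-currency product of one is a
substrate of the other.  Self-loops are dropped (simple graphs).

The adjacency matrix convention is A[i, j] = 1 iff there is an edge
node_j -> node_i (column = source, row = target), i.e. rows collect incoming
influence as in the standard linear dynamics x' = Ax + Bu.  Node order is
sorted node ids and is recorded on the network; driver-set extraction is
order-dependent, so exports always carry the node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import ValidationError
from .model_core import MetabolicModel

__all__ = [
    "DirectedNetwork", "build_mmn", "build_rrn", "degree_distribution",
    "network_from_edges", "export_graphml", "export_sif", "export_adjacency_mtx",
]


@dataclass
class DirectedNetwork:
    """A simple directed graph with a fixed, recorded node order."""

    node_ids: list[str]
    edges: set[tuple[str, str]]
    kind: str = "generic"  # MMN | RRN | generic
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        nodes = set(self.node_ids)
        for u, v in self.edges:
            if u not in nodes or v not in nodes:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValidationError(f"self-loop on {u!r} not allowed (simple graph)")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> np.ndarray:
        """A[target, source] 0/1 matrix in the recorded node order."""
        A = np.zeros((self.n, self.n))
        for u, v in self.edges:
            A[self._index[v], self._index[u]] = 1.0
        return A

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(sorted(self.edges))
        return g

    def total_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.node_ids}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def remove_node(self, node: str) -> "DirectedNetwork":
        if node not in self._index:
            raise ValidationError(f"unknown node {node!r}")
        return DirectedNetwork(
            node_ids=[n for n in self.node_ids if n != node],
            edges={(u, v) for u, v in self.edges if node not in (u, v)},
            kind=self.kind)


def network_from_edges(edges: Iterable[tuple[str, str]],
                       nodes: Iterable[str] = (), kind: str = "generic",
                       ) -> DirectedNetwork:
    """Build a network from an edge list; node order is sorted ids."""
    edges = {(str(u), str(v)) for u, v in edges if u != v}
    node_set = {str(n) for n in nodes}
    for u, v in edges:
        node_set.update((u, v))
    return DirectedNetwork(node_ids=sorted(node_set), edges=edges, kind=kind)


def _active_reactions(model: MetabolicModel) -> list[str]:
    """Reactions with a nonzero flux range (closed bounds = inactive)."""
    return [rid for j, rid in enumerate(model.reaction_ids)
            if not (model.lb[j] == 0 and model.ub[j] == 0)]


def _sides(model: MetabolicModel, rid: str) -> tuple[set[str], set[str]]:
    """(substrates, products) of a reaction over non-currency metabolites.

    Reversible reactions consume and produce on both sides, so both sets
    contain every participant.
    """
    j = model.reaction_index(rid)
    currency = set(model.currency_ids)
    subs, prods = set(), set()
    for i in np.where(model.S[:, j] != 0)[0]:
        met = model.metabolite_ids[i]
        if met in currency:
            continue
        s = model.S[i, j]
        if s < 0 or model.rev[j] == 1:
            subs.add(met)
        if s > 0 or model.rev[j] == 1:
            prods.add(met)
    return subs, prods


def _model_of(context) -> MetabolicModel:
    return context.model if hasattr(context, "model") else context


def build_mmn(context) -> DirectedNetwork:
    """Metabolite-metabolite network of a context (or bare model).

    Nodes are non-currency metabolites touched by at least one active
    reaction; each active reaction contributes substrate -> product edges for
    every (substrate, product) pair.  Co-substrates are not linked to each
    other.
    """
    model = _model_of(context)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for rid in _active_reactions(model):
        subs, prods = _sides(model, rid)
        nodes |= subs | prods
        for s in subs:
            for p in prods:
                if s != p:
                    edges.add((s, p))
    if not nodes:
        raise ValidationError("all participating metabolites are currency; "
                              "empty metabolite network")
    return DirectedNetwork(node_ids=sorted(nodes), edges=edges, kind="MMN")


def build_rrn(context) -> DirectedNetwork:
    """Reaction-reaction network: edge r1 -> r2 iff a non-currency product of
    r1 is a substrate of r2 (both orientations for reversible reactions)."""
    model = _model_of(context)
    active = _active_reactions(model)
    if not active:
        raise ValidationError("context has no active reactions")
    sides = {rid: _sides(model, rid) for rid in active}
    edges = {(r1, r2)
             for r1 in active for r2 in active if r1 != r2
             if sides[r1][1] & sides[r2][0]}
    return DirectedNetwork(node_ids=sorted(active), edges=edges, kind="RRN")


def degree_distribution(net: DirectedNetwork, seed: int = 0,
                        ) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Cumulative total-degree distribution plus an Erdos-Renyi reference.

    Returns two (k, P(degree >= k)) tables: one for the network, one for a
    seeded G(n, p) digraph with the same node count and expected edge count.
    """
    if net.n == 0:
        raise ValidationError("empty network")
    degrees = list(net.total_degree().values())

    def table(degs: list[int]) -> list[tuple[int, float]]:
        n = len(degs)
        kmax = max(degs) if degs else 0
        return [(k, sum(d >= k for d in degs) / n) for k in range(1, kmax + 1)]

    p = len(net.edges) / (net.n * (net.n - 1)) if net.n > 1 else 0.0
    er = nx.gnp_random_graph(net.n, p, seed=seed, directed=True)
    er_degs = [d for _, d in er.degree()]
    return table(degrees), table(er_degs)


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def export_graphml(net: DirectedNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def export_sif(net: DirectedNetwork, path: str | Path,
               relation: str = "directs") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")


def export_adjacency_mtx(net: DirectedNetwork, mtx_path: str | Path,
                         order_path: str | Path) -> None:
    """Adjacency (A[target, source]) as Matrix Market + node-order sidecar TSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(net.adjacency()))
    with open(order_path, "w") as fh:
        fh.write("index\tnode_id\n")
        for i, node in enumerate(net.node_ids):
            fh.write(f"{i}\t{node}\n")
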