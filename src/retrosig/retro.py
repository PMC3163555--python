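"""Directed-hypergraph retrosynthesis: exhaustive pathway enumeration.

A metabolic network maps onto a directed hypergraph whose hyperedges
connect substrate sets to product sets; reversible reactions contribute two
directed hyperedges.  Starting from a target compound, reactions are
applied backwards until every open substrate is either a chassis
metabolite or a currency cofactor.  Optimal-hyperpath search is NP-hard in
general, so the strategy here is full bounded enumeration followed by
ranking: every minimal valid pathway of at most ``max_depth`` reactions is
returned exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .config import RunConfig
from .network import MetabolicNetwork, enumerate_emrs

logger = logging.getLogger(__name__)

__all__ = [
    "HyperEdge",
    "Hypergraph",
    "Pathway",
    "build_hypergraph",
    "is_valid_pathway",
    "enumerate_pathways",
    "length_distribution",
    "complexity_curve",
]


@dataclass(frozen=True)
class HyperEdge:
    id: str
    reaction_id: str
    tail: FrozenSet[str]   # substrates consumed
    head: FrozenSet[str]   # products formed

    def __post_init__(self):
        if not self.tail or not self.head:
            raise ValueError(f"hyperedge {self.id}: empty tail or head")


class Hypergraph:
    def __init__(self, nodes: Iterable[str], edges: Iterable[HyperEdge]):
        self.nodes: Set[str] = set(nodes)
        self.edges: Dict[str, HyperEdge] = {}
        self.producers: Dict[str, List[str]] = {n: [] for n in self.nodes}
        for e in edges:
            if not (e.tail <= self.nodes and e.head <= self.nodes):
                raise ValueError(f"hyperedge {e.id} references unknown nodes")
            self.edges[e.id] = e
            for c in e.head:
                self.producers[c].append(e.id)
        for lst in self.producers.values():
            lst.sort()


def build_hypergraph(net: MetabolicNetwork) -> Hypergraph:
    """Expand each reaction to directed hyperedges (two if reversible)."""
    edges = []
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        tail = frozenset(c for _, c in r.substrates)
        head = frozenset(c for _, c in r.products)
        edges.append(HyperEdge(f"{rid}>", rid, tail, head))
        if r.direction == "reversible":
            edges.append(HyperEdge(f"{rid}<", rid, head, tail))
    return Hypergraph(net.compounds.keys(), edges)


@dataclass
class Pathway:
    """An ordered reaction list linking chassis precursors to a target."""

    target: str
    reactions: List[str] = field(default_factory=list)  # hyperedge ids, discovery order
    precursors: Set[str] = field(default_factory=set)   # chassis compounds consumed
    intermediates: Set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.reactions)

    def key(self) -> FrozenSet[str]:
        return frozenset(self.reactions)


def _dependency_order(
    g: Hypergraph, edge_ids: Sequence[str], satisfied: Set[str]
) -> Optional[List[str]]:
    """Topological order where each edge fires only on available compounds."""
    remaining = list(edge_ids)
    have = set(satisfied)
    order: List[str] = []
    while remaining:
        progressed = False
        for eid in sorted(remaining):
            if g.edges[eid].tail <= have:
                order.append(eid)
                have |= g.edges[eid].head
                remaining.remove(eid)
                progressed = True
                break
        if not progressed:
            return None
    return order


def _feasible(
    g: Hypergraph, edge_ids: Set[str], target: str, base: Set[str]
) -> bool:
    """Target produced, all substrates satisfied, acyclic firing order."""
    if not edge_ids:
        return target in base
    heads: Set[str] = set()
    for eid in edge_ids:
        heads |= g.edges[eid].head
    if target not in heads:
        return False
    for eid in edge_ids:
        if not g.edges[eid].tail <= base | heads:
            return False
    return _dependency_order(g, sorted(edge_ids), base) is not None


def is_valid_pathway(
    g: Hypergraph,
    edge_ids: Iterable[str],
    target: str,
    chassis: Set[str],
    currency: Set[str],
) -> bool:
    """Pathway validity predicate over a set of directed hyperedges.

    Valid means: the target is produced; every substrate of every edge is
    a chassis metabolite, a currency metabolite, or produced by another
    edge of the set; the dependency relation admits an acyclic firing
    order; and the set is minimal — removing any single edge breaks one
    of the above.  The empty set is valid only for endogenous targets.
    """
    edge_ids = set(edge_ids)
    base = chassis | currency
    if not _feasible(g, edge_ids, target, base):
        return False
    # the empty set is not a witness against a one-edge route: an
    # endogenous target keeps its native (empty) pathway AND any
    # non-empty alternatives
    return not any(
        len(edge_ids) > 1 and _feasible(g, edge_ids - {eid}, target, base)
        for eid in edge_ids
    )


def _make_pathway(
    g: Hypergraph, edges: Sequence[str], target: str, chassis: Set[str], currency: Set[str]
) -> Pathway:
    order = _dependency_order(g, edges, chassis | currency) or list(edges)
    consumed: Set[str] = set()
    produced: Set[str] = set()
    for eid in order:
        consumed |= g.edges[eid].tail
        produced |= g.edges[eid].head
    return Pathway(
        target=target,
        reactions=list(reversed(order)),  # backward discovery order
        precursors=consumed & chassis,
        intermediates=(produced | consumed) - chassis - currency - {target},
    )


def enumerate_pathways(
    g: Hypergraph,
    target: str,
    chassis: Iterable[str],
    currency: Iterable[str] = (),
    max_depth: int = 10,
    max_pathways: int = 10_000,
) -> List[Pathway]:
    """All minimal pathways producing ``target``, up to the stated bounds.

    Results are deterministic, ordered by length then lexicographic
    hyperedge ids, and unique by reaction set.  An endogenous target
    yields the empty pathway first, followed by any non-empty
    alternatives.  Backward expansion never recurses into currency
    metabolites, and a compound may not be a subtarget of its own
    derivation chain.
    """
    if target not in g.nodes:
        raise ValueError(f"target {target!r} not in hypergraph")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    chassis = set(chassis)
    currency = set(currency)
    base = chassis | currency
    found: Dict[FrozenSet[str], List[str]] = {}

    if target in base:
        logger.warning("target %s is endogenous; native (empty) pathway included", target)
        found[frozenset()] = []

    def expand(open_compounds: FrozenSet[str], chosen: FrozenSet[str]):
        """AND/OR backward search: each open compound is satisfied either
        by a producer already chosen (possibly a byproduct) or by
        branching over new producing hyperedges."""
        if len(found) > max_pathways:
            return
        if not open_compounds:
            if chosen and chosen not in found:
                if is_valid_pathway(g, chosen, target, chassis, currency):
                    found[chosen] = sorted(chosen)
            return
        c = min(open_compounds)
        rest = open_compounds - {c}
        if any(c in g.edges[eid].head for eid in chosen):
            expand(rest, chosen)
        for eid in g.producers.get(c, []):
            edge = g.edges[eid]
            if eid in chosen or len(chosen) >= max_depth:
                continue
            if c in edge.tail:
                continue  # a compound may not derive from itself
            expand(frozenset(rest | (edge.tail - base)), chosen | {eid})

    expand(frozenset({target}) if target not in base else frozenset(), frozenset())
    # non-empty alternatives to an endogenous target
    if target in base:
        expand(frozenset({target}), frozenset())

    if len(found) > max_pathways:
        logger.warning("pathway cap %d reached; output truncated", max_pathways)
    pathways = [
        _make_pathway(g, edges, target, chassis, currency) for edges in found
    ]
    pathways.sort(key=lambda p: (len(p), tuple(sorted(p.reactions))))
    return pathways[:max_pathways]


def length_distribution(pathways: Sequence[Pathway]) -> Dict[int, int]:
    """Histogram of pathway lengths (number of reactions)."""
    out: Dict[int, int] = {}
    for p in pathways:
        out[len(p)] = out.get(len(p), 0) + 1
    return out


def complexity_curve(
    net: MetabolicNetwork,
    target: str,
    chassis: Iterable[str],
    heights: Sequence[int],
    max_depth: int = 10,
    currency: Iterable[str] = (),
    config: Optional[RunConfig] = None,
):
    """(height, EMRS size, pathway count) rows: complexity versus height."""
    import pandas as pd

    rows = []
    for h in heights:
        emrs = enumerate_emrs(net, h, config)
        g = build_hypergraph(emrs)
        n = len(enumerate_pathways(g, target, chassis, currency, max_depth=max_depth))
        rows.append({"height": h, "emrs_size": len(emrs.reactions), "pathways": n})
    return pd.DataFrame(rows, columns=["height", "emrs_size", "pathways"])
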