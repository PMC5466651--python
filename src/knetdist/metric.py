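"""The kth-distance between two rooted phylogenetic networks.

For each order ``i`` in ``1..k`` the joint equivalence classes of the two
networks' disjoint union yield, per network, unique representatives and class
sizes; the order-``i`` discordance is the sum over both networks of
``max(0, e_i(v) - e_i(v'))`` where ``v'`` is the representative of the same
joint class on the other side (class size 0 if none).  The distance is the
total discordance normalized by ``k * (n1 + n2)``; it is kept as an exact
rational.

``brute_force_isomorphic`` is an independent oracle (VF2 backtracking over
the labelled DAGs) used to validate the distance's reflexivity on the reduced
space.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import networkx as nx
from networkx.algorithms.isomorphism import DiGraphMatcher

from .equivalence import equivalence_chain
from .errors import SizeError
from .network import PhyloNetwork, Tagged, disjoint_union

__all__ = [
    "ClassTable",
    "DistanceBreakdown",
    "class_tables",
    "kth_distance",
    "brute_force_isomorphic",
]


@dataclass(frozen=True)
class ClassTable:
    """Per-order unique representatives, class sizes, and the cross pairing."""

    order: int
    L1: tuple[Tagged, ...]
    L2: tuple[Tagged, ...]
    e1: Mapping[Tagged, int]
    e2: Mapping[Tagged, int]
    pairing: Mapping[Tagged, Tagged | None]

    def discordance(self) -> int:
        """The bracketed per-order sum of the distance formula."""
        total = 0
        for v in self.L1:
            mate = self.pairing[v]
            total += max(0, self.e1[v] - (self.e2[mate] if mate else 0))
        for u in self.L2:
            mate = self.pairing[u]
            total += max(0, self.e2[u] - (self.e1[mate] if mate else 0))
        return total


@dataclass(frozen=True)
class DistanceBreakdown:
    """The kth-distance with its per-order discordance sums."""

    k: int
    n1: int
    n2: int
    per_order_sum: Mapping[int, int]
    distance: Fraction

    @property
    def distance_float(self) -> float:
        return float(self.distance)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n1": self.n1,
            "n2": self.n2,
            "per_order_sum": {str(i): s for i, s in sorted(self.per_order_sum.items())},
            "distance_rational": [
                self.distance.numerator,
                self.distance.denominator,
            ],
            "distance_float": self.distance_float,
        }


def class_tables(n1: PhyloNetwork, n2: PhyloNetwork, k: int) -> list[ClassTable]:
    """One :class:`ClassTable` per order ``1..k`` over the joint universe.

    Representatives are the least node (in the deterministic universe order)
    of each joint class restricted to one network; the pairing links the two
    representatives of a class that spans both networks.  By the transfer
    property of the equivalence relations the pairing is at most one-to-one.
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    universe = disjoint_union(n1, n2)
    chain = equivalence_chain(universe, k)
    tables = []
    for partition in chain:
        reps: dict[tuple[int, int], Tagged] = {}
        sizes: dict[tuple[int, int], int] = {}
        for node in universe.nodes:  # deterministic: sorted within origin
            key = (node[0], partition.class_of[node])
            reps.setdefault(key, node)
            sizes[key] = sizes.get(key, 0) + 1
        L1 = tuple(rep for (origin, _), rep in sorted(reps.items()) if origin == 0)
        L2 = tuple(rep for (origin, _), rep in sorted(reps.items()) if origin == 1)
        e1 = {rep: sizes[(0, partition.class_of[rep])] for rep in L1}
        e2 = {rep: sizes[(1, partition.class_of[rep])] for rep in L2}
        pairing: dict[Tagged, Tagged | None] = {}
        for rep in L1:
            pairing[rep] = reps.get((1, partition.class_of[rep]))
        for rep in L2:
            pairing[rep] = reps.get((0, partition.class_of[rep]))
        tables.append(ClassTable(partition.order, L1, L2, e1, e2, pairing))
    return tables


def kth_distance(n1: PhyloNetwork, n2: PhyloNetwork, k: int) -> DistanceBreakdown:
    """The kth-distance between two validated networks (exact rational).

    The networks need not be reduced; the value is defined for any pair, but
    the metric axioms are only guaranteed on the order-``k`` reduced space.
    """
    tables = class_tables(n1, n2, k)
    sums = {t.order: t.discordance() for t in tables}
    total = sum(sums.values())
    distance = Fraction(total, k * (len(n1) + len(n2)))
    return DistanceBreakdown(k, len(n1), len(n2), sums, distance)


_ISO_BOUND = 16


def brute_force_isomorphic(
    n1: PhyloNetwork, n2: PhyloNetwork, *, max_nodes: int = _ISO_BOUND
) -> bool:
    """Label-preserving digraph isomorphism by backtracking search.

    Delegates the search to networkx's VF2 matcher with a node invariant that
    separates leaves by taxon label, keeping this oracle independent of the
    equivalence machinery it is used to validate.
    """
    if max(len(n1), len(n2)) > max_nodes:
        raise SizeError(
            f"isomorphism oracle limited to {max_nodes} nodes, "
            f"got {len(n1)} and {len(n2)}"
        )
    if len(n1) != len(n2) or len(n1.edges) != len(n2.edges):
        return False
    if n1.taxa != n2.taxa:
        return False

    def graph(net: PhyloNetwork) -> nx.DiGraph:
        g = net.to_digraph()
        for v in g:
            g.nodes[v]["taxon"] = net.leaf_labels.get(v)
        return g

    matcher = DiGraphMatcher(
        graph(n1),
        graph(n2),
        node_match=lambda a, b: a["taxon"] == b["taxon"],
    )
    return matcher.is_isomorphic()
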