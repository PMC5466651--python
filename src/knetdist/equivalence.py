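"""kth-order node equivalence over one network or a two-network universe.

Two independent routes are provided:

* a partition-refinement implementation (:func:`partition_order1`,
  :func:`refine_step`, :func:`equivalence_chain`) that computes each order as
  a signature-refinement pass over the whole universe, and
* :func:`naive_equivalent`, a memoized per-pair recursion that follows the
  defining clauses literally (degree check, leaf/root base cases, exhaustive
  bipartite matching of children or parents).  It is exponential in the worst
  case and serves as the test oracle for the fast route.

Orders alternate direction: order 1 and odd orders look at children (bottom-up
by height), even orders look at parents (top-down by depth).  Both recursions
are well-founded because heights strictly decrease along edges and depths
strictly increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

from .errors import SizeError
from .network import Tagged, Universe

__all__ = [
    "OrderedPartition",
    "partition_order1",
    "refine_step",
    "equivalence_chain",
    "naive_equivalent",
    "partition_to_tsv",
]


@dataclass(frozen=True)
class OrderedPartition:
    """The order-``k`` equivalence relation as a node -> class assignment."""

    order: int
    class_of: Mapping[Tagged, int]
    scope: str

    def classes(self) -> dict[int, tuple[Tagged, ...]]:
        out: dict[int, list[Tagged]] = {}
        for node, cid in self.class_of.items():
            out.setdefault(cid, []).append(node)
        return {cid: tuple(sorted(members)) for cid, members in out.items()}

    def same_class(self, u: Tagged, v: Tagged) -> bool:
        return self.class_of[u] == self.class_of[v]

    def is_discrete(self) -> bool:
        return len(set(self.class_of.values())) == len(self.class_of)


def _assign(signatures: dict[Tagged, object]) -> dict[Tagged, int]:
    """Map equal signatures to equal class ids, deterministically."""
    ids: dict[object, int] = {}
    class_of: dict[Tagged, int] = {}
    for node in sorted(signatures):
        sig = signatures[node]
        if sig not in ids:
            ids[sig] = len(ids)
        class_of[node] = ids[sig]
    return class_of


def partition_order1(universe: Universe) -> OrderedPartition:
    """First-order equivalence: leaves by taxon label, internal nodes by the
    multiset of their children's first-order classes, bottom-up by height."""
    class_of: dict[Tagged, int] = {}
    sig_ids: dict[object, int] = {}
    by_height: dict[int, list[Tagged]] = {}
    for v in universe.nodes:
        by_height.setdefault(universe.height[v], []).append(v)
    for h in sorted(by_height):
        sigs: dict[Tagged, object] = {}
        for v in by_height[h]:
            if not universe.children[v]:
                sigs[v] = ("leaf", universe.leaf_label[v])
            else:
                kids = tuple(sorted(class_of[c] for c in universe.children[v]))
                sigs[v] = ("internal", kids)
        for v in sorted(sigs):
            sig = sigs[v]
            if sig not in sig_ids:
                sig_ids[sig] = len(sig_ids)
            class_of[v] = sig_ids[sig]
    return OrderedPartition(1, class_of, universe.scope)


def refine_step(prev: OrderedPartition, universe: Universe) -> OrderedPartition:
    """Refine an order-``k-1`` partition into the order-``k`` one.

    Even ``k``: top-down by depth; a node's signature is its previous class
    plus the multiset of its parents' order-``k`` classes (roots pair with
    roots).  Odd ``k``: bottom-up by height; previous class plus leaf label or
    the multiset of the children's order-``k`` classes.
    """
    k = prev.order + 1
    class_of: dict[Tagged, int] = {}
    sig_ids: dict[object, int] = {}
    if k % 2 == 0:
        levels: dict[int, list[Tagged]] = {}
        for v in universe.nodes:
            levels.setdefault(universe.depth[v], []).append(v)
        neighbours = universe.parents
        base = lambda v: "root" if v in universe.roots else None
    else:
        levels = {}
        for v in universe.nodes:
            levels.setdefault(universe.height[v], []).append(v)
        neighbours = universe.children
        base = lambda v: (
            ("leaf", universe.leaf_label[v]) if not universe.children[v] else None
        )
    for level in sorted(levels):
        sigs: dict[Tagged, object] = {}
        for v in levels[level]:
            b = base(v)
            if b is not None:
                sigs[v] = (prev.class_of[v], b)
            else:
                near = tuple(sorted(class_of[n] for n in neighbours[v]))
                sigs[v] = (prev.class_of[v], near)
        for v in sorted(sigs):
            sig = sigs[v]
            if sig not in sig_ids:
                sig_ids[sig] = len(sig_ids)
            class_of[v] = sig_ids[sig]
    return OrderedPartition(k, class_of, universe.scope)


def equivalence_chain(universe: Universe, k: int) -> list[OrderedPartition]:
    """The partitions of orders ``1..k``.

    Once a partition is discrete the remaining orders are copies of it:
    refinement cannot coarsen, so a discrete partition is a fixpoint.
    """
    if k < 1:
        raise ValueError("the equivalence chain starts at order 1")
    chain = [partition_order1(universe)]
    while len(chain) < k:
        prev = chain[-1]
        if prev.is_discrete():
            chain.append(OrderedPartition(prev.order + 1, prev.class_of, prev.scope))
        else:
            chain.append(refine_step(prev, universe))
    return chain


# ---------------------------------------------------------------------------
# naive oracle
# ---------------------------------------------------------------------------

_ORACLE_BOUND = 16


def naive_equivalent(
    u: Tagged,
    v: Tagged,
    k: int,
    universe: Universe,
    *,
    max_nodes: int = _ORACLE_BOUND,
    _memo: dict | None = None,
) -> bool:
    """Direct memoized recursion on the defining clauses of order-``k`` equivalence.

    Exhaustively searches for a bijection between children (odd orders) or
    parents (even orders) such that matched nodes are equivalent at the same
    order.  Exponential worst case; guarded by ``max_nodes`` per network.
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    for net in universe.networks:
        if len(net) > max_nodes:
            raise SizeError(
                f"naive oracle limited to {max_nodes} nodes per network, got {len(net)}"
            )
    memo: dict = {} if _memo is None else _memo

    def matchable(xs: tuple[Tagged, ...], ys: tuple[Tagged, ...], order: int) -> bool:
        if len(xs) != len(ys):
            return False
        for perm in permutations(ys):
            if all(eq(a, b, order) for a, b in zip(xs, perm)):
                return True
        return False

    def eq(a: Tagged, b: Tagged, order: int) -> bool:
        key = (a, b, order) if a <= b else (b, a, order)
        if key in memo:
            return memo[key]
        memo[key] = False  # cycle guard; recursion is well-founded anyway
        a_leaf = not universe.children[a]
        b_leaf = not universe.children[b]
        if order == 1:
            if a_leaf or b_leaf:
                res = (
                    a_leaf
                    and b_leaf
                    and universe.leaf_label[a] == universe.leaf_label[b]
                )
            else:
                res = matchable(universe.children[a], universe.children[b], 1)
        elif order % 2 == 0:
            if not eq(a, b, order - 1):
                res = False
            elif a in universe.roots or b in universe.roots:
                res = a in universe.roots and b in universe.roots
            else:
                res = matchable(universe.parents[a], universe.parents[b], order)
        else:
            if not eq(a, b, order - 1):
                res = False
            elif a_leaf or b_leaf:
                res = (
                    a_leaf
                    and b_leaf
                    and universe.leaf_label[a] == universe.leaf_label[b]
                )
            else:
                res = matchable(universe.children[a], universe.children[b], order)
        memo[key] = res
        return res

    return eq(u, v, k)


def partition_to_tsv(chain: list[OrderedPartition]) -> str:
    """Debug export: one row per node with its class id at every order."""
    orders = [p.order for p in chain]
    header = "node_id\torigin\t" + "\t".join(f"class_k{o}" for o in orders)
    rows = [header]
    for node in sorted(chain[0].class_of):
        origin, nid = node
        cells = [str(p.class_of[node]) for p in chain]
        rows.append(f"{nid}\t{origin}\t" + "\t".join(cells))
    return "\n".join(rows) + "\n"
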