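"""Membership in, and projection onto, the space of kth-order reduced networks.

A network is order-``k`` reduced when every node is order-``k`` equivalent
only with itself and no node has in-degree 1 and out-degree 1.  ``reduce``
iterates merge-equivalents / suppress-unary passes to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .equivalence import equivalence_chain
from .errors import ReductionDiverged
from .network import PhyloNetwork, compute_index, disjoint_union, validate_network

__all__ = ["ReductionReport", "is_kth_order_reduced", "suppress_unary", "reduce"]


@dataclass
class ReductionReport:
    """Audit trail of one reduction run."""

    input_size: int
    output: PhyloNetwork
    merged_classes: list[list[frozenset[str]]] = field(default_factory=list)
    suppressed: list[list[str]] = field(default_factory=list)
    passes: int = 0

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "output_size": len(self.output),
            "passes": self.passes,
            "merged_classes": [
                [sorted(c) for c in step] for step in self.merged_classes
            ],
            "suppressed": self.suppressed,
        }


def _has_unary(net: PhyloNetwork) -> bool:
    idx = compute_index(net)
    return any(
        len(idx.parents[v]) == 1 and len(idx.children[v]) == 1 for v in net.node_ids
    )


def is_kth_order_reduced(net: PhyloNetwork, k: int) -> bool:
    """True iff the order-``k`` partition of ``net`` is discrete and no node
    has in-degree 1 and out-degree 1."""
    if k < 1:
        raise ValueError("order must be >= 1")
    chain = equivalence_chain(disjoint_union(net), k)
    return chain[-1].is_discrete() and not _has_unary(net)


def suppress_unary(net: PhyloNetwork) -> PhyloNetwork:
    """Remove every in-degree-1/out-degree-1 node, joining its parent to its
    child, until none remain.  Duplicate edges created by a contraction are
    collapsed (the edge set stays a set)."""
    nodes = set(net.node_ids)
    edges = set(net.edges)
    labels = dict(net.leaf_labels)
    while True:
        parents: dict[str, list[str]] = {v: [] for v in nodes}
        children: dict[str, list[str]] = {v: [] for v in nodes}
        for u, v in edges:
            children[u].append(v)
            parents[v].append(u)
        unary = [
            v for v in nodes if len(parents[v]) == 1 and len(children[v]) == 1
        ]
        if not unary:
            break
        v = min(unary)
        (p,) = parents[v]
        (c,) = children[v]
        nodes.remove(v)
        edges.discard((p, v))
        edges.discard((v, c))
        edges.add((p, c))
    return validate_network(nodes, edges, labels, net.name)


def reduce(net: PhyloNetwork, k: int, max_passes: int | None = None) -> ReductionReport:
    """Project ``net`` into the space of order-``k`` reduced networks.

    Each pass: (1) compute the order-``k`` partition; (2) collapse every
    non-singleton class onto its lexicographically least member, redirecting
    incident edges (duplicates dropped); (3) suppress unary nodes.  Repeats
    until :func:`is_kth_order_reduced` holds.  Node count strictly shrinks
    each pass, so the defensive ``max_passes`` bound (default ``|V|``) can
    only trip on a logic error.
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    report = ReductionReport(input_size=len(net), output=net)
    budget = max_passes if max_passes is not None else max(1, len(net))
    current = net
    while True:
        report.passes += 1
        if report.passes > budget:
            raise ReductionDiverged(f"reduction exceeded {budget} passes")
        partition = equivalence_chain(disjoint_union(current), k)[-1]
        merged: list[frozenset[str]] = []
        target: dict[str, str] = {}
        for members in partition.classes().values():
            ids = sorted(v for _, v in members)
            if len(ids) > 1:
                merged.append(frozenset(ids))
                rep = ids[0]
                for other in ids:
                    target[other] = rep
        if merged:
            nodes = {target.get(v, v) for v in current.node_ids}
            edges = {
                (target.get(u, u), target.get(v, v)) for u, v in current.edges
            }
            labels = {
                target.get(v, v): lab for v, lab in current.leaf_labels.items()
            }
            current = validate_network(nodes, edges, labels, current.name)
        report.merged_classes.append(sorted(merged, key=sorted))

        before = set(current.node_ids)
        current = suppress_unary(current)
        report.suppressed.append(sorted(before - set(current.node_ids)))

        if not merged and not report.suppressed[-1]:
            break
    report.output = current
    return report
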