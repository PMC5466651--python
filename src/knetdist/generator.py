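"""Seeded random network generation for property testing.

Stands in for external network constructors: a random rooted binary tree is
decorated with randomly placed reticulation edges.  Same config, same
network, bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import GenerationError
from .network import PhyloNetwork, compute_index, validate_network

__all__ = ["GeneratorConfig", "random_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one reproducible draw.

    ``max_extra_depth`` (when positive) caps ``depth(child) - depth(parent)``
    of added reticulation edges, keeping reticulations local; 0 means
    unconstrained.
    """

    n_leaves: int
    n_reticulations: int = 0
    seed: int = 0
    max_extra_depth: int = 0


def random_network(cfg: GeneratorConfig) -> PhyloNetwork:
    """Draw a validated network: random binary tree plus acyclic cross edges.

    Cross edges (u, v) are chosen uniformly among internal-node pairs with
    ``depth(u) < depth(v)`` (which already guarantees acyclicity) that are not
    yet edges and keep v a non-root.  Raises :class:`GenerationError` when no
    legal edge remains for the requested reticulation count.
    """
    if cfg.n_leaves < 1:
        raise GenerationError("n_leaves must be >= 1")
    if cfg.n_reticulations < 0:
        raise GenerationError("n_reticulations must be >= 0")
    rng = random.Random(cfg.seed)

    leaves = [f"L{i}" for i in range(1, cfg.n_leaves + 1)]
    labels = {f"L{i}": str(i) for i in range(1, cfg.n_leaves + 1)}
    nodes = list(leaves)
    edges: list[tuple[str, str]] = []
    subroots = list(leaves)
    counter = 0
    while len(subroots) > 1:
        counter += 1
        a, b = rng.sample(range(len(subroots)), 2)
        u, v = subroots[a], subroots[b]
        parent = f"I{counter}"
        nodes.append(parent)
        edges.append((parent, u))
        edges.append((parent, v))
        subroots = [s for s in subroots if s not in (u, v)] + [parent]

    net = validate_network(nodes, edges, labels)
    for _ in range(cfg.n_reticulations):
        idx = compute_index(net)
        root = net.root
        edge_set = set(net.edges)
        candidates = sorted(
            (u, v)
            for u in net.node_ids
            if idx.children[u]  # the new parent must stay an internal node
            for v in net.node_ids
            if v != root
            and v != u
            and idx.depth[u] < idx.depth[v]
            and (u, v) not in edge_set
            and (
                cfg.max_extra_depth <= 0
                or idx.depth[v] - idx.depth[u] <= cfg.max_extra_depth
            )
        )
        if not candidates:
            raise GenerationError(
                f"no legal reticulation edge available (requested "
                f"{cfg.n_reticulations}, placed {len(net.edges) - len(edges)})"
            )
        u, v = rng.choice(candidates)
        net = validate_network(
            net.node_ids, set(net.edges) | {(u, v)}, net.leaf_labels
        )
    return PhyloNetwork(
        net.node_ids,
        net.edges,
        net.leaf_labels,
        name=f"rand_l{cfg.n_leaves}_r{cfg.n_reticulations}_s{cfg.seed}",
    )
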