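"""Shared helpers and fixtures for the knetdist test suite."""

from __future__ import annotations

import pytest

from knetdist import (
    GeneratorConfig,
    PhyloNetwork,
    load_fixture,
    random_network,
    validate_network,
)


def net(edges, labels, name=None) -> PhyloNetwork:
    """Build a validated network from an edge list and a leaf-label map."""
    nodes = {x for e in edges for x in e} | set(labels)
    return validate_network(nodes, edges, labels, name)


def renamed(network: PhyloNetwork, tag: str = "z") -> PhyloNetwork:
    """A node-renamed copy (same structure, opaque fresh ids)."""
    m = {v: f"{tag}{i}" for i, v in enumerate(sorted(network.node_ids))}
    return validate_network(
        [m[v] for v in network.node_ids],
        [(m[u], m[v]) for u, v in network.edges],
        {m[v]: lab for v, lab in network.leaf_labels.items()},
    )


def draw(seed: int, leaves: int | None = None, retics: int | None = None) -> PhyloNetwork:
    """A seeded random network with a feasible, seed-derived configuration."""
    cfg = GeneratorConfig(
        n_leaves=leaves if leaves is not None else 3 + seed % 5,
        n_reticulations=retics if retics is not None else seed % 3,
        seed=seed,
    )
    return random_network(cfg)


@pytest.fixture(scope="session")
def figures():
    return {name: load_fixture(name) for name in (
        "fig1_n1", "fig1_n2", "fig2_n1", "fig2_n2", "fig3_n1", "fig3_n2", "fig7_n",
    )}


@pytest.fixture
def cherry():
    return net([("r", "a"), ("r", "b")], {"a": "1", "b": "2"})


@pytest.fixture
def chain3():
    # root -> mid -> leaf; mid is unary
    return net([("r", "m"), ("m", "x")], {"x": "1"})
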