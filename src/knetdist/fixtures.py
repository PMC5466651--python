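"""Transcribed figure networks with self-verifying documented facts.

Each fixture is stored as a version-controlled edge list; ``load_fixture``
re-evaluates every documented fact against the transcription and raises
:class:`FixtureIntegrityError` if any fails, so the transcriptions are pinned
by checkable structure rather than by trust.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable

from .equivalence import equivalence_chain
from .errors import FixtureIntegrityError
from .metric import brute_force_isomorphic, class_tables
from .network import PhyloNetwork, disjoint_union, parse_edgelist
from .reduction import is_kth_order_reduced

__all__ = ["NetworkFixture", "FIXTURE_NAMES", "load_fixture"]

FIXTURE_NAMES = (
    "fig1_n1",
    "fig1_n2",
    "fig2_n1",
    "fig2_n2",
    "fig3_n1",
    "fig3_n2",
    "fig7_n",
)

_PARTNER = {
    "fig1_n1": "fig1_n2",
    "fig1_n2": "fig1_n1",
    "fig2_n1": "fig2_n2",
    "fig2_n2": "fig2_n1",
    "fig3_n1": "fig3_n2",
    "fig3_n2": "fig3_n1",
}


@dataclass(frozen=True)
class NetworkFixture:
    name: str
    network: PhyloNetwork
    documented_facts: tuple[str, ...]


def _read(name: str) -> PhyloNetwork:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    text = (
        resources.files("knetdist.data").joinpath(f"{name}.edges").read_text("utf-8")
    )
    return parse_edgelist(text, name=name)


def _same_order_class(net: PhyloNetwork, k: int, u: str, v: str) -> bool:
    chain = equivalence_chain(disjoint_union(net), k)
    return chain[-1].same_class((0, u), (0, v))


def _unpaired_order1(n1: PhyloNetwork, n2: PhyloNetwork) -> tuple[set[str], set[str]]:
    table = class_tables(n1, n2, 1)[0]
    u1 = {v for (_, v) in table.L1 if table.pairing[(0, v)] is None}
    u2 = {v for (_, v) in table.L2 if table.pairing[(1, v)] is None}
    return u1, u2


def _facts(name: str) -> list[tuple[str, Callable[[PhyloNetwork], bool]]]:
    if name in ("fig1_n1", "fig1_n2"):
        return [
            ("C and E are first-order equivalent",
             lambda n: _same_order_class(n, 1, "C", "E")),
            ("D and F are first-order equivalent",
             lambda n: _same_order_class(n, 1, "D", "F")),
            ("H and J are first-order equivalent",
             lambda n: _same_order_class(n, 1, "H", "J")),
            ("H and J are second-order equivalent",
             lambda n: _same_order_class(n, 2, "H", "J")),
            ("no other non-trivial first-order class",
             lambda n: sorted(
                 tuple(v for _, v in c)
                 for c in equivalence_chain(disjoint_union(n), 1)[-1].classes().values()
                 if len(c) > 1
             ) == [("C", "E"), ("D", "F"), ("H", "J")]),
            ("every third-order class is a singleton",
             lambda n: equivalence_chain(disjoint_union(n), 3)[-1].is_discrete()),
            ("third-order reduced",
             lambda n: is_kth_order_reduced(n, 3)),
            ("the pair is not isomorphic",
             lambda n: not brute_force_isomorphic(n, _read(_PARTNER[name]))),
        ]
    if name == "fig2_n1":
        return [
            ("13 nodes", lambda n: len(n) == 13),
            ("taxa {1..6}", lambda n: n.taxa == frozenset("123456")),
            ("order-1 nodes unpaired against fig2_n2 are exactly {R,B,F}",
             lambda n: _unpaired_order1(n, _read("fig2_n2"))[0] == {"R", "B", "F"}),
        ]
    if name == "fig2_n2":
        return [
            ("15 nodes", lambda n: len(n) == 15),
            ("taxa {1..6}", lambda n: n.taxa == frozenset("123456")),
            ("order-1 nodes unpaired against fig2_n1 are exactly {R,B,E,F,K}",
             lambda n: _unpaired_order1(_read("fig2_n1"), n)[1]
             == {"R", "B", "E", "F", "K"}),
            ("the pair is not isomorphic",
             lambda n: not brute_force_isomorphic(n, _read("fig2_n1"))),
        ]
    if name == "fig3_n1":
        return [
            ("13 nodes", lambda n: len(n) == 13),
            ("taxa {1..5}", lambda n: n.taxa == frozenset("12345")),
            ("order-1 nodes unpaired against fig3_n2 are exactly {R,B,F}",
             lambda n: _unpaired_order1(n, _read("fig3_n2"))[0] == {"R", "B", "F"}),
        ]
    if name == "fig3_n2":
        return [
            ("15 nodes", lambda n: len(n) == 15),
            ("taxa {1..6}", lambda n: n.taxa == frozenset("123456")),
            ("order-1 nodes unpaired against fig3_n1 are exactly {R,B,F,H,6}",
             lambda n: _unpaired_order1(_read("fig3_n1"), n)[1]
             == {"R", "B", "F", "H", "6"}),
        ]
    if name == "fig7_n":
        return [
            ("A and B are kth-order equivalent for k = 1..6",
             lambda n: all(_same_order_class(n, k, "A", "B") for k in range(1, 7))),
            ("not kth-order reduced for k = 1..4",
             lambda n: not any(is_kth_order_reduced(n, k) for k in range(1, 5))),
        ]
    raise KeyError(name)


def load_fixture(name: str) -> NetworkFixture:
    """Load a transcribed figure network and verify all its documented facts."""
    net = _read(name)
    descriptions = []
    for description, predicate in _facts(name):
        if not predicate(net):
            raise FixtureIntegrityError(f"{name}: fact failed: {description}")
        descriptions.append(description)
    return NetworkFixture(name, net, tuple(descriptions))
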