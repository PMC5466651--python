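"""Data model, validation, I/O and structural indices for rooted phylogenetic networks.

A network is a single-rooted leaf-labelled DAG.  Two interchange formats are
supported: extended Newick (``#H`` hybrid tags) and a plain line-oriented
edge-list dialect used for auditable figure transcriptions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CycleError,
    DisconnectedError,
    LabelError,
    MultiRootError,
    ParseError,
)

__all__ = [
    "PhyloNetwork",
    "NodeIndex",
    "Universe",
    "validate_network",
    "compute_index",
    "parse_enewick",
    "serialize_enewick",
    "parse_edgelist",
    "serialize_edgelist",
    "disjoint_union",
]


@dataclass(frozen=True)
class PhyloNetwork:
    """A validated rooted phylogenetic network ``N = ((V, E), f)``.

    Instances should be built through :func:`validate_network` (or the
    parsers), which enforce the model invariants: acyclicity, a unique root,
    reachability, and a bijective leaf labelling.
    """

    node_ids: frozenset[str]
    edges: frozenset[tuple[str, str]]
    leaf_labels: Mapping[str, str]
    name: str | None = None

    @property
    def root(self) -> str:
        (r,) = [v for v in self.node_ids if not any(e[1] == v for e in self.edges)]
        return r

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels.values())

    def __len__(self) -> int:
        return len(self.node_ids)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class NodeIndex:
    """Structural indices of a validated network.

    ``height``/``depth`` are longest-path lengths to a leaf / from the root;
    ``category`` holds the degree-based node categories (a node may belong to
    several, e.g. ``root`` and ``leaf`` in the one-node network).
    """

    root: str
    height: Mapping[str, int]
    depth: Mapping[str, int]
    category: Mapping[str, frozenset[str]]
    children: Mapping[str, tuple[str, ...]]
    parents: Mapping[str, tuple[str, ...]]


def validate_network(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str]],
    leaf_labels: Mapping[str, str],
    name: str | None = None,
) -> PhyloNetwork:
    """Check all model invariants and return a :class:`PhyloNetwork`.

    Raises :class:`CycleError`, :class:`MultiRootError`, :class:`LabelError`
    or :class:`DisconnectedError` on the first violated invariant.
    """
    node_set = frozenset(str(n) for n in nodes)
    edge_list = [(str(u), str(v)) for u, v in edges]
    edge_set = frozenset(edge_list)
    if len(edge_list) != len(edge_set):
        raise LabelError("parallel edges are not admitted")
    for u, v in edge_set:
        if u not in node_set or v not in node_set:
            raise LabelError(f"edge ({u}, {v}) references an unknown node")
        if u == v:
            raise CycleError(f"self-loop at node {u}")

    g = nx.DiGraph()
    g.add_nodes_from(node_set)
    g.add_edges_from(edge_set)
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError("the edge relation contains a directed cycle")

    # an orphan node is itself an extra in-degree-0 node, so the two error
    # conditions overlap; the in-degree-0 node reaching the most nodes is
    # taken as the root candidate (a tie is a genuine multi-root situation)
    roots = [v for v in node_set if g.in_degree(v) == 0]
    if not roots:
        raise MultiRootError("no in-degree-0 node")
    reach = {r: len(nx.descendants(g, r)) + 1 for r in roots}
    best = max(reach.values())
    top = [r for r in roots if reach[r] == best]
    if len(top) != 1:
        raise MultiRootError(
            f"expected exactly one in-degree-0 node, found {len(roots)}: {sorted(roots)}"
        )
    root = top[0]

    reachable = {root} | nx.descendants(g, root)
    if reachable != node_set:
        orphans = sorted(node_set - reachable)
        raise DisconnectedError(f"nodes unreachable from the root: {orphans}")

    labels = {str(k): str(v) for k, v in leaf_labels.items()}
    leaves = {v for v in node_set if g.out_degree(v) == 0}
    for v in leaves:
        if v not in labels:
            raise LabelError(f"leaf {v} has no taxon label")
    for v in labels:
        if v not in node_set:
            raise LabelError(f"label assigned to unknown node {v}")
        if v not in leaves:
            raise LabelError(f"non-leaf node {v} carries a taxon label")
    seen: dict[str, str] = {}
    for v, taxon in labels.items():
        if taxon in seen.values():
            raise LabelError(f"duplicate taxon label {taxon!r}")
        seen[v] = taxon

    return PhyloNetwork(node_set, edge_set, labels, name)


def compute_index(net: PhyloNetwork) -> NodeIndex:
    """Longest-path heights/depths over a topological order plus degree categories."""
    g = net.to_digraph()
    order = list(nx.topological_sort(g))

    height = {v: 0 for v in g}
    for v in reversed(order):
        for c in g.successors(v):
            height[v] = max(height[v], height[c] + 1)

    depth = {v: 0 for v in g}
    for v in order:
        for c in g.successors(v):
            depth[c] = max(depth[c], depth[v] + 1)

    category: dict[str, frozenset[str]] = {}
    for v in g:
        cats = set()
        indeg, outdeg = g.in_degree(v), g.out_degree(v)
        if indeg == 0:
            cats.add("root")
        if indeg <= 1:
            cats.add("tree")
        if indeg >= 2:
            cats.add("reticulate")
        if outdeg == 0:
            cats.add("leaf")
        if outdeg >= 1:
            cats.add("internal")
        category[v] = frozenset(cats)

    children = {v: tuple(sorted(g.successors(v))) for v in g}
    parents = {v: tuple(sorted(g.predecessors(v))) for v in g}
    return NodeIndex(net.root, height, depth, category, children, parents)


# ---------------------------------------------------------------------------
# extended Newick
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[^(),;#\s]+")
_HYBRID_RE = re.compile(r"#H([^(),;#\s]+)")


class _ENewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.counter = 0
        # hybrid tag -> canonical node id
        self.hybrids: dict[str, str] = {}
        self.hybrid_names: dict[str, str] = {}
        self.edges: list[tuple[str, str]] = []
        self.names: dict[str, str] = {}  # node id -> display name

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, self.pos)

    def fresh(self) -> str:
        self.counter += 1
        return f"_n{self.counter}"

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> tuple[str, list[tuple[str, str]], dict[str, str]]:
        self.skip_ws()
        root = self.subtree()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the statement")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing content after ';'")
        return root, self.edges, self.names

    def subtree(self) -> str:
        self.skip_ws()
        children: list[str] = []
        if self.peek() == "(":
            self.pos += 1
            children.append(self.subtree())
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                children.append(self.subtree())
                self.skip_ws()
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
        name, hybrid = self.label()
        if not children and name is None and hybrid is None:
            raise self.error("expected a subtree or label")
        if hybrid is not None:
            node = self.hybrids.setdefault(hybrid, f"_h{hybrid}")
            if name:
                prior = self.hybrid_names.get(hybrid)
                if prior is not None and prior != name:
                    raise self.error(
                        f"conflicting names {prior!r}/{name!r} for hybrid tag #H{hybrid}"
                    )
                self.hybrid_names[hybrid] = name
                self.names[node] = name
        else:
            node = self.fresh()
            if name:
                self.names[node] = name
        for c in children:
            self.edges.append((node, c))
        return node

    def label(self) -> tuple[str | None, str | None]:
        self.skip_ws()
        name = None
        m = _NAME_RE.match(self.text, self.pos)
        if m:
            name = m.group(0)
            self.pos = m.end()
        hybrid = None
        m = _HYBRID_RE.match(self.text, self.pos)
        if m:
            hybrid = m.group(1)
            self.pos = m.end()
        return name, hybrid


def parse_enewick(text: str, name: str | None = None) -> PhyloNetwork:
    """Parse a single ``;``-terminated eNewick statement into a validated network.

    Occurrences sharing a ``#H<id>`` hybrid tag are unified into one node.
    Leaf names become taxon labels; internal names become node ids where they
    are unique, otherwise opaque ids are generated.
    """
    root, edges, names = _ENewickParser(text).parse()

    # collapse duplicate edges arising from repeated hybrid occurrences
    nodes = {root}
    for u, v in edges:
        nodes.add(u)
        nodes.add(v)
    edge_set = set(edges)
    if len(edge_set) != len(edges):
        raise ParseError("hybrid tag yields a parallel edge")

    has_child = {u for u, _ in edge_set}
    leaf_labels = {}
    rename: dict[str, str] = {}
    used: set[str] = set()
    for v in sorted(nodes):
        display = names.get(v)
        if v not in has_child:
            if display is None:
                raise ParseError(f"unlabelled leaf in eNewick input (node {v})")
            leaf_labels[v] = display
        if display is not None and display not in used:
            rename[v] = display
            used.add(display)
    # apply renames where unambiguous so node ids stay human-readable
    final = {v: rename.get(v, v) for v in nodes}
    if len(set(final.values())) != len(nodes):
        final = {v: v for v in nodes}  # fall back to opaque ids on collision
    return validate_network(
        [final[v] for v in nodes],
        [(final[u], final[v]) for u, v in edge_set],
        {final[v]: lab for v, lab in leaf_labels.items()},
        name,
    )


def serialize_enewick(net: PhyloNetwork) -> str:
    """Deterministic eNewick serialization.

    Children are ordered by the sorted set of leaf labels reachable below them
    (ties broken by node id); each reticulate node is written in full once and
    afterwards referenced by its ``#H`` tag.
    """
    idx = compute_index(net)
    g = net.to_digraph()

    below: dict[str, tuple[str, ...]] = {}
    for v in reversed(list(nx.topological_sort(g))):
        if not idx.children[v]:
            below[v] = (net.leaf_labels[v],)
        else:
            acc: set[str] = set()
            for c in idx.children[v]:
                acc.update(below[c])
            below[v] = tuple(sorted(acc))

    # hybrid numbers are assigned in first-encounter order of the canonical
    # traversal, so structurally identical networks serialize identically
    # regardless of their node ids
    hybrid_ids: dict[str, int] = {}
    emitted: set[str] = set()

    def render(v: str) -> str:
        if len(idx.parents[v]) >= 2 and v not in hybrid_ids:
            hybrid_ids[v] = len(hybrid_ids) + 1
        tag = f"#H{hybrid_ids[v]}" if v in hybrid_ids else ""
        label = net.leaf_labels.get(v, "")
        if v in emitted:
            return tag
        emitted.add(v)
        kids = sorted(idx.children[v], key=lambda c: (below[c], c))
        if not kids:
            return f"{label}{tag}"
        inner = ",".join(render(c) for c in kids)
        return f"({inner}){label}{tag}"

    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# edge-list dialect
# ---------------------------------------------------------------------------


def parse_edgelist(text: str, name: str | None = None) -> PhyloNetwork:
    """Parse the plain fixture format: ``edge <parent> <child>`` / ``leaf <node> <label>``.

    ``#`` starts a comment; blank lines are ignored.  Node ids are opaque
    strings.  The format is lossless for any validated network.
    """
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "edge" and len(parts) == 3:
            nodes.update(parts[1:])
            edges.append((parts[1], parts[2]))
        elif parts[0] == "leaf" and len(parts) == 3:
            nodes.add(parts[1])
            labels[parts[1]] = parts[2]
        elif parts[0] == "node" and len(parts) == 2:
            nodes.add(parts[1])
        else:
            raise ParseError(f"unrecognized edge-list line {lineno}: {raw!r}")
    return validate_network(nodes, edges, labels, name)


def serialize_edgelist(net: PhyloNetwork) -> str:
    """Deterministic, lossless edge-list rendering of a validated network."""
    lines = []
    if len(net) == 1:
        lines.append(f"node {net.root}")
    for u, v in sorted(net.edges):
        lines.append(f"edge {u} {v}")
    for v in sorted(net.leaf_labels):
        lines.append(f"leaf {v} {net.leaf_labels[v]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# disjoint union (origin-tagged node universe)
# ---------------------------------------------------------------------------

Tagged = tuple[int, str]


@dataclass(frozen=True)
class Universe:
    """One or two indexed networks over a shared, origin-tagged node set.

    Nodes are ``(origin, node_id)`` pairs.  Leaf labels are kept per node and
    never merged across origins: cross-network label identity is consumed only
    by the equivalence base case.
    """

    networks: tuple[PhyloNetwork, ...]
    nodes: tuple[Tagged, ...]
    children: Mapping[Tagged, tuple[Tagged, ...]]
    parents: Mapping[Tagged, tuple[Tagged, ...]]
    leaf_label: Mapping[Tagged, str]
    roots: frozenset[Tagged]
    height: Mapping[Tagged, int]
    depth: Mapping[Tagged, int]
    indices: tuple[NodeIndex, ...] = field(repr=False, default=())

    @property
    def scope(self) -> str:
        return "one-network" if len(self.networks) == 1 else "two-network"

    def origin_nodes(self, origin: int) -> tuple[Tagged, ...]:
        return tuple(v for v in self.nodes if v[0] == origin)


def disjoint_union(*nets: PhyloNetwork) -> Universe:
    """Build the tagged node universe of one or two validated networks."""
    if not 1 <= len(nets) <= 2:
        raise ValueError("a universe is built from one or two networks")
    nodes: list[Tagged] = []
    children: dict[Tagged, tuple[Tagged, ...]] = {}
    parents: dict[Tagged, tuple[Tagged, ...]] = {}
    leaf_label: dict[Tagged, str] = {}
    roots: set[Tagged] = set()
    height: dict[Tagged, int] = {}
    depth: dict[Tagged, int] = {}
    indices = []
    for origin, net in enumerate(nets):
        idx = compute_index(net)
        indices.append(idx)
        for v in sorted(net.node_ids):
            t = (origin, v)
            nodes.append(t)
            children[t] = tuple((origin, c) for c in idx.children[v])
            parents[t] = tuple((origin, p) for p in idx.parents[v])
            height[t] = idx.height[v]
            depth[t] = idx.depth[v]
            if v in net.leaf_labels:
                leaf_label[t] = net.leaf_labels[v]
        roots.add((origin, idx.root))
    return Universe(
        tuple(nets),
        tuple(nodes),
        children,
        parents,
        leaf_label,
        frozenset(roots),
        height,
        depth,
        tuple(indices),
    )
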