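"""Directed-graph data model for gene regulatory networks.

Node identifiers are case-sensitive opaque strings (gene symbols, probe
IDs, ...). A :class:`DirectedGraph` may contain cycles, as real
transcription-factor networks do; a :class:`Dag` is validated acyclic at
construction and caches a deterministic topological order. The
:class:`AugmentedDag` adds a discrete treatment node with edges into a
subset of genes -- the hybrid-network structure under which treatment
effects are tested.

Algorithms (cycle detection, topological sorting, weak components,
d-separation) are delegated to networkx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import CycleError, NetworkParseError

__all__ = [
    "DirectedGraph",
    "Dag",
    "AugmentedDag",
    "read_network",
    "as_dag",
    "d_separated",
    "restrict_to_measured",
    "weak_components",
    "induced_subgraph",
    "write_edge_list",
    "write_graphml",
    "write_dot",
]


class DirectedGraph:
    """A simple directed graph over string node labels.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is
    a node. Endpoints of supplied edges are added to the node set
    automatically. Instances are treated as immutable.
    """

    __slots__ = ("_nodes", "_edges")

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        node_set = {str(n) for n in nodes}
        edge_set = set()
        for e in edges:
            u, v = e
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop {u!r} -> {v!r} not allowed")
            edge_set.add((u, v))
            node_set.add(u)
            node_set.add(v)
        self._nodes = frozenset(node_set)
        self._edges = frozenset(edge_set)

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    def __eq__(self, other):
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self):
        return hash((self._nodes, self._edges))

    def __len__(self):
        return len(self._nodes)

    def __repr__(self):
        return f"{type(self).__name__}({len(self._nodes)} nodes, {len(self._edges)} edges)"

    def in_neighbours(self, g: str) -> frozenset[str]:
        if g not in self._nodes:
            raise KeyError(g)
        return frozenset(u for (u, v) in self._edges if v == g)

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(sorted(self._nodes))
        G.add_edges_from(sorted(self._edges))
        return G


class Dag(DirectedGraph):
    """A validated acyclic directed graph with a cached topological order.

    The order is the lexicographic topological sort, so it is a
    deterministic function of the graph alone.
    """

    __slots__ = ("_order", "_parents")

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        super().__init__(nodes, edges)
        G = self.to_networkx()
        try:
            order = list(nx.lexicographical_topological_sort(G))
        except nx.NetworkXUnfeasible:
            cycle_edges = nx.find_cycle(G)
            witness = [u for u, _ in cycle_edges] + [cycle_edges[0][0]]
            raise CycleError(witness) from None
        self._order = tuple(order)
        parents: dict[str, set[str]] = {n: set() for n in self._nodes}
        for u, v in self._edges:
            parents[v].add(u)
        self._parents = {n: frozenset(ps) for n, ps in parents.items()}

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._order

    def parents(self, g: str) -> frozenset[str]:
        """Set of nodes with an arrow into ``g``."""
        if g not in self._parents:
            raise KeyError(g)
        return self._parents[g]


@dataclass(frozen=True)
class AugmentedDag:
    """A gene DAG augmented with a discrete treatment node.

    ``treated_genes`` is the set V_T of genes receiving a direct edge from
    the treatment node; the augmented graph is acyclic by construction
    because the treatment node has no incoming edges.
    """

    base: Dag
    treated_genes: frozenset[str] = field(default_factory=frozenset)
    treatment_node: str = "T"

    def __post_init__(self):
        object.__setattr__(self, "treated_genes", frozenset(self.treated_genes))
        if self.treatment_node in self.base.nodes:
            raise ValueError(
                f"treatment node label {self.treatment_node!r} collides with a gene"
            )
        extra = self.treated_genes - self.base.nodes
        if extra:
            raise ValueError(f"treated genes not in the network: {sorted(extra)}")

    @property
    def treatment_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((self.treatment_node, g) for g in self.treated_genes)


def read_network(path, fmt: str = "edgelist") -> DirectedGraph:
    """Read a directed network from an edge-list or SIF file.

    Edge list: two whitespace/tab-separated columns ``source target``,
    ``#`` comments and blank lines ignored. SIF:
    ``source interaction target [target ...]`` with the interaction label
    ignored and multiple targets fanned out. Self-loops are dropped with
    a warning (common in public pathway exports). Duplicate edges
    collapse by set semantics.
    """
    if fmt not in ("edgelist", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fmt == "edgelist":
                if len(fields) != 2:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) == 1:
                    # SIF allows an isolated node on a line by itself
                    nodes.add(fields[0])
                    continue
                if len(fields) < 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: SIF line needs source, interaction, "
                        f"target(s); got {len(fields)} fields"
                    )
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                if u == v:
                    warnings.warn(
                        f"{path}:{lineno}: dropping self-loop {u!r} -> {v!r}",
                        stacklevel=2,
                    )
                    nodes.add(u)
                    continue
                edges.add((u, v))
    return DirectedGraph(nodes, edges)


def as_dag(g: DirectedGraph) -> Dag:
    """Validate acyclicity; raises :class:`CycleError` with a witness cycle."""
    if isinstance(g, Dag):
        return g
    return Dag(g.nodes, g.edges)


def parents(d: Dag, g: str) -> frozenset[str]:
    return d.parents(g)


def d_separated(d: Dag, u: Iterable[str], v: Iterable[str], w: Iterable[str]) -> bool:
    """Standard d-separation of node sets ``u`` and ``v`` given ``w``.

    The three sets must be pairwise disjoint subsets of the DAG's nodes.
    """
    us, vs, ws = frozenset(u), frozenset(v), frozenset(w)
    if us & vs or us & ws or vs & ws:
        raise ValueError("u, v, w must be pairwise disjoint")
    unknown = (us | vs | ws) - d.nodes
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(unknown)}")
    return nx.is_d_separator(d.to_networkx(), us, vs, ws)


def restrict_to_measured(g: DirectedGraph, measured: Iterable[str]) -> DirectedGraph:
    """Drop genes absent from the expression data, with incident edges.

    No transitive bypass edges are created: a regulatory chain through an
    unmeasured gene is broken, which deliberately preserves the
    conditional-independence semantics of the remaining graph.
    """
    keep = g.nodes & frozenset(measured)
    return induced_subgraph(g, keep)


def induced_subgraph(g: DirectedGraph, keep: Iterable[str]) -> DirectedGraph:
    keep = g.nodes & frozenset(keep)
    edges = {(u, v) for (u, v) in g.edges if u in keep and v in keep}
    cls = Dag if isinstance(g, Dag) else DirectedGraph
    return cls(keep, edges)


def weak_components(g: DirectedGraph) -> list[frozenset[str]]:
    """Weakly connected components, sorted by decreasing size then
    lexicographically by smallest member for determinism."""
    comps = [frozenset(c) for c in nx.weakly_connected_components(g.to_networkx())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def write_edge_list(g: DirectedGraph, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")


def write_graphml(g: DirectedGraph, path, node_attrs: dict[str, dict] | None = None) -> None:
    """GraphML export; ``node_attrs`` maps node -> attribute dict
    (e.g. ``is_tf``, ``adjusted_p``) for visualization tools."""
    G = g.to_networkx()
    for node, attrs in (node_attrs or {}).items():
        if node in G:
            G.nodes[node].update(attrs)
    nx.write_graphml(G, path)


def write_dot(g: DirectedGraph, path, node_attrs: dict[str, dict] | None = None) -> None:
    """Minimal DOT export (no pydot dependency)."""
    node_attrs = node_attrs or {}
    with open(path, "w") as fh:
        fh.write("digraph G {\n")
        for n in sorted(g.nodes):
            attrs = node_attrs.get(n, {})
            if attrs:
                inner = ", ".join(f'{k}="{v}"' for k, v in sorted(attrs.items()))
                fh.write(f'  "{n}" [{inner}];\n')
            else:
                fh.write(f'  "{n}";\n')
        for u, v in sorted(g.edges):
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")
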