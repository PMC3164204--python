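"""Source->sink shortest-path analysis of a mixed interaction graph.

The graph mixes undirected protein-protein interaction (ppi) edges with
directed regulatory (reg) edges, traversed regulator->target only.  The
reprogramming factors act as sources and pluripotency-regulated genes as
sinks; the subnetwork of interest is the union of all shortest paths
between every (source, sink) pair.  Each intermediate node v is scored
with a betweenness variant: the number of source->sink shortest paths
passing through v divided by the mean length (edge count) of exactly
those paths — favouring nodes that sit on many short shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_TYPES = ("ppi", "reg")


@dataclass
class InteractionNetwork:
    """Typed mixed graph with node roles (source / sink / other).

    ``edges`` are ``(a, type, b)`` triples; ppi edges are undirected,
    reg edges are directed a->b.  Self-loops are rejected.
    """

    edges: list[tuple[str, str, str]]
    roles: dict[str, str] = field(default_factory=dict)
    nodes: list[str] = field(default_factory=list)

    @classmethod
    def from_edges(cls, edges, roles=None, nodes=None) -> "InteractionNetwork":
        edges = [tuple(e) for e in edges]
        node_order: dict[str, None] = {}
        for n in nodes or []:
            node_order.setdefault(n, None)
        for a, etype, b in edges:
            if etype not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {etype!r}")
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            node_order.setdefault(a, None)
            node_order.setdefault(b, None)
        roles = dict(roles or {})
        for n, r in roles.items():
            if r not in ("source", "sink"):
                raise ValueError(f"unknown role {r!r}")
            if n not in node_order:
                raise ValueError(f"role declared for unknown node {n!r}")
        return cls(edges=edges, roles=roles, nodes=list(node_order))

    @property
    def sources(self) -> list[str]:
        return [n for n in self.nodes if self.roles.get(n) == "source"]

    @property
    def sinks(self) -> list[str]:
        return [n for n in self.nodes if self.roles.get(n) == "sink"]

    def traversal_graph(self, undirected_all: bool = False) -> nx.DiGraph:
        """Directed traversal view: ppi both ways, reg forward only
        (``undirected_all`` collapses everything to both ways)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, etype, b in self.edges:
            g.add_edge(a, b, type=etype)
            if etype == "ppi" or undirected_all:
                g.add_edge(b, a, type=etype)
        return g

    def to_graphml(self, path, node_attrs: pd.DataFrame | None = None) -> None:
        """Export as GraphML, optionally attaching per-node attributes
        (e.g. score / class columns indexed by node id)."""
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, role=self.roles.get(n, "other"))
        for a, etype, b in self.edges:
            g.add_edge(a, b, type=etype)
        if node_attrs is not None:
            for n, row in node_attrs.iterrows():
                if n in g:
                    for k, v in row.items():
                        g.nodes[n][k] = v if not isinstance(v, (np.floating, np.integer)) else v.item()
        nx.write_graphml(g, path)


def _check_endpoints(net: InteractionNetwork, sources, sinks) -> tuple[list, list]:
    sources, sinks = list(sources), list(sinks)
    unknown = [n for n in [*sources, *sinks] if n not in net.nodes]
    if unknown:
        raise KeyError(f"unknown source/sink nodes: {unknown}")
    return sources, sinks


def _pair_shortest_paths(net: InteractionNetwork, sources, sinks,
                         undirected_all: bool = False):
    """Yield (source, sink, [paths]) with *all* shortest paths per pair."""
    g = net.traversal_graph(undirected_all=undirected_all)
    for s in sources:
        for t in sinks:
            if s == t:
                continue
            try:
                paths = [list(p) for p in nx.all_shortest_paths(g, s, t)]
            except nx.NetworkXNoPath:
                logger.info("no route from source %r to sink %r", s, t)
                continue
            yield s, t, paths


def build_subnetwork(net: InteractionNetwork, sources=None, sinks=None,
                     undirected_all: bool = False) -> InteractionNetwork:
    """Union of all shortest paths between every (source, sink) pair.

    Keeps the original typed edges that appear consecutively on some
    shortest path; unreachable pairs contribute nothing.
    """
    sources, sinks = _check_endpoints(net, sources or net.sources, sinks or net.sinks)
    used_nodes: dict[str, None] = {}
    used_steps: set[tuple[str, str]] = set()
    for _, _, paths in _pair_shortest_paths(net, sources, sinks, undirected_all):
        for p in paths:
            for v in p:
                used_nodes.setdefault(v, None)
            used_steps.update(zip(p, p[1:]))
    sub_edges = []
    for a, etype, b in net.edges:
        if (a, b) in used_steps or ((b, a) in used_steps and (etype == "ppi" or undirected_all)):
            sub_edges.append((a, etype, b))
    roles = {n: r for n, r in net.roles.items() if n in used_nodes}
    return InteractionNetwork.from_edges(sub_edges, roles, nodes=list(used_nodes))


def score_nodes(net: InteractionNetwork, sources=None, sinks=None,
                undirected_all: bool = False) -> pd.DataFrame:
    """Betweenness-variant score for every non-source/sink node.

    For each node: ``path_count`` source->sink shortest paths containing
    it as an interior node (accumulated across pairs), the mean length of
    exactly those paths, and ``score = path_count / mean_path_length``
    (0 when the node lies on no path).  Sources and sinks are not scored.
    """
    sources, sinks = _check_endpoints(net, sources or net.sources, sinks or net.sinks)
    endpoint = set(sources) | set(sinks)
    counts: dict[str, int] = {}
    length_sums: dict[str, int] = {}
    for _, _, paths in _pair_shortest_paths(net, sources, sinks, undirected_all):
        for p in paths:
            plen = len(p) - 1
            for v in p[1:-1]:
                counts[v] = counts.get(v, 0) + 1
                length_sums[v] = length_sums.get(v, 0) + plen
    rows = []
    for v in net.nodes:
        if v in endpoint:
            continue
        c = counts.get(v, 0)
        mean_len = length_sums[v] / c if c else np.nan
        rows.append((v, c, mean_len, c / mean_len if c else 0.0))
    return pd.DataFrame(rows, columns=["node", "path_count", "mean_path_length",
                                       "score"]).set_index("node")


def classify_nodes(scores: pd.DataFrame, high_quantile: float = 0.75) -> pd.DataFrame:
    """Split scored nodes into high/low at a quantile of positive scores.

    A node is *high* when its score is >= the ``high_quantile`` quantile
    of the positive scores (boundary ties go high); zero-score nodes are
    low.  With no positive score at all, everything is low.
    """
    if scores.empty:
        raise ValueError("empty score list")
    out = scores.copy()
    positive = out["score"][out["score"] > 0]
    if positive.empty:
        out["class"] = "low"
        return out
    threshold = float(np.quantile(positive.to_numpy(), high_quantile))
    out["class"] = np.where(out["score"] >= threshold, "high", "low")
    return out


def paths_through(net: InteractionNetwork, sources=None, sinks=None, *,
                  via: str, undirected_all: bool = False) -> list[tuple[str, ...]]:
    """All source->sink shortest paths whose interior contains ``via``.

    Returned as ordered node tuples, sorted by (source, sink, path).
    """
    if via not in net.nodes:
        raise KeyError(f"unknown via node {via!r}")
    sources, sinks = _check_endpoints(net, sources or net.sources, sinks or net.sinks)
    hits = []
    for s, t, paths in _pair_shortest_paths(net, sources, sinks, undirected_all):
        for p in paths:
            if via in p[1:-1]:
                hits.append(tuple(p))
    return sorted(hits)
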