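"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit enumeration, direct
summation) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values by explicit min-over-tail computation."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary two-sample pooled t statistic and its log2 fold change."""
    n1, n2 = len(x), len(y)
    lfc = float(np.mean(x) - np.mean(y))
    ss = float(((x - np.mean(x)) ** 2).sum() + ((y - np.mean(y)) ** 2).sum())
    s2 = ss / (n1 + n2 - 2)
    return lfc / math.sqrt(s2 * (1 / n1 + 1 / n2)), lfc


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric by direct summation over all overlaps."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def binomial_tail_sum(n: int, x: int, p: float) -> float:
    """Upper-tail binomial by brute-force summation."""
    return sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j) for j in range(x, n + 1))


# --- mixed-graph shortest-path enumeration ------------------------------

def _adjacency(edges) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, etype, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set())
        if etype == "ppi":
            adj[b].add(a)
    return adj


def all_simple_paths(edges, start: str, end: str) -> list[list[str]]:
    """Every simple path from start to end under mixed-graph semantics."""
    adj = _adjacency(edges)
    out: list[list[str]] = []

    def dfs(node, path):
        if node == end:
            out.append(list(path))
            return
        for nxt in adj.get(node, ()):  # noqa: B007
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    if start in adj:
        dfs(start, [start])
    return out


def shortest_paths_enumeration(edges, sources, sinks) -> dict[tuple[str, str], list[list[str]]]:
    """All shortest paths per (source, sink) pair by exhaustive DFS."""
    result = {}
    for s in sources:
        for t in sinks:
            if s == t:
                continue
            paths = all_simple_paths(edges, s, t)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            result[(s, t)] = [p for p in paths if len(p) - 1 == d]
    return result


def score_nodes_enumeration(edges, nodes, sources, sinks) -> dict[str, tuple[int, float, float]]:
    """(path_count, mean_path_length, score) per interior node, by DFS."""
    sp = shortest_paths_enumeration(edges, sources, sinks)
    endpoint = set(sources) | set(sinks)
    out = {}
    for v in nodes:
        if v in endpoint:
            continue
        lengths = [len(p) - 1 for paths in sp.values() for p in paths if v in p[1:-1]]
        if lengths:
            mean_len = sum(lengths) / len(lengths)
            out[v] = (len(lengths), mean_len, len(lengths) / mean_len)
        else:
            out[v] = (0, float("nan"), 0.0)
    return out


def random_mixed_graph(rng: np.random.Generator, max_nodes: int = 12):
    """Random typed mixed graph with random source/sink roles."""
    n = int(rng.integers(4, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u = rng.uniform()
            if u < 0.35:
                etype = "ppi" if rng.uniform() < 0.6 else "reg"
                a, b = (nodes[i], nodes[j]) if rng.uniform() < 0.5 else (nodes[j], nodes[i])
                edges.append((a, etype, b))
    k_src = int(rng.integers(1, 3))
    k_snk = int(rng.integers(1, 3))
    picks = rng.choice(n, size=min(n, k_src + k_snk), replace=False)
    sources = [nodes[i] for i in picks[:k_src]]
    sinks = [nodes[i] for i in picks[k_src:]]
    return nodes, edges, sources, sinks
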