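"""Hand-written brute-force oracles, independent of networkx and of the
package implementation.  All operate on plain adjacency dicts
{node: set(neighbors)} and are only meant for tiny graphs."""

from __future__ import annotations

import itertools
import random


def random_adjacency(n: int, p: float, seed: int) -> dict[str, set[str]]:
    """Erdos-Renyi-style random simple graph as an adjacency dict."""
    rng = random.Random(seed)
    nodes = [f"n{i}" for i in range(n)]
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def edges_of(adj: dict[str, set[str]]) -> list[tuple[str, str]]:
    return [(a, b) for a in sorted(adj) for b in sorted(adj[a]) if a < b]


def all_simple_paths(
    adj: dict[str, set[str]], s: str, t: str, n_nodes: int
) -> list[tuple[str, ...]]:
    """Every simple path from s to t with exactly n_nodes members."""
    out: list[tuple[str, ...]] = []

    def rec(path: list[str]) -> None:
        last = path[-1]
        if len(path) == n_nodes:
            if last == t:
                out.append(tuple(path))
            return
        if last == t:
            return
        for nb in sorted(adj[last]):
            if nb not in path:
                rec(path + [nb])

    rec([s])
    return out


def shortest_dist(adj: dict[str, set[str]], s: str) -> dict[str, int]:
    """Plain BFS distances."""
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for v in frontier:
            for nb in adj[v]:
                if nb not in dist:
                    dist[nb] = dist[v] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = shortest_dist(adj, s)
        if t not in dist:
            continue
        length = dist[t] + 1  # node count of a shortest path
        sps = all_simple_paths(adj, s, t, length)
        if not sps:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            bc[v] += through / len(sps)
    return bc


def floyd_warshall(adj: dict[str, set[str]]) -> dict[tuple[str, str], float]:
    nodes = sorted(adj)
    inf = float("inf")
    d = {(a, b): (0 if a == b else (1 if b in adj[a] else inf))
         for a in nodes for b in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(adj: dict[str, set[str]], v: str) -> float:
    """Local clustering coefficient by triangle counting."""
    nbrs = sorted(adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
    )
    return 2.0 * links / (k * (k - 1))


def brute_avg_clustering(adj: dict[str, set[str]]) -> float:
    return sum(brute_clustering(adj, v) for v in adj) / len(adj)


def brute_cpl_diameter(adj: dict[str, set[str]]) -> tuple[float, int]:
    """(mean shortest-path length over connected ordered pairs,
    diameter of the largest component)."""
    d = floyd_warshall(adj)
    finite = [val for (a, b), val in d.items() if a != b and val < float("inf")]
    cpl = sum(finite) / len(finite) if finite else 0.0
    comps = components(adj)
    largest = max(comps, key=len)
    diam = max(
        (int(d[a, b]) for a in largest for b in largest if d[a, b] < float("inf")),
        default=0,
    )
    return cpl, diam


def components(adj: dict[str, set[str]]) -> list[set[str]]:
    """Connected components by union-find."""
    parent = {v: v for v in adj}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a in adj:
        for b in adj[a]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for v in adj:
        groups.setdefault(find(v), set()).add(v)
    return list(groups.values())


def delete_node(adj: dict[str, set[str]], v: str) -> dict[str, set[str]]:
    return {a: {b for b in nbrs if b != v} for a, nbrs in adj.items() if a != v}
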