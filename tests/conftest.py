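"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
betweenness is the pair-dependency formulation over BFS counts, average
shortest path goes through Floyd-Warshall, BH is the literal step-up
recursion, and the hypergeometric tail is exhaustive draw enumeration.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from switchnet import ExpressionMatrix, SyntheticConfig, generate

STRONG_CONFIG = SyntheticConfig()  # 4x25 modules, 5 switch, 10+10, 0.9/0.3/1.5
BENCH_THRESHOLD = 0.6  # correlation cut-off of the planted benchmark


@pytest.fixture(scope="session")
def strong_data():
    return generate(SyntheticConfig(seed=1))


@pytest.fixture()
def tiny_expr():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3", "s4"])
    groups = pd.Series(["control", "control", "case", "case"],
                       index=values.columns)
    return ExpressionMatrix(values, groups)


def random_expression(rng, n_genes=12, n_per_group=4) -> ExpressionMatrix:
    cols = [f"c{i}" for i in range(n_per_group)] + [f"d{i}" for i in range(n_per_group)]
    values = pd.DataFrame(rng.normal(8, 2, (n_genes, 2 * n_per_group)),
                          index=[f"g{i}" for i in range(n_genes)], columns=cols)
    groups = pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=cols)
    return ExpressionMatrix(values, groups)


def random_graph(rng, n=15, p=0.25) -> dict[str, set[str]]:
    """Adjacency-set random graph with string node ids."""
    nodes = [f"n{i}" for i in range(n)]
    adj = {v: set() for v in nodes}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[nodes[i]].add(nodes[j])
                adj[nodes[j]].add(nodes[i])
    return adj


def adj_to_nx(adj):
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(adj)
    G.add_edges_from((u, v) for u, nbrs in adj.items() for v in nbrs if u < v)
    return G


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def brute_within_module_degree_z(adj, community) -> dict:
    kappa = {v: sum(1 for w in adj[v] if community[w] == community[v]) for v in adj}
    out = {}
    for v in adj:
        peers = [kappa[w] for w in adj if community[w] == community[v]]
        mu = sum(peers) / len(peers)
        sd = (sum((k - mu) ** 2 for k in peers) / len(peers)) ** 0.5
        out[v] = (kappa[v] - mu) / sd if sd > 0 else 0.0
    return out


def brute_clusterphobic(adj, community) -> dict:
    out = {}
    for v in adj:
        k_tot = len(adj[v])
        if k_tot == 0:
            out[v] = 0.0
            continue
        k_in = sum(1 for w in adj[v] if community[w] == community[v])
        out[v] = 1.0 - (k_in / k_tot) ** 2
    return out


def _bfs_counts(adj, s):
    dist, sigma = {s: 0}, {s: 1}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in sorted(adj[u]):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def brute_betweenness(adj) -> dict:
    """Unnormalized betweenness via sigma(s,v)*sigma(v,t)/sigma(s,t) pair sums."""
    nodes = sorted(adj)
    info = {s: _bfs_counts(adj, s) for s in nodes}
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        ds, ss = info[s]
        for t in nodes[i + 1:]:
            if t not in ds:
                continue
            dt, st = info[t]
            for v in nodes:
                if v in (s, t) or v not in ds or v not in dt:
                    continue
                if ds[v] + dt[v] == ds[t]:
                    bc[v] += ss[v] * st[v] / ss[t]
    return bc


def brute_average_shortest_path(adj) -> float:
    """Floyd-Warshall ASP over the largest component (own DFS components)."""
    from scipy.sparse.csgraph import floyd_warshall

    seen, comps = set(), []
    for v in adj:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    comp = sorted(max(comps, key=len))
    idx = {v: i for i, v in enumerate(comp)}
    A = np.zeros((len(comp), len(comp)))
    for u in comp:
        for w in adj[u]:
            if w in idx:
                A[idx[u], idx[w]] = 1
    D = floyd_warshall(A, unweighted=True)
    iu = np.triu_indices(len(comp), k=1)
    return float(D[iu].mean())


def brute_bh(p) -> np.ndarray:
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def brute_hypergeom_tail(background: int, successes: int, draws: int,
                         observed: int) -> Fraction:
    """P(X >= observed) by enumerating every equally likely draw."""
    hits, total = 0, 0
    good = set(range(successes))
    for draw in combinations(range(background), draws):
        total += 1
        if len(good.intersection(draw)) >= observed:
            hits += 1
    return Fraction(hits, total)


def f1_score(called: set, planted: set) -> float:
    tp = len(called & planted)
    if not called or not planted or tp == 0:
        return 0.0
    precision, recall = tp / len(called), tp / len(planted)
    return 2 * precision * recall / (precision + recall)
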