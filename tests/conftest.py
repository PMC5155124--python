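"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dcgn import CoexNetwork


def net_from_edges(
    edges: dict[tuple[str, str], float],
    genes: list[str] | None = None,
    label: str = "",
) -> CoexNetwork:
    """Build a network from an explicit weighted edge dict."""
    if genes is None:
        genes = sorted({g for pair in edges for g in pair})
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return CoexNetwork.from_weights(genes, W, phase_label=label)


def random_network(
    rng: np.random.Generator, n: int, density: float = 0.3, label: str = ""
) -> CoexNetwork:
    """Random sparse symmetric weighted network with weights in (0, 1)."""
    genes = [f"g{i}" for i in range(n)]
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 0.95)
    return CoexNetwork.from_weights(genes, W, phase_label=label)


# ---------------------------------------------------------------------------
# independent oracles

def ball_and_edges_oracle(net: CoexNetwork, center: str, k: int):
    """k-hop ball and induced edge set via boolean matrix powers."""
    A = (net.W > 0).astype(int)
    n = A.shape[0]
    reach = np.eye(n, dtype=int)
    power = np.eye(n, dtype=int)
    for _ in range(k):
        power = (power @ A > 0).astype(int)
        reach = ((reach + power) > 0).astype(int)
    c = net.gene_ids.index(center)
    members = [net.gene_ids[i] for i in np.flatnonzero(reach[c])]
    member_set = set(members)
    edges = {
        tuple(sorted((a, b)))
        for a, b in itertools.combinations(members, 2)
        if net.W[net.index()[a], net.index()[b]] > 0
    }
    return member_set, edges


def enumerate_min_hop_walk_prob(net: CoexNetwork, sub_nodes: set[str],
                                center: str, target: str) -> float:
    """Exhaustive max product of transition probabilities over minimal-hop
    walks from center to target, restricted to ``sub_nodes``."""
    idx = net.index()
    nodes = sorted(sub_nodes, key=idx.get)
    # BFS distance inside the node set
    adj = {
        g: [h for h in nodes if h != g and net.W[idx[g], idx[h]] > 0]
        for g in nodes
    }
    dist = {center: 0}
    frontier = [center]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    L = dist[target]

    best = 0.0

    def walk(u: str, steps_left: int, prob: float) -> None:
        nonlocal best
        if steps_left == 0:
            if u == target:
                best = max(best, prob)
            return
        for v in adj[u]:
            walk(v, steps_left - 1, prob * net.M[idx[u], idx[v]])

    walk(center, L, 1.0)
    return best


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160330)
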