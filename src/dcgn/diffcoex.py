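"""Per-gene differential coexpression between two phase-specific networks.

Two metrics quantify how much the local (k-hop) neighbourhood of a gene
changes between two coexpression networks:

**DCGN-S** — topological-structure dissimilarity: one minus the Jaccard
index of the two k-neighbourhood *edge* sets,

    d_i = 1 - |E_i^{t1,k} ∩ E_i^{t2,k}| / |E_i^{t1,k} ∪ E_i^{t2,k}|,

where E_i^{t,k} is the edge set of the subgraph induced by the nodes within
k steps of gene i in phase t.

**DCGN-I** — variation of local topological information.  Each gene-centric
subnetwork is first collapsed to a star: for every member j of the k-hop
neighbourhood, the maximum product of random-walk transition probabilities
over minimal-hop walks from the centre to j (p_ij^max) is computed, these
are normalized to probabilities p_ij, inverted and renormalized
(q_ij ∝ 1/p_ij, so that strong, short connections carry more information),
and each partner is assigned the information I_ij = -q_ij ln q_ij.  The
score of gene i is the information carried by neighbourhood members that are
exclusive to one of the two phases:

    I_i = Σ_{j in N^{t1,k} \\ N^{t2,k}} I_ij^{t1,k}
        + Σ_{j in N^{t2,k} \\ N^{t1,k}} I_ij^{t2,k}.

DCGN-S operates on edge sets, DCGN-I on node sets; both are symmetric in the
two networks, vanish on identical networks, and a gene isolated in both
phases scores 0 under both (no evidence of differential coexpression).
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netbuild import CoexNetwork

__all__ = [
    "Subnetwork",
    "StarInfoNetwork",
    "ScoreTable",
    "extract_subnetwork",
    "dcgn_s",
    "max_least_step_prob",
    "star_transform",
    "dcgn_i",
    "score_all",
]

# probabilities are clamped here before taking logs
_LOG_FLOOR = 1e-300


@dataclass
class Subnetwork:
    """The gene-centric k-level neighbourhood of one network.

    ``nodes`` lists the member genes in parent-network order; ``weights`` and
    ``trans`` are the restrictions of the parent ``W`` and ``M`` to those
    nodes.  ``trans`` is deliberately *not* renormalized: transition
    probabilities are those of the full network, so rows may sum to < 1
    inside the subnetwork.
    """

    center: str
    k: int
    nodes: list[str]
    node_set: frozenset[str]
    edge_set: frozenset[tuple[str, str]]
    weights: np.ndarray
    trans: np.ndarray
    phase_label: str = ""
    # BFS hop distance from the centre, aligned with ``nodes``
    hop_dist: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self._pmax: dict[str, float] | None = None


@dataclass
class StarInfoNetwork:
    """Star collapse of a gene-centric subnetwork.

    ``norm_probs`` are the normalized maximal minimal-hop walk probabilities
    p_ij (summing to 1), ``partner_probs`` the inverse-renormalized q_ij
    (also summing to 1), and ``partner_info`` the per-partner information
    values -q ln q.
    """

    center: str
    norm_probs: dict[str, float]
    partner_probs: dict[str, float]
    partner_info: dict[str, float]

    def total_info(self) -> float:
        return float(sum(self.partner_info.values()))


@dataclass
class ScoreTable:
    """Differential-coexpression values of every gene for one phase pair."""

    gene_ids: list[str]
    metric: str  # "S" or "I"
    k: int
    phase_pair: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("one value per gene required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "phase_pair": f"{self.phase_pair[0]}|{self.phase_pair[1]}",
                "metric": self.metric,
                "k": self.k,
                "value": self.values,
            }
        )


def extract_subnetwork(net: CoexNetwork, center: str, k: int) -> Subnetwork:
    """BFS ball of radius ``k`` around ``center`` with its induced subgraph."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = net.index()
    if center not in idx:
        raise KeyError(f"gene {center!r} not in network")
    c = idx[center]

    dist = {c: 0}
    frontier = deque([c])
    while frontier:
        u = frontier.popleft()
        if dist[u] == k:
            continue
        for v in net.neighbors(u):
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)

    members = sorted(dist)  # parent-network order
    genes = [net.gene_ids[i] for i in members]
    sub_w = net.W[np.ix_(members, members)]
    sub_m = net.M[np.ix_(members, members)]
    ii, jj = np.nonzero(np.triu(sub_w, k=1))
    edges = frozenset(tuple(sorted((genes[i], genes[j]))) for i, j in zip(ii, jj))
    return Subnetwork(
        center=center,
        k=k,
        nodes=genes,
        node_set=frozenset(genes),
        edge_set=edges,
        weights=sub_w,
        trans=sub_m,
        phase_label=net.phase_label,
        hop_dist=np.array([dist[i] for i in members], dtype=int),
    )


def dcgn_s(
    net_a: CoexNetwork,
    net_b: CoexNetwork,
    gene: str,
    k: int = 1,
    _sub_a: Subnetwork | None = None,
    _sub_b: Subnetwork | None = None,
) -> float:
    """Topological dissimilarity of a gene's k-neighbourhoods (DCGN-S).

    Returns ``1 - Jaccard(E_a, E_b)`` over the induced k-neighbourhood edge
    sets, and 0 when both edge sets are empty (a gene isolated in both
    phases shows no coexpression change).
    """
    sub_a = _sub_a or extract_subnetwork(net_a, gene, k)
    sub_b = _sub_b or extract_subnetwork(net_b, gene, k)
    ea, eb = sub_a.edge_set, sub_b.edge_set
    union = len(ea | eb)
    if union == 0:
        return 0.0
    return 1.0 - len(ea & eb) / union


def _max_hop_walk_probs(sub: Subnetwork) -> dict[str, float]:
    """Maximum walk probability over minimal-hop walks, centre -> every node.

    Layered dynamic program: any minimal-hop walk visits nodes of strictly
    increasing BFS depth, so best[v] at depth d is the max over neighbours u
    at depth d-1 of best[u] * m(u -> v).  Cached on the subnetwork.
    """
    if sub._pmax is not None:
        return sub._pmax
    n = len(sub.nodes)
    pos = {g: i for i, g in enumerate(sub.nodes)}
    c = pos[sub.center]
    adj = sub.weights > 0
    best = np.zeros(n)
    best[c] = 1.0
    depth = sub.hop_dist
    for d in range(1, int(depth.max(initial=0)) + 1):
        prev = np.flatnonzero(depth == d - 1)
        for v in np.flatnonzero(depth == d):
            cand = prev[adj[prev, v]]
            if cand.size:
                best[v] = float(np.max(best[cand] * sub.trans[cand, v]))
    sub._pmax = {g: float(best[pos[g]]) for g in sub.nodes if g != sub.center}
    return sub._pmax


def max_least_step_prob(sub: Subnetwork, target: str) -> float:
    """Maximum product of transition probabilities over minimal-hop walks
    from the subnetwork centre to ``target``."""
    if target == sub.center:
        raise ValueError("target must differ from the centre")
    if target not in sub.node_set:
        raise KeyError(f"{target!r} not in subnetwork of {sub.center!r}")
    p = _max_hop_walk_probs(sub)[target]
    assert p > 0, "members of the BFS ball are reachable by construction"
    return p


def star_transform(sub: Subnetwork) -> StarInfoNetwork:
    """Collapse a gene-centric subnetwork into its information star.

    Pipeline per partner j: maximal minimal-hop walk probability p_ij^max;
    normalization p_ij = p_ij^max / Σ p_ij^max; inverse renormalization
    q_ij = (1/p_ij) / Σ (1/p_ij) so that strong connections carry more
    information; information I_ij = -q_ij ln q_ij.
    """
    pmax = _max_hop_walk_probs(sub)
    if not pmax:
        return StarInfoNetwork(sub.center, {}, {}, {})
    partners = list(pmax)
    raw = np.array([pmax[j] for j in partners])
    p = raw / raw.sum()
    inv = 1.0 / p
    q = inv / inv.sum()
    with np.errstate(divide="ignore"):
        info = np.where(q >= 1.0, 0.0, -np.log(np.maximum(q, _LOG_FLOOR)) * q)
    return StarInfoNetwork(
        center=sub.center,
        norm_probs=dict(zip(partners, p.tolist())),
        partner_probs=dict(zip(partners, q.tolist())),
        partner_info=dict(zip(partners, info.tolist())),
    )


def dcgn_i(
    net_a: CoexNetwork,
    net_b: CoexNetwork,
    gene: str,
    k: int = 1,
    _sub_a: Subnetwork | None = None,
    _sub_b: Subnetwork | None = None,
) -> float:
    """Variation of local topological information of a gene (DCGN-I).

    Sums the information of neighbourhood members exclusive to phase A
    (taken from A's star) and of members exclusive to phase B (from B's
    star).  Zero when the two node sets coincide.
    """
    sub_a = _sub_a or extract_subnetwork(net_a, gene, k)
    sub_b = _sub_b or extract_subnetwork(net_b, gene, k)
    na = sub_a.node_set - {gene}
    nb = sub_b.node_set - {gene}
    total = 0.0
    only_a = na - nb
    if only_a:
        star = star_transform(sub_a)
        total += sum(star.partner_info[j] for j in only_a)
    only_b = nb - na
    if only_b:
        star = star_transform(sub_b)
        total += sum(star.partner_info[j] for j in only_b)
    return float(total)


def score_all(
    nets: list[CoexNetwork], metric: str, k: int = 1
) -> list[ScoreTable]:
    """Score every gene for every unordered pair of phase networks.

    All networks must share the same gene universe and order.  Returns one
    :class:`ScoreTable` per pair, C(N, 2) in total.
    """
    if metric not in ("S", "I"):
        raise ValueError("metric must be 'S' or 'I'")
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    genes = nets[0].gene_ids
    for net in nets[1:]:
        if net.gene_ids != genes:
            raise ValueError("all networks must share the same gene universe")
    labels = [net.phase_label for net in nets]
    if len(set(labels)) != len(labels):
        labels = [f"net{i}" for i in range(len(nets))]

    score_fn = dcgn_s if metric == "S" else dcgn_i
    # one subnetwork extraction per (network, gene), reused across pairs
    subs = [{g: extract_subnetwork(net, g, k) for g in genes} for net in nets]

    tables = []
    for ia, ib in itertools.combinations(range(len(nets)), 2):
        values = np.array(
            [
                score_fn(nets[ia], nets[ib], g, k,
                         _sub_a=subs[ia][g], _sub_b=subs[ib][g])
                for g in genes
            ]
        )
        tables.append(
            ScoreTable(
                gene_ids=list(genes),
                metric=metric,
                k=k,
                phase_pair=(labels[ia], labels[ib]),
                values=values,
            )
        )
    return tables
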