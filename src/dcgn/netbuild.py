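"""Construction of phase-specific weighted gene coexpression networks.

A coexpression network is built WGCNA-style from one expression matrix
(genes x samples) per phase / time point: the absolute Pearson correlation
between every pair of gene expression profiles is raised to a soft-threshold
power ``beta`` chosen so that the resulting degree distribution is
approximately scale-free, and weights below a hard cutoff ``tau`` are then
removed to sparsify the network.  Three aligned matrices describe each
network:

* ``W`` — symmetric weight matrix, entries in ``[0, 1)``, zero diagonal;
* ``A`` — binary adjacency, ``a_ij = 1`` iff ``w_ij != 0``;
* ``M`` — random-walk transition matrix, ``m_ij = w_ij / sum_j w_ij`` for
  nodes with at least one neighbour and an all-zero row otherwise.

Genes with zero expression variance cannot enter a correlation and are kept
as isolated nodes (all-zero weight row) so that gene indices stay aligned
across phases.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CoexNetwork",
    "NetworkBuildConfig",
    "DEFAULT_SOFT_POWER",
    "build_weight_matrix",
    "select_soft_power",
    "scale_free_fit",
    "transition_matrix",
    "network_similarity",
]

#: Fallback soft-threshold exponent when the scale-free scan is degenerate.
#: 6 is the conventional default for unsigned coexpression networks.
DEFAULT_SOFT_POWER = 6

#: Perfect correlations are clamped to 1 - _WEIGHT_EPS so weights stay in [0, 1).
_WEIGHT_EPS = 1e-12


@dataclass
class ExpressionMatrix:
    """Expression levels of ``n`` genes across ``m`` samples at one phase."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} genes x {m} samples"
            )
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if n < 2:
            raise ValueError("need at least 2 genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing data)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phase_label: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            phase_label=phase_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CoexNetwork:
    """One phase-specific weighted coexpression network.

    ``W``, ``A`` and ``M`` share the row/column order of ``gene_ids``.
    """

    gene_ids: list[str]
    W: np.ndarray
    A: np.ndarray
    M: np.ndarray
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self._index: dict[str, int] | None = None
        self._edge_set: frozenset[tuple[str, str]] | None = None
        self._neighbors: list[np.ndarray] | None = None

    @classmethod
    def from_weights(
        cls, gene_ids: list[str], W: np.ndarray, phase_label: str = ""
    ) -> "CoexNetwork":
        """Derive ``A`` and ``M`` from a weight matrix."""
        W = np.asarray(W, dtype=float)
        if W.shape[0] != W.shape[1] or W.shape[0] != len(gene_ids):
            raise ValueError("W must be square and match gene_ids")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        A = (W != 0).astype(np.int8)
        return cls(gene_ids=list(gene_ids), W=W, A=A, M=transition_matrix(W),
                   phase_label=phase_label)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
        return self._index

    def neighbors(self, i: int) -> np.ndarray:
        """Integer indices of the neighbours of node ``i`` (cached)."""
        if self._neighbors is None:
            self._neighbors = [np.flatnonzero(row) for row in self.A]
        return self._neighbors[i]

    def edge_set(self) -> frozenset[tuple[str, str]]:
        """Undirected edges as gene-ID pairs, smaller ID first."""
        if self._edge_set is None:
            ii, jj = np.nonzero(np.triu(self.W, k=1))
            g = self.gene_ids
            self._edge_set = frozenset(
                tuple(sorted((g[i], g[j]))) for i, j in zip(ii, jj)
            )
        return self._edge_set

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, k=1)))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    def to_graph(self):
        """networkx.Graph view (nodes = gene IDs, 'weight' attribute on edges)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        ii, jj = np.nonzero(np.triu(self.W, k=1))
        g.add_weighted_edges_from(
            (self.gene_ids[i], self.gene_ids[j], float(self.W[i, j]))
            for i, j in zip(ii, jj)
        )
        return g


@dataclass
class NetworkBuildConfig:
    """Parameters of the WGCNA-style network construction.

    ``power`` fixes the soft-threshold exponent directly; when ``None`` the
    exponent is chosen from ``power_grid`` by the scale-free criterion.
    """

    power_grid: tuple[int, ...] = tuple(range(1, 13))
    scale_free_r2_target: float = 0.8
    hard_weight_cutoff: float = 0.1
    correlation_kind: str = "pearson"
    power: int | None = None

    def __post_init__(self) -> None:
        if not self.power_grid:
            raise ValueError("power_grid must be nonempty")
        if any(b < 1 for b in self.power_grid):
            raise ValueError("all soft-threshold exponents must be >= 1")
        if not 0.0 <= self.hard_weight_cutoff < 1.0:
            raise ValueError("hard_weight_cutoff must be in [0, 1)")
        if self.correlation_kind != "pearson":
            raise ValueError("only Pearson correlation is supported")


def _abs_correlation(expr: ExpressionMatrix) -> np.ndarray:
    """|Pearson correlation| between gene profiles; zero-variance genes isolated."""
    if expr.n_samples < 3:
        raise ValueError(
            f"need at least 3 samples to estimate correlations, "
            f"got {expr.n_samples}"
        )
    sd = expr.values.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(expr.values)
    corr = np.nan_to_num(corr, nan=0.0)
    if zero_var.size:
        warnings.warn(
            f"{zero_var.size} gene(s) with zero expression variance kept as "
            f"isolated nodes: {[expr.gene_ids[i] for i in zero_var[:10]]}",
            stacklevel=3,
        )
        corr[zero_var, :] = 0.0
        corr[:, zero_var] = 0.0
    corr = np.abs(corr)
    np.fill_diagonal(corr, 0.0)
    # numerical noise can push |r| marginally over 1
    np.clip(corr, 0.0, 1.0, out=corr)
    return corr


def scale_free_fit(degrees: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10(frequency) ~ log10(degree) fit.

    Degrees are binned into ``n_bins`` histogram bins; the R^2 of the linear
    fit is negated when the slope is positive (a rising degree distribution is
    the opposite of scale-free).  Returns NaN when fewer than 3 distinct
    positive degrees (or fewer than 3 occupied bins) are available.
    """
    d = np.asarray(degrees, dtype=float)
    d = d[d > 0]
    if d.size == 0 or np.unique(d).size < 3:
        return float("nan")
    hist, edges = np.histogram(d, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = hist > 0
    if keep.sum() < 3:
        return float("nan")
    res = stats.linregress(np.log10(centers[keep]), np.log10(hist[keep]))
    r2 = float(res.rvalue**2)
    return r2 if res.slope < 0 else -r2


def _select_soft_power_from_corr(
    corr: np.ndarray, config: NetworkBuildConfig
) -> int:
    fits: list[tuple[int, float]] = []
    for beta in config.power_grid:
        w = corr**beta
        w = np.where(w < config.hard_weight_cutoff, 0.0, w)
        degrees = (w > 0).sum(axis=1)
        fits.append((beta, scale_free_fit(degrees)))
    valid = [(b, r2) for b, r2 in fits if np.isfinite(r2)]
    if not valid:
        warnings.warn(
            "degree distribution degenerate at every candidate exponent; "
            f"falling back to beta = {DEFAULT_SOFT_POWER}",
            stacklevel=3,
        )
        return DEFAULT_SOFT_POWER
    for beta, r2 in valid:
        if r2 >= config.scale_free_r2_target:
            return beta
    best_beta, best_r2 = max(valid, key=lambda br: br[1])
    warnings.warn(
        f"no soft-threshold exponent reached scale-free R^2 "
        f">= {config.scale_free_r2_target}; using argmax beta = {best_beta} "
        f"(R^2 = {best_r2:.3f})",
        stacklevel=3,
    )
    return best_beta


def select_soft_power(
    expr: ExpressionMatrix, config: NetworkBuildConfig | None = None
) -> int:
    """Smallest exponent in ``config.power_grid`` whose thresholded network
    passes the scale-free criterion (argmax-R^2 fallback with a warning)."""
    config = config or NetworkBuildConfig()
    return _select_soft_power_from_corr(_abs_correlation(expr), config)


def build_weight_matrix(
    expr: ExpressionMatrix, config: NetworkBuildConfig | None = None
) -> CoexNetwork:
    """Build one phase-specific coexpression network.

    ``w_ij = |pearson(x_i, x_j)|^beta`` with entries below the hard cutoff
    set to zero; perfect correlations are clamped to just below 1 so that
    weights live in ``[0, 1)``.  Adjacency and transition matrices are
    derived from the final ``W``.
    """
    config = config or NetworkBuildConfig()
    corr = _abs_correlation(expr)
    beta = config.power if config.power is not None else (
        _select_soft_power_from_corr(corr, config)
    )
    W = corr**beta
    np.minimum(W, 1.0 - _WEIGHT_EPS, out=W)
    W[W < config.hard_weight_cutoff] = 0.0
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return CoexNetwork.from_weights(expr.gene_ids, W, phase_label=expr.phase_label)


def transition_matrix(W: np.ndarray) -> np.ndarray:
    """Row-normalize a weight matrix into random-walk transition probabilities.

    ``m_ij = w_ij / sum_{j in N_i} w_ij`` when node ``i`` has neighbours,
    otherwise the row is all zeros.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("weight matrix must be nonnegative")
    row_sums = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.divide(W, row_sums, out=np.zeros_like(W), where=row_sums > 0)
    return M


def network_similarity(net_a: CoexNetwork, net_b: CoexNetwork) -> float:
    """Jaccard index of the two networks' global edge sets.

    Two edgeless networks are deemed identical (similarity 1) with a warning.
    """
    if net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must share the same gene universe and order")
    ea, eb = net_a.edge_set(), net_b.edge_set()
    union = len(ea | eb)
    if union == 0:
        warnings.warn("both networks are edgeless; similarity 1 by convention",
                      stacklevel=2)
        return 1.0
    return len(ea & eb) / union


def pairwise_similarities(nets: list[CoexNetwork]) -> pd.DataFrame:
    """Edge-set Jaccard similarity for every unordered pair of networks."""
    rows = []
    for a, b in itertools.combinations(nets, 2):
        rows.append(
            {"phase_a": a.phase_label, "phase_b": b.phase_label,
             "similarity": network_similarity(a, b)}
        )
    return pd.DataFrame(rows, columns=["phase_a", "phase_b", "similarity"])
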