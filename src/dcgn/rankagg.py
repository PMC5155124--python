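"""Rank-product aggregation of per-pair differential-coexpression scores.

Within each phase pair, genes are ranked in descending score order (rank 1 =
most differentially coexpressed; ties receive the average of the ranks they
span).  The comprehensive score of gene i over the C = N(N-1)/2 network
pairs is the geometric mean of its per-pair ranks,

    R_i = (prod_{pairs} r_i)^(1/C),

computed in log space, and the final priority list sorts R_i ascending
(ties broken lexicographically by gene ID for determinism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diffcoex import ScoreTable

__all__ = ["RankResult", "rank_scores", "rank_product", "aggregate_scores"]


@dataclass
class RankResult:
    """Final rank-product prioritization over all network pairs."""

    gene_ids: list[str]
    per_pair_ranks: dict[tuple[str, str], np.ndarray]
    rank_product: np.ndarray
    final_order: list[str]
    C: int

    def to_frame(self) -> pd.DataFrame:
        """One row per gene, sorted by final rank."""
        df = pd.DataFrame({"gene_id": self.gene_ids})
        for pair, ranks in self.per_pair_ranks.items():
            df[f"rank_{pair[0]}|{pair[1]}"] = ranks
        df["rank_product"] = self.rank_product
        order = {g: i + 1 for i, g in enumerate(self.final_order)}
        df["final_rank"] = [order[g] for g in self.gene_ids]
        return df.sort_values("final_rank", kind="stable").reset_index(drop=True)


def rank_scores(table: ScoreTable) -> np.ndarray:
    """Descending ranks of one score table (rank 1 = largest score).

    Ties are average-ranked, which keeps rank sums invariant.
    """
    values = np.asarray(table.values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("scores contain NaN")
    return rankdata(-values, method="average")


def rank_product(
    per_pair_ranks: dict[tuple[str, str], np.ndarray], gene_ids: list[str]
) -> RankResult:
    """Geometric mean of each gene's per-pair ranks, plus the final order."""
    if not per_pair_ranks:
        raise ValueError("need at least one pair of ranks")
    n = len(gene_ids)
    mat = []
    for pair, ranks in per_pair_ranks.items():
        ranks = np.asarray(ranks, dtype=float)
        if ranks.shape != (n,):
            raise ValueError(f"pair {pair} is missing ranks for some genes")
        if np.any(ranks <= 0) or np.isnan(ranks).any():
            raise ValueError(f"pair {pair} has invalid ranks")
        mat.append(ranks)
    log_ranks = np.log(np.vstack(mat))
    rp = np.exp(log_ranks.mean(axis=0))
    order = sorted(range(n), key=lambda i: (rp[i], gene_ids[i]))
    return RankResult(
        gene_ids=list(gene_ids),
        per_pair_ranks={p: np.asarray(r, dtype=float)
                        for p, r in per_pair_ranks.items()},
        rank_product=rp,
        final_order=[gene_ids[i] for i in order],
        C=len(per_pair_ranks),
    )


def aggregate_scores(tables: list[ScoreTable]) -> RankResult:
    """Rank each per-pair score table and aggregate by rank product."""
    if not tables:
        raise ValueError("no score tables given")
    genes = tables[0].gene_ids
    for t in tables[1:]:
        if t.gene_ids != genes:
            raise ValueError("score tables disagree on the gene universe")
    return rank_product({t.phase_pair: rank_scores(t) for t in tables}, genes)
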