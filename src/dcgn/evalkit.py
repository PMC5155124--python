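"""Evaluation of gene priority lists against labelled disease genes.

Provides ROC/AUC evaluation of a ranking against a disease / non-disease
gene labelling (genes tied on the rank product advance TPR and FPR as one
block), overlap tables between two rankings within rank ranges, and two
differential-*expression* rank-product baselines (fold-change and Welch t)
for comparison with the differential-coexpression scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .netbuild import ExpressionMatrix
from .rankagg import RankResult, rank_product

__all__ = [
    "LabeledGeneSet",
    "EvalResult",
    "roc_auc",
    "overlap_table",
    "rp_baselines",
]


@dataclass
class LabeledGeneSet:
    """Disjoint sets of known disease and non-disease gene IDs."""

    disease: frozenset[str]
    nondisease: frozenset[str]

    def __post_init__(self) -> None:
        self.disease = frozenset(self.disease)
        self.nondisease = frozenset(self.nondisease)
        if self.disease & self.nondisease:
            raise ValueError("a gene cannot be both disease and non-disease")

    def restrict(self, universe: Sequence[str]) -> "LabeledGeneSet":
        """Drop labelled genes outside the scored universe (with a warning)."""
        uni = set(universe)
        dropped = (self.disease | self.nondisease) - uni
        if dropped:
            warnings.warn(
                f"{len(dropped)} labelled gene(s) absent from the ranking "
                "were dropped", stacklevel=2,
            )
        return LabeledGeneSet(self.disease & uni, self.nondisease & uni)


@dataclass
class EvalResult:
    """ROC curve and its area for one ranking."""

    roc_points: np.ndarray  # (n_vertices, 2) columns FPR, TPR
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])


def _ranking_scores(ranking: RankResult | Sequence[str]) -> tuple[list[str], np.ndarray]:
    """Gene list plus a 'larger = stronger candidate' score per gene.

    For a :class:`RankResult` the score is the negated rank product, so genes
    sharing an R value form a genuine tie block on the ROC curve.  For a
    plain ordered gene list, positions are used (no ties).
    """
    if isinstance(ranking, RankResult):
        return list(ranking.gene_ids), -np.asarray(ranking.rank_product, dtype=float)
    genes = list(ranking)
    return genes, -np.arange(len(genes), dtype=float)


def roc_auc(ranking: RankResult | Sequence[str], labels: LabeledGeneSet) -> EvalResult:
    """ROC curve and AUC of a ranking against disease labels.

    Sweeps a cutoff down the priority list; at each cutoff TPR is the
    fraction of disease genes above it and FPR the fraction of non-disease
    genes above it.  AUC is the trapezoidal area; unlabelled genes are
    ignored.
    """
    genes, scores = _ranking_scores(ranking)
    labels = labels.restrict(genes)
    keep = [i for i, g in enumerate(genes)
            if g in labels.disease or g in labels.nondisease]
    y = np.array([1 if genes[i] in labels.disease else 0 for i in keep])
    s = scores[keep]
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one disease and one non-disease gene")
    fpr, tpr, _ = skm.roc_curve(y, s, drop_intermediate=False)
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        auc=float(skm.auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def plot_roc(results: dict[str, EvalResult], path) -> None:
    """Write a ROC figure (one curve per labelled result) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        ax.plot(res.roc_points[:, 0], res.roc_points[:, 1],
                label=f"{name} (AUC = {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def overlap_table(
    list_a: Sequence[str],
    list_b: Sequence[str],
    ranges: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Overlap of two rankings within half-open rank intervals ``[a, b)``.

    The default intervals are consecutive blocks of 1000 covering the list.
    Ranges beyond the list length are truncated with a warning; the fraction
    divides by the (possibly truncated) range length.
    """
    if set(list_a) != set(list_b):
        raise ValueError("rankings must cover the same gene universe")
    n = len(list_a)
    if ranges is None:
        step = 1000
        ranges = [(s, min(s + step, n)) for s in range(0, n, step)]
    rows = []
    for start, stop in ranges:
        if start < 0 or stop <= start:
            raise ValueError(f"invalid range [{start}, {stop})")
        if stop > n:
            warnings.warn(
                f"range [{start}, {stop}) exceeds list length {n}; truncated",
                stacklevel=2,
            )
            stop = n
        seg_a, seg_b = set(list_a[start:stop]), set(list_b[start:stop])
        count = len(seg_a & seg_b)
        length = stop - start
        rows.append({"start": start, "stop": stop, "overlap": count,
                     "fraction": count / length if length else float("nan")})
    return pd.DataFrame(rows, columns=["start", "stop", "overlap", "fraction"])


def rp_baselines(exprs: list[ExpressionMatrix], mode: str = "FC") -> RankResult:
    """Differential-expression rank-product baselines RP-FC and RP-t.

    For every phase pair, each gene is scored by the absolute mean expression
    difference (``mode='FC'``; expression is assumed to be on a log-like
    scale already) or by the absolute Welch t statistic (``mode='t'``),
    ranked descending, and the per-pair ranks are aggregated with the same
    rank product used for the coexpression scores.  A comparison
    convenience, not a method contribution.
    """
    if mode not in ("FC", "t"):
        raise ValueError("mode must be 'FC' or 't'")
    if len(exprs) < 2:
        raise ValueError("need at least two phases")
    genes = exprs[0].gene_ids
    for e in exprs[1:]:
        if e.gene_ids != genes:
            raise ValueError("phases disagree on the gene universe")
    labels = [e.phase_label or f"phase{i}" for i, e in enumerate(exprs)]

    per_pair = {}
    for ia, ib in itertools.combinations(range(len(exprs)), 2):
        xa, xb = exprs[ia].values, exprs[ib].values
        if mode == "FC":
            score = np.abs(xa.mean(axis=1) - xb.mean(axis=1))
        else:
            if xa.shape[1] < 2 or xb.shape[1] < 2:
                raise ValueError("mode 't' needs >= 2 samples per phase")
            with np.errstate(invalid="ignore", divide="ignore"):
                t, _ = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
            score = np.abs(t)
            degenerate = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
            if degenerate.any():
                warnings.warn(
                    f"{int(degenerate.sum())} gene(s) with zero within-phase "
                    "variance; t statistic set to +inf", stacklevel=2,
                )
                score[degenerate] = np.inf
            score = np.nan_to_num(score, nan=0.0, posinf=np.inf)
        per_pair[(labels[ia], labels[ib])] = stats.rankdata(-score, method="average")
    return rank_product(per_pair, genes)
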