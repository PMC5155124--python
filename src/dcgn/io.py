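"""Reading and writing the package's file formats.

Expression matrices are TSV/CSV with gene IDs in the first column and
sample IDs in the header; networks are 3-column weighted edge lists (each
undirected edge written once, lexicographically smaller ID first) or
GraphML; score tables, rankings and labels are plain TSV.  All numeric
output uses a fixed ``%.12g`` format so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .diffcoex import ScoreTable
from .evalkit import LabeledGeneSet
from .netbuild import CoexNetwork, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "write_edge_list",
    "read_edge_list",
    "read_edge_lists",
    "write_graphml",
    "write_score_table",
    "read_score_table",
    "read_labels",
    "write_labels",
    "load_yaml_config",
]

FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_expression(path: str | Path, phase_label: str | None = None) -> ExpressionMatrix:
    """Load a genes x samples TSV/CSV (delimiter sniffed automatically)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix.from_dataframe(
        df, phase_label=phase_label if phase_label is not None else path.stem
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_dataframe().to_csv(Path(path), sep="\t", float_format=FLOAT_FMT,
                               index_label="gene_id")


def write_edge_list(net: CoexNetwork, path: str | Path) -> None:
    """Write the network as a sorted 3-column weighted edge list."""
    idx = net.index()
    rows = sorted(net.edge_set())
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\t{_fmt(net.W[idx[a], idx[b]])}\n")


def read_edge_list(
    path: str | Path,
    gene_ids: Sequence[str] | None = None,
    phase_label: str | None = None,
) -> CoexNetwork:
    """Load a weighted edge list into a network.

    When ``gene_ids`` is omitted, the universe is the sorted union of the
    endpoints in the file; pass an explicit universe to keep the matrix
    order aligned across phases.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if gene_ids is None:
        gene_ids = sorted(set(df["gene_a"].astype(str)) | set(df["gene_b"].astype(str)))
    genes = [str(g) for g in gene_ids]
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for a, b, w in zip(df["gene_a"].astype(str), df["gene_b"].astype(str),
                       df["weight"].astype(float)):
        if a not in idx or b not in idx:
            raise ValueError(f"edge endpoint outside the gene universe: {a}-{b}")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return CoexNetwork.from_weights(
        genes, W,
        phase_label=phase_label if phase_label is not None else path.stem,
    )


def read_edge_lists(paths: Sequence[str | Path]) -> list[CoexNetwork]:
    """Load several phase edge lists over a shared, consistently ordered
    gene universe (sorted union of all endpoints)."""
    frames = [pd.read_csv(Path(p), sep="\t") for p in paths]
    universe: set[str] = set()
    for df in frames:
        universe |= set(df["gene_a"].astype(str)) | set(df["gene_b"].astype(str))
    genes = sorted(universe)
    return [read_edge_list(p, gene_ids=genes) for p in paths]


def write_graphml(net: CoexNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_graph(), str(path))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(Path(path), sep="\t", index=False,
                            float_format=FLOAT_FMT)


def read_score_table(path: str | Path) -> ScoreTable:
    df = pd.read_csv(Path(path), sep="\t")
    pair = str(df["phase_pair"].iloc[0]).split("|")
    return ScoreTable(
        gene_ids=list(df["gene_id"].astype(str)),
        metric=str(df["metric"].iloc[0]),
        k=int(df["k"].iloc[0]),
        phase_pair=(pair[0], pair[1]),
        values=df["value"].to_numpy(dtype=float),
    )


def read_labels(path: str | Path) -> LabeledGeneSet:
    """Two-column TSV: gene_id, label (1 = disease, 0 = non-disease)."""
    df = pd.read_csv(Path(path), sep="\t")
    gene_col, label_col = df.columns[:2]
    genes = df[gene_col].astype(str)
    lab = df[label_col].astype(int)
    return LabeledGeneSet(
        disease=frozenset(genes[lab == 1]),
        nondisease=frozenset(genes[lab == 0]),
    )


def write_labels(labels: LabeledGeneSet, path: str | Path) -> None:
    rows = sorted([(g, 1) for g in labels.disease]
                  + [(g, 0) for g in labels.nondisease])
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g, lab in rows:
            fh.write(f"{g}\t{lab}\n")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
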