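"""End-to-end orchestration: build networks, score, aggregate, evaluate.

:func:`run_pipeline` executes the whole framework on a list of phase
expression matrices — phase-specific network construction, per-pair
differential-coexpression scoring for the requested metric(s), rank-product
aggregation, and (when labels are supplied) ROC/AUC evaluation plus an
overlap table between the two metric rankings — writing every artifact to
an output directory together with a JSON manifest.  All output is
deterministic under a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as dio
from .diffcoex import score_all
from .evalkit import LabeledGeneSet, overlap_table, roc_auc
from .netbuild import NetworkBuildConfig, build_weight_matrix, pairwise_similarities
from .rankagg import RankResult, aggregate_scores

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("dcgn")

VERSION = "1.0.0"


@dataclass(kw_only=True)
class PipelineConfig:
    """Everything one run needs; phases may be in-memory or file paths."""

    outdir: Path
    expressions: list | None = None  # list[ExpressionMatrix]
    phase_files: list[Path] | None = None
    build: NetworkBuildConfig = field(default_factory=NetworkBuildConfig)
    metrics: tuple[str, ...] = ("S", "I")
    k: int = 1
    labels: LabeledGeneSet | str | Path | None = None
    seed: int = 0
    write_graphml: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.expressions is None and not self.phase_files:
            raise ValueError("provide expressions or phase_files")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        bad = set(self.metrics) - {"S", "I"}
        if bad:
            raise ValueError(f"unknown metrics: {bad}")

    def describe(self) -> dict:
        """JSON-serializable summary used for the manifest config hash."""
        return {
            "phase_files": [str(p) for p in self.phase_files or []],
            "n_expressions": len(self.expressions or []),
            "build": {
                "power_grid": list(self.build.power_grid),
                "scale_free_r2_target": self.build.scale_free_r2_target,
                "hard_weight_cutoff": self.build.hard_weight_cutoff,
                "power": self.build.power,
            },
            "metrics": list(self.metrics),
            "k": self.k,
            "seed": self.seed,
        }


def _load_labels(config: PipelineConfig) -> LabeledGeneSet | None:
    if config.labels is None:
        return None
    if isinstance(config.labels, LabeledGeneSet):
        return config.labels
    return dio.read_labels(config.labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full framework and return the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": VERSION,
        "config": config.describe(),
        "stages": {},
        "outputs": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    # --- load phases -------------------------------------------------------
    if config.expressions is not None:
        exprs = list(config.expressions)
    else:
        exprs = [dio.read_expression(p) for p in config.phase_files]
    if len(exprs) < 2:
        raise ValueError("need at least two phases")
    genes = exprs[0].gene_ids
    for e in exprs[1:]:
        if e.gene_ids != genes:
            raise ValueError("phases disagree on the gene universe/order")
    manifest["stages"]["input"] = {
        "n_phases": len(exprs),
        "n_genes": len(genes),
        "n_samples": [e.n_samples for e in exprs],
    }

    # --- networks ----------------------------------------------------------
    logger.info("building %d phase-specific networks", len(exprs))
    nets = [build_weight_matrix(e, config.build) for e in exprs]
    for net in nets:
        dio.write_edge_list(net, record(out / f"network_{net.phase_label}.edges.tsv"))
        if config.write_graphml:
            dio.write_graphml(net, record(out / f"network_{net.phase_label}.graphml"))
    sims = pairwise_similarities(nets)
    sims.to_csv(record(out / "network_similarity.tsv"), sep="\t", index=False,
                float_format=dio.FLOAT_FMT)
    manifest["stages"]["netbuild"] = {
        "n_networks": len(nets),
        "n_edges": [net.n_edges for net in nets],
    }

    # --- scoring and aggregation -------------------------------------------
    rankings: dict[str, RankResult] = {}
    for metric in config.metrics:
        logger.info("scoring metric %s at k=%d", metric, config.k)
        tables = score_all(nets, metric, config.k)
        for t in tables:
            name = f"scores_{metric}_k{config.k}_{t.phase_pair[0]}_{t.phase_pair[1]}.tsv"
            dio.write_score_table(t, record(out / name))
        result = aggregate_scores(tables)
        rankings[metric] = result
        result.to_frame().to_csv(
            record(out / f"ranks_{metric}_k{config.k}.tsv"),
            sep="\t", index=False, float_format=dio.FLOAT_FMT,
        )
        manifest["stages"][f"score_{metric}"] = {
            "n_pairs": len(tables),
            "n_genes": len(result.gene_ids),
        }

    # --- evaluation --------------------------------------------------------
    labels = _load_labels(config)
    if labels is not None:
        summary = {}
        for metric, result in rankings.items():
            ev = roc_auc(result, labels)
            ev.to_frame().to_csv(
                record(out / f"roc_{metric}_k{config.k}.tsv"),
                sep="\t", index=False, float_format=dio.FLOAT_FMT,
            )
            summary[metric] = {"auc": round(ev.auc, 12),
                               "n_pos": ev.n_pos, "n_neg": ev.n_neg}
        with open(record(out / "evaluation.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["stages"]["evaluate"] = summary
    if len(rankings) == 2:
        ov = overlap_table(rankings["S"].final_order, rankings["I"].final_order,
                           ranges=[(0, max(1, len(genes) // 4))])
        ov.to_csv(record(out / "overlap_S_vs_I.tsv"), sep="\t", index=False,
                  float_format=dio.FLOAT_FMT)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
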