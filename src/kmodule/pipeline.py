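"""End-to-end pipeline: similarity -> adjacency -> TOM -> dendrogram ->
dynamic cut -> optional refinement, with a reproducibility manifest.

Two stages mirror the method's structure: the network stage detects modules
by hierarchical clustering of TOM dissimilarity, and the refinement stage
re-adjusts labels with the k-module algorithm (or the k-eigengene
comparator for comparison).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_CUT_HEIGHT,
    DEFAULT_MIN_MODULE_SIZE,
    ModulePartition,
    average_linkage_tree,
    dynamic_tree_cut,
)
from .correlation import pairwise_similarity
from .evaluate import change_rate, dunn_index, proportion_highest_mc, silhouette_mean
from .exprdata import ExpressionMatrix, cv_filter, read_expression
from .network import (
    DEFAULT_CANDIDATE_BETAS,
    DEFAULT_N_BINS,
    DEFAULT_R2_CUT,
    adjacency,
    dissimilarity,
    pick_soft_threshold,
    tom,
    write_sft_table,
)
from .refine import DEFAULT_MAX_ITER, k_eigengene_refine, k_module_refine

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "detect_modules", "run_pipeline", "replay"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline; defaults match the module-level defaults."""

    correlation_method: str = "distance-correlation"
    cv_threshold: float | None = None
    require_above_mean_intensity: bool = False
    candidate_betas: tuple = DEFAULT_CANDIDATE_BETAS
    r2_cut: float = DEFAULT_R2_CUT
    n_bins: int = DEFAULT_N_BINS
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    cut_height: float = DEFAULT_CUT_HEIGHT
    cut_height_absolute: bool = False
    refinement: str = "k-module"   # none | k-module | k-eigengene | both
    max_iter: int = DEFAULT_MAX_ITER
    reassign_grey: bool = False
    denominator: str = "literal"
    evaluate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.refinement not in ("none", "k-module", "k-eigengene", "both"):
            raise ValueError(f"unknown refinement {self.refinement!r}")
        object.__setattr__(self, "candidate_betas", tuple(self.candidate_betas))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidate_betas"] = list(self.candidate_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "candidate_betas" in d:
            d["candidate_betas"] = tuple(d["candidate_betas"])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def detect_modules(expr: ExpressionMatrix, config: PipelineConfig) -> dict:
    """Run the network stage and both refiners on one expression matrix.

    Returns a dict with the intermediates and the partitions keyed by
    method name: "wgcna" (raw dynamic cut), "k-module", "k-eigengene".
    """
    sim = pairwise_similarity(expr, method=config.correlation_method)
    beta, sft_table = pick_soft_threshold(
        sim, config.candidate_betas, r2_cut=config.r2_cut, n_bins=config.n_bins,
        n_samples=expr.n_samples,
    )
    net = tom(adjacency(sim, beta))
    diss = dissimilarity(net)
    tree = average_linkage_tree(diss, gene_ids=expr.gene_ids)
    cut = dynamic_tree_cut(
        tree,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        absolute_height=config.cut_height_absolute,
    )
    out = {
        "similarity": sim,
        "beta": beta,
        "sft_table": sft_table,
        "network": net,
        "dissimilarity": diss,
        "tree": tree,
        "wgcna": cut,
    }
    if cut.n_modules:
        km = k_module_refine(
            cut, net.adjacency, max_iter=config.max_iter,
            reassign_grey=config.reassign_grey, denominator=config.denominator,
        )
        ke = k_eigengene_refine(
            expr, cut, max_iter=config.max_iter, reassign_grey=config.reassign_grey
        )
        out["k-module"] = km.partition
        out["k-eigengene"] = ke.partition
        out["k-module-result"] = km
        out["k-eigengene-result"] = ke
    else:
        logger.warning("dynamic cut produced no module; refinement skipped")
        out["k-module"] = cut
        out["k-eigengene"] = cut
    return out


def _write_refinement_log(result, path: Path) -> None:
    pd.DataFrame(
        {
            "iteration": np.arange(1, result.iterations + 1),
            "n_changes": list(result.changes_per_iteration),
        }
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, expr_path, outdir) -> Path:
    """Execute the full pipeline on a delimited expression file and write a
    run directory: partitions before/after refinement, SFT diagnostics,
    metrics report, refinement logs, and a manifest that reproduces the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("[%s] %.1fs", name, time.time() - t0)

    expr = read_expression(expr_path)
    stage("read")
    if config.cv_threshold is not None:
        expr, report = cv_filter(
            expr, config.cv_threshold,
            require_above_mean_intensity=config.require_above_mean_intensity,
            return_report=True,
        )
        report[~report["kept"]].to_csv(outdir / "removed_genes.tsv", sep="\t", index=False)
        expr.write(outdir / "filtered_expression.tsv")
        stage("cv_filter")
    try:
        stages = detect_modules(expr, config)
    except Exception as exc:
        raise RuntimeError(f"network stage failed on {expr_path}: {exc}") from exc
    stage("network+cut")
    write_sft_table(stages["sft_table"], outdir / "sft_table.tsv")
    stages["wgcna"].write_tsv(outdir / "partition_wgcna.tsv")
    stages["tree"].write_tsv(outdir / "dendrogram.tsv")

    methods = {"none": [], "k-module": ["k-module"], "k-eigengene": ["k-eigengene"],
               "both": ["k-module", "k-eigengene"]}[config.refinement]
    summaries = {}
    for m in methods:
        key = f"{m}-result"
        if key in stages:
            stages[m].write_tsv(outdir / f"partition_{m.replace('-', '_')}.tsv")
            _write_refinement_log(stages[key], outdir / f"refinement_log_{m.replace('-', '_')}.tsv")
            summaries[m] = stages[key].summary()
    if config.refinement == "none":
        stages["wgcna"].write_tsv(outdir / "partition_refined.tsv")
    metrics = {}
    if config.evaluate and stages["wgcna"].n_modules >= 2:
        diss = stages["dissimilarity"]
        adj = stages["network"].adjacency
        for name in ["wgcna"] + methods:
            part = stages[name]
            metrics[name] = {
                "n_modules": part.n_modules,
                "n_grey": part.n_grey,
                "silhouette": silhouette_mean(diss, part) if part.n_modules >= 2 else None,
                "dunn": dunn_index(diss, part) if part.n_modules >= 2 else None,
                "proportion_highest_mc": proportion_highest_mc(
                    part, adj, denominator=config.denominator
                ),
            }
            if name != "wgcna":
                metrics[name]["change_rate_vs_wgcna"] = change_rate(stages["wgcna"], part)
    summary = {
        "beta": float(stages["beta"]),
        "n_genes": expr.n_genes,
        "n_samples": expr.n_samples,
        "refinement": summaries,
        "metrics": metrics,
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {
        "config": config.to_dict(),
        "expr_path": str(Path(expr_path).resolve()),
        "versions": {
            "kmodule": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    stage("done")
    return outdir


def replay(manifest_path, outdir) -> Path:
    """Re-execute a run from its manifest; outputs are identical bytes."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, manifest["expr_path"], outdir)
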