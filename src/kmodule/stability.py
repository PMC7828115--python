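"""Module preservation between partitions from independent sample splits.

Two module detections on disjoint sample halves (or k folds) are compared
module-by-module with a one-sided Fisher's exact test on the overlap: for
modules A_i (size K) and B_j (size N) over n common genes with overlap o,
p = P(X >= o) for X hypergeometric(n, K, N).  The tail is evaluated in log
space so overlaps of large identical modules — p-values far below the
smallest positive double — still yield finite preservation significance
-log10(p).  A module counts as preserved when its best significance over
the other partition's non-grey modules exceeds a cut (50 by default, i.e.
p < 1e-50).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .clustering import GREY, ModulePartition
from .exprdata import ExpressionMatrix, split_samples

logger = logging.getLogger(__name__)

__all__ = [
    "PreservationTable",
    "overlap_fisher",
    "preservation_count",
    "stability_report",
    "split_stability",
]

DEFAULT_SIGNIFICANCE_CUT = 50.0
NEG_LOG10_P_CAP = 1e6
_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PreservationTable:
    """Module x module overlap counts and -log10 one-sided Fisher p-values.

    Rows index partition A's labels, columns partition B's; the grey label
    (0) is included for display but excluded from significance counting.
    """

    overlap_counts: pd.DataFrame
    neg_log10_p: pd.DataFrame

    @property
    def modules_a(self) -> tuple:
        return tuple(self.overlap_counts.index)

    @property
    def modules_b(self) -> tuple:
        return tuple(self.overlap_counts.columns)

    def transpose(self) -> "PreservationTable":
        return PreservationTable(self.overlap_counts.T, self.neg_log10_p.T)

    def write_tsv(self, counts_path, neg_log10_p_path) -> None:
        self.overlap_counts.to_csv(counts_path, sep="\t", index_label="module_a")
        self.neg_log10_p.to_csv(neg_log10_p_path, sep="\t", index_label="module_a")

    def render(self, significance_cut: float = DEFAULT_SIGNIFICANCE_CUT) -> str:
        """Plain-text heat summary: overlap counts, with '*' marking cells
        whose preservation significance exceeds the cut."""
        lines = ["\t" + "\t".join(str(m) for m in self.modules_b)]
        for i in self.modules_a:
            cells = []
            for j in self.modules_b:
                mark = "*" if self.neg_log10_p.loc[i, j] > significance_cut else ""
                cells.append(f"{int(self.overlap_counts.loc[i, j])}{mark}")
            lines.append(f"{i}\t" + "\t".join(cells))
        return "\n".join(lines)


def log10_fisher_tail(o: int, n: int, size_a: int, size_b: int) -> float:
    """-log10 of the one-sided Fisher (hypergeometric upper-tail) p-value
    P(X >= o) for overlap o of module sizes size_a, size_b in n genes.

    Exact summation of log-pmf terms; capped at 1e6 for display.
    """
    lo = max(0, size_a + size_b - n)
    hi = min(size_a, size_b)
    if o <= lo:
        return 0.0
    ks = np.arange(o, hi + 1)
    logpmf = (
        gammaln(size_a + 1) - gammaln(ks + 1) - gammaln(size_a - ks + 1)
        + gammaln(n - size_a + 1) - gammaln(size_b - ks + 1)
        - gammaln(n - size_a - size_b + ks + 1)
        - (gammaln(n + 1) - gammaln(size_b + 1) - gammaln(n - size_b + 1))
    )
    logp = logsumexp(logpmf)
    return float(min(-logp / _LN10, NEG_LOG10_P_CAP))


def overlap_fisher(part_a: ModulePartition, part_b: ModulePartition) -> PreservationTable:
    """Overlap counts and preservation significance for every module pair.

    Both partitions must cover the identical gene set; genes are aligned by
    identifier.  Grey rows/columns appear in the output (their overlaps are
    reported like any other) but downstream significance counting skips them.
    """
    if set(part_a.gene_ids) != set(part_b.gene_ids):
        raise ValueError("partitions must cover the same gene set")
    order = {g: i for i, g in enumerate(part_b.gene_ids)}
    b_aligned = part_b.labels[[order[g] for g in part_a.gene_ids]]
    n = part_a.n_genes
    labels_a = sorted(np.unique(part_a.labels))
    labels_b = sorted(np.unique(b_aligned))
    counts = pd.crosstab(
        pd.Series(part_a.labels, name="a"), pd.Series(b_aligned, name="b")
    ).reindex(index=labels_a, columns=labels_b, fill_value=0)
    sizes_a = counts.sum(axis=1)
    sizes_b = counts.sum(axis=0)
    neg = pd.DataFrame(0.0, index=labels_a, columns=labels_b)
    for i in labels_a:
        for j in labels_b:
            neg.loc[i, j] = log10_fisher_tail(
                int(counts.loc[i, j]), n, int(sizes_a[i]), int(sizes_b[j])
            )
    return PreservationTable(counts, neg)


def preservation_count(
    table: PreservationTable, significance_cut: float = DEFAULT_SIGNIFICANCE_CUT
) -> int:
    """Number of row-partition modules whose best preservation significance
    over the other partition's non-grey modules exceeds the cut."""
    if significance_cut <= 0:
        raise ValueError("significance_cut must be > 0")
    rows = [m for m in table.modules_a if m != GREY]
    cols = [m for m in table.modules_b if m != GREY]
    if not rows or not cols:
        return 0
    best = table.neg_log10_p.loc[rows, cols].max(axis=1)
    return int((best > significance_cut).sum())


def _run_part(part: ExpressionMatrix, config):
    """Similarity -> soft threshold -> TOM -> tree -> cut on one sample part."""
    from .pipeline import PipelineConfig, detect_modules  # local import: avoid cycle

    cfg = config if config is not None else PipelineConfig()
    return detect_modules(part, cfg)


def stability_report(
    parts,
    config=None,
    methods=("wgcna", "k-module", "k-eigengene"),
    significance_cut: float = DEFAULT_SIGNIFICANCE_CUT,
):
    """Preservation counts across every unordered pair of pre-split parts.

    Each part is processed independently through the full pipeline; for each
    method the partition is the raw dynamic-cut result ("wgcna") or its
    k-module / k-eigengene refinement.  Returns ``(report, pair_counts)``:
    a per-method DataFrame with mean/min/max preservation counts, and the
    per-pair counts dict.  The count for an unordered pair uses the
    earlier-indexed part as the row partition.
    """
    partitions = {m: [] for m in methods}
    for part in parts:
        stage = _run_part(part, config)
        for m in methods:
            partitions[m].append(stage[m])
    pair_counts = {m: [] for m in methods}
    for i, j in itertools.combinations(range(len(parts)), 2):
        for m in methods:
            table = overlap_fisher(partitions[m][i], partitions[m][j])
            pair_counts[m].append(preservation_count(table, significance_cut))
    report = pd.DataFrame(
        {
            "method": list(methods),
            "mean": [float(np.mean(pair_counts[m])) for m in methods],
            "min": [int(np.min(pair_counts[m])) for m in methods],
            "max": [int(np.max(pair_counts[m])) for m in methods],
        }
    )
    return report, pair_counts


def split_stability(
    expr: ExpressionMatrix,
    config=None,
    n_parts: int = 2,
    seed: int = 0,
    methods=("wgcna", "k-module", "k-eigengene"),
    significance_cut: float = DEFAULT_SIGNIFICANCE_CUT,
):
    """Split the samples into ``n_parts`` folds, run the full pipeline on
    each independently, and report per-method preservation counts over all
    unordered fold pairs (mean and min-max range)."""
    parts = split_samples(expr, n_parts, seed)
    return stability_report(parts, config=config, methods=methods,
                            significance_cut=significance_cut)
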