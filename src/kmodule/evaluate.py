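"""Cluster-validity metrics and refinement diagnostics.

Silhouette and Dunn are computed on whatever dissimilarity the clustering
itself used (TOM dissimilarity by default in the pipeline); grey genes are
unassigned by definition and are excluded from both.
"""

from __future__ import annotations

import numpy as np

from .clustering import GREY, ModulePartition
from .refine import DENOMINATORS, _mc_matrix

__all__ = ["silhouette_mean", "dunn_index", "proportion_highest_mc", "change_rate"]


def _nongrey(diss: np.ndarray, partition: ModulePartition):
    mask = partition.labels != GREY
    idx = np.flatnonzero(mask)
    return np.asarray(diss, dtype=float)[np.ix_(idx, idx)], partition.labels[idx]


def silhouette_mean(diss, partition: ModulePartition) -> float:
    """Mean silhouette width of the non-grey genes.

    Per gene: a = mean dissimilarity to the other members of its own module,
    b = the smallest mean dissimilarity to any other module, and
    s = (b - a) / max(a, b).  Members of singleton modules contribute s = 0
    (standard convention).  Result lies in [-1, 1].
    """
    d, labels = _nongrey(diss, partition)
    mods = np.unique(labels)
    if len(mods) < 2:
        raise ValueError("silhouette needs at least 2 non-grey modules")
    indicator = (labels[:, None] == mods[None, :]).astype(float)
    sums = d @ indicator                      # (n, k) total dissimilarity per module
    sizes = indicator.sum(axis=0)
    own_col = np.searchsorted(mods, labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        size_own = sizes[own_col[i]]
        if size_own <= 1:
            continue
        a = sums[i, own_col[i]] / (size_own - 1)   # d_ii = 0
        other = [sums[i, c] / sizes[c] for c in range(len(mods)) if c != own_col[i]]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def dunn_index(diss, partition: ModulePartition) -> float:
    """Smallest between-module dissimilarity over largest within-module
    dissimilarity (grey excluded).  Higher is better."""
    d, labels = _nongrey(diss, partition)
    if len(np.unique(labels)) < 2:
        raise ValueError("Dunn index needs at least 2 non-grey modules")
    same = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(len(labels), dtype=bool)
    intra = d[same & offdiag]
    max_intra = intra.max() if intra.size else 0.0
    if max_intra == 0:
        raise ValueError("maximum intra-module dissimilarity is 0; Dunn index undefined")
    min_inter = d[~same].min()
    return float(min_inter / max_intra)


def proportion_highest_mc(
    partition: ModulePartition, adj, denominator: str = "literal"
) -> float:
    """Fraction of non-grey genes already sitting in the module to which they
    have the highest mean connectivity (ties count as satisfying).

    Equals 1.0 exactly on any converged k-module refinement output — that is
    the algorithm's defining fixed-point property.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    module_ids = list(partition.module_ids)
    if not module_ids:
        raise ValueError("partition has no non-grey module")
    a = np.asarray(adj, dtype=float)
    mc = _mc_matrix(a, partition.labels, module_ids, denominator)
    col_of = {m: c for c, m in enumerate(module_ids)}
    idx = np.flatnonzero(partition.labels != GREY)
    own = np.array([col_of[int(partition.labels[i])] for i in idx])
    rows = mc[idx]
    satisfied = rows[np.arange(len(idx)), own] >= rows.max(axis=1)
    return float(satisfied.mean())


def change_rate(before: ModulePartition, after: ModulePartition) -> float:
    """Fraction of genes whose module label differs between two partitions
    over the identical gene set."""
    if before.gene_ids != after.gene_ids:
        raise ValueError("partitions must share an identical gene set and order")
    return float((before.labels != after.labels).mean())
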