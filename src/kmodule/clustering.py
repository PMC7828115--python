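"""Average-linkage hierarchical clustering and dynamic tree cut into modules.

Genes are clustered with UPGMA on the TOM dissimilarity; branches of the
dendrogram are modules.  The tree-cut here is the "tree" variant of dynamic
tree cut: all merges above a cut height are severed, the resulting subtrees
are candidate branches, and branches with at least ``min_module_size``
leaves become modules.  Everything else is assigned to the grey
(unassigned) pool, label 0.  Module labels 1..k are ordered by decreasing
size (ties by first-gene index), mirroring the size-ordered color
convention of co-expression tools without naming colors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["ModulePartition", "Dendrogram", "average_linkage_tree", "dynamic_tree_cut"]

GREY = 0

DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.99


@dataclass(frozen=True)
class ModulePartition:
    """Gene -> module-label map; label 0 is the grey (unassigned) pool."""

    gene_ids: tuple
    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (len(self.gene_ids),):
            raise ValueError("labels must be one per gene")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative (0 = grey)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def module_ids(self) -> tuple:
        """Sorted non-grey module labels present in the partition."""
        return tuple(int(m) for m in np.unique(self.labels) if m != GREY)

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    @property
    def n_grey(self) -> int:
        return int((self.labels == GREY).sum())

    def module_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(m): int(c) for m, c in zip(ids, counts) if m != GREY}

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def relabeled_by_size(self) -> "ModulePartition":
        """Renumber non-grey modules 1..k by decreasing size (ties broken by
        the index of the module's first gene)."""
        order = sorted(
            self.module_ids,
            key=lambda m: (-int((self.labels == m).sum()), int(self.members(m)[0])),
        )
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[GREY] = GREY
        new_labels = np.array([mapping[int(l)] for l in self.labels], dtype=int)
        return ModulePartition(self.gene_ids, new_labels)

    def write_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": list(self.gene_ids), "module": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "ModulePartition":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "module": int})
        return cls(tuple(frame["gene_id"]), frame["module"].to_numpy())


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree: a scipy-format linkage matrix plus the leaf ids."""

    gene_ids: tuple
    linkage: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        z = np.asarray(self.linkage, dtype=float)
        object.__setattr__(self, "linkage", z)
        n = len(self.gene_ids)
        if z.shape != (n - 1, 4):
            raise ValueError(f"linkage shape {z.shape} invalid for {n} leaves")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.linkage[:, 2].max())

    def merges(self):
        """Merge order as (cluster_a, cluster_b, height) triples."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.linkage, columns=["cluster_a", "cluster_b", "height", "size"]).to_csv(
            path, sep="\t", index=False
        )


def _validate_dissimilarity(diss: np.ndarray) -> np.ndarray:
    d = np.asarray(diss, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("dissimilarity must have a zero diagonal")
    if d.min() < 0:
        raise ValueError("dissimilarity must be non-negative")
    return (d + d.T) / 2.0


def average_linkage_tree(diss, gene_ids=None) -> Dendrogram:
    """Agglomerative average-linkage (UPGMA) dendrogram of a dissimilarity
    matrix.  Deterministic: identical input gives a bit-identical tree."""
    d = _validate_dissimilarity(diss)
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(d.shape[0]))
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(tuple(gene_ids), z)


def dynamic_tree_cut(
    tree: Dendrogram,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    absolute_height: bool = False,
) -> ModulePartition:
    """Cut the dendrogram into modules (tree variant of dynamic tree cut).

    ``cut_height`` is a fraction of the maximum merge height by default, or
    an absolute height when ``absolute_height`` is set.  Branches below the
    cut with at least ``min_module_size`` leaves become modules 1..k in
    decreasing size order; all other genes are grey (0).
    """
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    if absolute_height:
        h = float(cut_height)
    else:
        if not 0 < cut_height <= 1:
            raise ValueError("fractional cut_height must lie in (0, 1]")
        h = float(cut_height) * tree.max_height
    branch = hierarchy.fcluster(tree.linkage, t=h, criterion="distance")
    labels = np.zeros(len(branch), dtype=int)
    ids, counts = np.unique(branch, return_counts=True)
    next_label = 1
    for b in ids[counts >= min_module_size]:
        labels[branch == b] = next_label
        next_label += 1
    return ModulePartition(tree.gene_ids, labels).relabeled_by_size()
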