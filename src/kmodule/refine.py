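"""Module refinement: the k-module algorithm and the k-eigengene comparator.

Hierarchical clustering never revisits a merge, so a gene can end up in a
module it is only weakly connected to.  The k-module algorithm repairs this
by iterating a global reassignment: the mean connectivity of gene g_i to
module m with member set S_m (n_m genes) is

    mc(i, m) = (1 / n_m) * sum_{g_j in S_m} a_ij,

and each eligible gene is moved to argmax_m mc(i, m).  Updates are
synchronous — every argmax in an iteration is computed against the
memberships frozen at the start of that iteration — which makes the result
independent of gene order.  Iteration stops when no label changes or a
maximum iteration count is reached.  At a converged fixed point every gene
sits in its own highest-mean-connectivity module by construction.

The k-eigengene comparator instead assigns each gene to
argmax_j |Pearson(g_i, eg_j)| where eg_j is module j's eigengene (first
principal component of the module's standardized expression submatrix).
Unlike k-module, this update can cycle (the assignment criterion is not the
objective the principal component optimizes), so recurrence of a previously
seen label vector is detected and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import GREY, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementResult",
    "EigengeneSet",
    "mean_connectivity",
    "k_module_refine",
    "module_eigengene",
    "k_eigengene_refine",
]

DEFAULT_MAX_ITER = 100
DENOMINATORS = ("literal", "exclude-self")


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of an iterative refinement run."""

    partition: ModulePartition
    iterations: int
    changes_per_iteration: tuple
    converged: bool
    oscillation_detected: bool = False
    retired_modules: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "changes_per_iteration", tuple(int(c) for c in self.changes_per_iteration)
        )
        if self.converged and self.changes_per_iteration[-1] != 0:
            raise ValueError("converged run must end with zero changes")

    def summary(self) -> dict:
        return {
            "iterations": self.iterations,
            "changes_per_iteration": list(self.changes_per_iteration),
            "converged": self.converged,
            "oscillation_detected": self.oscillation_detected,
            "retired_modules": list(self.retired_modules),
            "n_modules": self.partition.n_modules,
        }


@dataclass(frozen=True)
class EigengeneSet:
    """Per-module eigengenes (unit-norm sample-space vectors) and the
    proportion of module variance each captures."""

    module_ids: tuple
    eigengenes: dict
    variance_proportion: dict


def _mc_matrix(adj: np.ndarray, labels: np.ndarray, module_ids, denominator: str) -> np.ndarray:
    """Mean connectivity of every gene to every module, shape (n, k).

    ``denominator="literal"`` divides by n_m (module size, counting the gene
    itself when it is a member; the self-term a_ii = 0 still contributes
    nothing).  ``"exclude-self"`` divides by n_m - 1 for members.
    """
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = len(module_ids)
    indicator = np.zeros((n, k))
    sizes = np.empty(k)
    for col, m in enumerate(module_ids):
        mask = labels == m
        sizes[col] = mask.sum()
        if sizes[col] == 0:
            raise ValueError(f"module {m} is empty")
        indicator[mask, col] = 1.0
    sums = a @ indicator
    denom = np.tile(sizes, (n, 1))
    if denominator == "exclude-self":
        member = indicator.astype(bool)
        denom = denom - member
        if (denom[member] == 0).any():
            raise ValueError("exclude-self denominator undefined for singleton modules")
    return sums / denom


def mean_connectivity(
    gene_index: int,
    module: int,
    adj: np.ndarray,
    partition: ModulePartition,
    denominator: str = "literal",
) -> float:
    """Mean adjacency of one gene to the members of one non-grey module."""
    if module == GREY:
        raise ValueError("mean connectivity to the grey pool is undefined")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    members = partition.members(module)
    if members.size == 0:
        raise ValueError(f"module {module} is empty")
    row = np.asarray(adj, dtype=float)[gene_index, members].copy()
    row[members == gene_index] = 0.0
    n_m = members.size
    if denominator == "exclude-self" and gene_index in members:
        n_m -= 1
        if n_m == 0:
            raise ValueError("exclude-self denominator undefined for a singleton module")
    return float(row.sum() / n_m)


def _check_adj(adj: np.ndarray, partition: ModulePartition) -> np.ndarray:
    a = np.asarray(adj, dtype=float)
    n = partition.n_genes
    if a.shape != (n, n):
        raise ValueError(f"adjacency shape {a.shape} does not match {n} genes")
    return a


def k_module_refine(
    partition: ModulePartition,
    adj: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    reassign_grey: bool = False,
    denominator: str = "literal",
) -> RefinementResult:
    """Iteratively reassign each gene to its highest-mean-connectivity module.

    Grey genes are frozen unless ``reassign_grey`` is set; the grey pool is
    never a target.  Ties go to the lowest module label.  The set of module
    ids is preserved unless a module empties, in which case its id is
    retired with a warning (an extreme case that should not occur on real
    module structure).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    a = _check_adj(adj, partition)
    module_ids = list(partition.module_ids)
    if not module_ids:
        raise ValueError("partition has no non-grey module")
    labels = partition.labels.copy()
    return _iterate(
        labels,
        module_ids,
        max_iter,
        reassign_grey,
        lambda lab, mods: _mc_matrix(a, lab, mods, denominator),
        partition.gene_ids,
    )


def _iterate(labels, module_ids, max_iter, reassign_grey, score_fn, gene_ids):
    """Shared synchronous-update loop for both refiners.

    ``score_fn(labels, module_ids)`` returns the (n, k) per-gene scores to
    maximize.  Detects recurrence of a previously seen label vector
    (oscillation) and keeps iterating to max_iter, as convergence is then
    impossible.
    """
    changes_hist = []
    converged = False
    oscillation = False
    retired = []
    seen = {tuple(labels)}
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        scores = score_fn(labels, module_ids)
        # np.argmax takes the first maximum; module_ids is sorted ascending,
        # so ties resolve to the lowest module label.
        targets = np.asarray(module_ids, dtype=int)[np.argmax(scores, axis=1)]
        eligible = np.ones(labels.size, dtype=bool) if reassign_grey else labels != GREY
        new_labels = labels.copy()
        new_labels[eligible] = targets[eligible]
        changes = int((new_labels != labels).sum())
        changes_hist.append(changes)
        labels = new_labels
        emptied = [m for m in module_ids if not (labels == m).any()]
        if emptied:
            logger.warning("module(s) %s emptied during refinement; retiring id(s)", emptied)
            retired.extend(emptied)
            module_ids = [m for m in module_ids if m not in emptied]
            if not module_ids:
                raise ValueError("all modules emptied during refinement")
        if changes == 0:
            converged = True
            break
        key = tuple(labels)
        if key in seen and not oscillation:
            oscillation = True
            logger.warning(
                "label assignment recurred without convergence (oscillation); "
                "iterating to max_iter=%d", max_iter,
            )
        seen.add(key)
    return RefinementResult(
        partition=ModulePartition(gene_ids, labels),
        iterations=iterations,
        changes_per_iteration=tuple(changes_hist),
        converged=converged,
        oscillation_detected=oscillation,
        retired_modules=tuple(retired),
    )


def _standardize_rows(x: np.ndarray, gene_ids, module) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = [gene_ids[i] for i in np.flatnonzero(sd.ravel() == 0)]
        raise ValueError(f"constant gene(s) {bad[:5]} in module {module}; eigengene undefined")
    return (x - mu) / sd


def module_eigengene(expr, partition: ModulePartition) -> EigengeneSet:
    """First-principal-component eigengene of every non-grey module.

    Genes are standardized (zero mean, unit variance) before the
    decomposition.  Each eigengene is the unit-norm first right singular
    vector over samples, with its sign fixed so it correlates non-negatively
    with the module's mean standardized profile.  ``variance_proportion`` is
    the fraction of the module's (standardized) variance the first component
    captures.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    eigengenes = {}
    varprop = {}
    for m in partition.module_ids:
        members = partition.members(m)
        if members.size < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        z = _standardize_rows(expr.values[members], expr.gene_ids, m)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eg = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eg, mean_profile) < 0:
            eg = -eg
        eigengenes[m] = eg
        varprop[m] = float(s[0] ** 2 / (s**2).sum())
    return EigengeneSet(tuple(partition.module_ids), eigengenes, varprop)


def _abs_corr_to_eigengenes(expr_values, labels, module_ids, gene_ids, expr) -> np.ndarray:
    part = ModulePartition(gene_ids, labels)
    egs = module_eigengene(expr, part)
    m = expr_values.shape[1]
    xc = expr_values - expr_values.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1, keepdims=True)
    degenerate = xn.ravel() == 0
    xn[degenerate] = 1.0
    xc = xc / xn
    scores = np.empty((expr_values.shape[0], len(module_ids)))
    for col, mod in enumerate(module_ids):
        e = egs.eigengenes[mod]
        ec = e - e.mean()
        en = np.linalg.norm(ec)
        scores[:, col] = np.abs(xc @ (ec / en)) if en > 0 else 0.0
    if degenerate.any():
        scores[degenerate] = 0.0
    return scores


def k_eigengene_refine(
    expr,
    partition: ModulePartition,
    max_iter: int = DEFAULT_MAX_ITER,
    reassign_grey: bool = False,
) -> RefinementResult:
    """Iteratively reassign each gene to the module whose eigengene it most
    strongly correlates with (absolute Pearson; ties to the lowest label).

    Eigengenes are recomputed from the current memberships each iteration.
    Sets ``oscillation_detected`` when a previously seen label vector recurs
    without convergence — this comparator, unlike k-module, can enter such a
    cycle under synchronous updates.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    module_ids = list(partition.module_ids)
    if not module_ids:
        raise ValueError("partition has no non-grey module")
    labels = partition.labels.copy()
    values = expr.values
    return _iterate(
        labels,
        module_ids,
        max_iter,
        reassign_grey,
        lambda lab, mods: _abs_corr_to_eigengenes(values, lab, mods, partition.gene_ids, expr),
        partition.gene_ids,
    )
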