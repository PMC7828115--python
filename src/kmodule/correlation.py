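"""Gene-gene similarity matrices: distance correlation or absolute Pearson.

Distance correlation (dCor) is the energy-statistics dependence measure of
Szekely, Rizzo & Bakirov: for paired samples x, y of length m, pairwise
Euclidean distance matrices are double-centered and

    dCov^2(x, y) = mean(A * B),    dVar^2(x) = mean(A * A),
    dCor(x, y)   = dCov(x, y) / sqrt(dVar(x) dVar(y)).

This is the biased V-statistic form (always in [0, 1]); it detects both
linear and nonlinear dependence, and it is invariant to shifting either
vector and to rescaling either vector by a nonzero constant.  The pairwise
computation over n genes and m samples costs O(n^2 m^2) time — quadratic in
both genes and samples — which is why upstream CV filtering matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SimilarityMatrix", "distance_correlation", "pairwise_similarity"]

_METHODS = ("distance-correlation", "absolute-pearson")
_CACHE_FORMAT = 1


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric gene-gene similarity in [0, 1] with unit diagonal."""

    gene_ids: tuple
    values: np.ndarray
    method: str

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.gene_ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity shape {v.shape} does not match {n} genes")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.gene_ids)
        ).to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path, method: str) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(frame.index.astype(str)), frame.to_numpy(dtype=float), method)

    def save_cache(self, path) -> None:
        """Binary cache (npz with a format-version field) to skip recomputation."""
        np.savez_compressed(
            path,
            format=np.array(_CACHE_FORMAT),
            method=np.array(self.method),
            gene_ids=np.array(self.gene_ids),
            values=self.values,
        )

    @classmethod
    def load_cache(cls, path) -> "SimilarityMatrix":
        with np.load(path, allow_pickle=False) as z:
            if int(z["format"]) != _CACHE_FORMAT:
                raise ValueError(f"unsupported cache format {int(z['format'])}")
            return cls(tuple(z["gene_ids"]), z["values"], str(z["method"]))


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix of a 1-D sample."""
    d = np.abs(x[:, None] - x[None, :])
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def distance_correlation(x, y) -> float:
    """Distance correlation of two equal-length 1-D samples; a value in [0, 1].

    By convention a constant vector (zero distance variance) yields 0 — the
    ratio is 0/0 and independence from a constant is vacuous.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        logger.debug("constant vector in distance_correlation; returning 0 by convention")
        return 0.0
    dcov2 = (a * b).mean()
    r2 = dcov2 / np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def pairwise_similarity(expr, method: str = "distance-correlation") -> SimilarityMatrix:
    """Similarity s_ij for all gene pairs of an expression matrix.

    ``absolute-pearson`` gives s_ij = |Pearson(x_i, x_j)|; both measures
    treat positive and negative co-expression equally (unsigned network).
    The diagonal is set to 1; constant genes get off-diagonal similarity 0
    and are listed in a warning.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {_METHODS}")
    if expr.n_genes < 2 or expr.n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    X = expr.values
    constant = X.std(axis=1) == 0
    if constant.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "%d constant gene(s) have zero off-diagonal similarity: %s",
            len(names), names[:10],
        )
    if method == "absolute-pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.abs(np.corrcoef(X))
        s[np.isnan(s)] = 0.0
    else:
        s = _pairwise_dcor(X, constant)
    np.clip(s, 0.0, 1.0, out=s)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(expr.gene_ids, s, method)


def _pairwise_dcor(X: np.ndarray, constant: np.ndarray) -> np.ndarray:
    # Flatten each gene's double-centered distance matrix so every pairwise
    # dCov^2 is a single dot product: C @ C.T / m^2.  Memory is n * m^2
    # doubles, fine at desk scale (the formats this targets are pre-filtered
    # to a few thousand genes).
    n, m = X.shape
    C = np.empty((n, m * m))
    for i in range(n):
        C[i] = _centered_distances(X[i]).ravel()
    dcov2 = (C @ C.T) / (m * m)
    dvar = np.diag(dcov2).copy()
    dvar[dvar <= 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = dcov2 / np.sqrt(np.outer(dvar, dvar))
    r2[np.isnan(r2)] = 0.0
    return np.sqrt(np.clip(r2, 0.0, 1.0))
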