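"""Expression-matrix container, delimited-text I/O, and informative-gene filtering.

The universal input of the pipeline is a genes x samples matrix of
pre-normalized expression values (microarray log-intensities or
log-transformed RNA-seq estimates).  Missing values are not supported and
are rejected at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "read_expression", "cv_filter", "split_samples"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix with identifiers.

    Parameters
    ----------
    gene_ids :
        Ordered, unique gene identifiers (one per row).
    sample_ids :
        Ordered, unique sample identifiers (one per column).
    values :
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; every
        entry must be finite.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = _first_duplicate(ids)
                raise ValueError(f"duplicate {name} identifier: {dup!r}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep) -> "ExpressionMatrix":
        """Return a new matrix restricted to genes selected by a boolean mask
        or an iterable of gene identifiers (input order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[str(g)] for g in keep], dtype=int)
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in idx), self.sample_ids, self.values[idx]
        )

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.gene_ids, tuple(self.sample_ids[i] for i in idx), self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy(dtype=float))

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV or CSV, auto-detected).

    The first column holds identifiers and the header row holds the other
    axis's identifiers.  ``orientation="genes-in-columns"`` transposes the
    file so genes always end up in rows.

    Raises
    ------
    ValueError
        On duplicate identifiers, non-numeric cells or malformed rows; the
        message names the offending identifier or cell.
    """
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate identifier {dup!r} in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {frame.iat[i, j]!r} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if orientation == "genes-in-columns":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def cv_filter(
    expr: ExpressionMatrix,
    cv_threshold: float,
    require_above_mean_intensity: bool = False,
    return_report: bool = False,
):
    """Retain informative genes by coefficient-of-variation filtering.

    When ``require_above_mean_intensity`` is set, genes whose mean expression
    does not exceed the grand mean of all gene means are dropped first.  Then
    genes with CV = sd / mean (sample sd, n−1 denominator) strictly greater
    than ``cv_threshold`` are retained.  Genes with mean <= 0 have an
    undefined CV and are excluded with a logged warning.

    Returns the filtered :class:`ExpressionMatrix`, plus a per-gene report
    DataFrame when ``return_report`` is true.
    """
    if cv_threshold < 0:
        raise ValueError("cv_threshold must be >= 0")
    if expr.n_samples < 2:
        raise ValueError("cv_filter needs at least 2 samples")
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1)
    keep = np.ones(expr.n_genes, dtype=bool)
    reasons = np.array([""] * expr.n_genes, dtype=object)
    if require_above_mean_intensity:
        low = means <= means.mean()
        keep &= ~low
        reasons[low] = "intensity<=grand-mean"
    undefined = keep & (means <= 0)
    if undefined.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(undefined)]
        logger.warning("CV undefined (mean <= 0) for %d genes: %s", len(names), names[:10])
        keep &= ~undefined
        reasons[undefined] = "cv-undefined(mean<=0)"
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    low_cv = keep & ~(cv > cv_threshold)
    keep &= ~low_cv
    reasons[low_cv] = f"cv<={cv_threshold}"
    out = expr.subset_genes(keep)
    if return_report:
        report = pd.DataFrame(
            {
                "gene_id": list(expr.gene_ids),
                "mean": means,
                "cv": cv,
                "kept": keep,
                "reason_removed": reasons,
            }
        )
        return out, report
    return out


def split_samples(expr: ExpressionMatrix, n_parts: int, seed: int) -> list:
    """Partition the samples uniformly at random into ``n_parts`` disjoint,
    exhaustive, size-balanced parts (sizes differ by at most one).

    Reproducible given ``seed``; every part keeps the gene set and the
    original relative sample order.
    """
    if n_parts < 2:
        raise ValueError("n_parts must be >= 2")
    if expr.n_samples // n_parts < 2:
        raise ValueError(
            f"cannot split {expr.n_samples} samples into {n_parts} parts of >= 2 samples"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expr.n_samples)
    groups = np.array_split(perm, n_parts)
    return [expr.subset_samples(np.sort(g)) for g in groups]
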