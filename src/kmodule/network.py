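"""Soft-thresholded adjacency, scale-free-topology fit, and topological overlap.

The similarity matrix is turned into a weighted unsigned network by the
soft threshold a_ij = s_ij ** beta.  beta is chosen as the smallest power
whose connectivity distribution approximates scale-free topology (signed
R-squared of the log-log frequency/connectivity regression at least
``r2_cut``).  The topological overlap matrix (TOM) credits shared
neighbors:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_u a_iu a_uj  (u != i, j),   k_i = sum_u a_iu  (u != i),

with TOM_ii = 1.  Self-adjacency is excluded throughout (a_ii := 0 for
every connectivity computation), the standard convention for weighted
co-expression networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom",
    "dissimilarity",
]

DEFAULT_CANDIDATE_BETAS = tuple(range(1, 21))
DEFAULT_R2_CUT = 0.85
DEFAULT_N_BINS = 10


@dataclass(frozen=True)
class GeneNetwork:
    """Weighted unsigned network over one gene index.

    ``adjacency`` has a zero diagonal (self-connections excluded); ``tom``
    is present after :func:`tom` and has a unit diagonal.
    """

    gene_ids: tuple
    adjacency: np.ndarray
    beta: float
    sft_r2: float | None = None
    tom: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        a = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", a)
        n = len(self.gene_ids)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} genes")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if a.min() < 0 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if self.tom is not None:
            t = np.asarray(self.tom, dtype=float)
            object.__setattr__(self, "tom", t)
            if t.shape != a.shape:
                raise ValueError("tom shape does not match adjacency")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def adjacency(sim, beta: float) -> GeneNetwork:
    """Soft-threshold a similarity matrix: a_ij = s_ij ** beta, a_ii = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = sim.values**beta
    np.fill_diagonal(a, 0.0)
    return GeneNetwork(sim.gene_ids, a, beta=float(beta))


def connectivity(net: GeneNetwork) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return net.adjacency.sum(axis=1)


def scale_free_fit(net_or_k, n_bins: int = DEFAULT_N_BINS) -> float:
    """Signed scale-free-topology fit index of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; for each
    nonempty bin the mean connectivity and the frequency (fraction of genes)
    are computed, and log10(frequency) is regressed on log10(mean k).  The
    returned index is R-squared with the sign flipped to the regression
    slope's opposite, so a decaying (scale-free-like) distribution scores
    positive and an increasing one negative.

    Raises
    ------
    ValueError
        If the connectivities are all equal (the fit is undefined).
    """
    if isinstance(net_or_k, GeneNetwork):
        k = connectivity(net_or_k)
    else:
        k = np.asarray(net_or_k, dtype=float)
    if k.size < 3:
        raise ValueError("need at least 3 connectivities")
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        dk.append(mk)
        freq.append(mask.sum() / k.size)
    if len(dk) < 3:
        raise ValueError("fewer than 3 usable bins; scale-free fit undefined")
    fit = stats.linregress(np.log10(dk), np.log10(freq))
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def _fallback_beta(n_samples: int | None) -> int:
    """Conventional default unsigned soft-thresholding power when the
    scale-free criterion is not met, keyed to sample count (the standard
    recommendation for unsigned weighted networks)."""
    if n_samples is None or n_samples >= 40:
        return 6
    if n_samples >= 30:
        return 7
    if n_samples >= 20:
        return 8
    return 9


def pick_soft_threshold(
    sim,
    candidate_betas=DEFAULT_CANDIDATE_BETAS,
    r2_cut: float = DEFAULT_R2_CUT,
    n_bins: int = DEFAULT_N_BINS,
    n_samples: int | None = None,
    min_mean_k: float = 1.0,
):
    """Choose the soft-thresholding power by the scale-free-topology criterion.

    Returns ``(beta, table)`` where ``table`` is a diagnostic DataFrame with
    one row per candidate (beta, sft_r2, mean_k, median_k, max_k).  The
    chosen beta is the smallest candidate with signed R² >= ``r2_cut``
    whose mean connectivity stays at least ``min_mean_k`` — at high powers
    the fit index rises spuriously as connectivity collapses toward zero,
    so a "fit" over a vacuously sparse network does not qualify.  If no
    candidate qualifies a prominent warning is logged and the conventional
    default unsigned power for the sample count (6 for >= 40 samples, up to
    9 below 20; nearest candidate if that power is not offered) is used.
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ValueError("candidate_betas must be nonempty")
    off = sim.values[~np.eye(sim.n_genes, dtype=bool)]
    if np.ptp(off) == 0:
        raise ValueError("degenerate similarity (all off-diagonal entries equal)")
    rows = []
    for beta in candidates:
        net = adjacency(sim, beta)
        k = connectivity(net)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append(
            {
                "beta": beta,
                "sft_r2": r2,
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
                "max_k": k.max(),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table[(table["sft_r2"] >= r2_cut) & (table["mean_k"] >= min_mean_k)]
    if len(qualifying):
        beta = qualifying.iloc[0]["beta"]
    else:
        target = _fallback_beta(n_samples)
        beta = min(candidates, key=lambda b: (abs(b - target), b))
        logger.warning(
            "no candidate beta reached signed R^2 >= %.3g (best %.3g); falling "
            "back to the conventional default power beta=%s",
            r2_cut, table["sft_r2"].max(), beta,
        )
    return beta, table


def tom(net: GeneNetwork) -> GeneNetwork:
    """Topological overlap matrix of an adjacency-only network."""
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # With a zero diagonal, (A @ A)_ij already equals sum over u != i, j.
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return GeneNetwork(net.gene_ids, net.adjacency, beta=net.beta, sft_r2=net.sft_r2, tom=t)


def dissimilarity(net: GeneNetwork) -> np.ndarray:
    """TOM dissimilarity d_ij = 1 - TOM_ij with zero diagonal."""
    if net.tom is None:
        raise ValueError("network has no TOM; call tom() first")
    d = 1.0 - net.tom
    np.fill_diagonal(d, 0.0)
    return d


def write_sft_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
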