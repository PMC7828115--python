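"""Ground-truth expression generator with planted module structure.

Each module m is driven by one latent factor f_m ~ N(0, 1) across samples.
A member gene is loading * f_m plus Gaussian noise; optional variants are
anti-genes (negated loading — an unsigned network treats them identically)
and nonlinear genes tied to the factor through the standardized even
function (f^2 - 1) / sqrt(2), whose Pearson correlation with linear
module-mates is ~0 while its distance correlation stays substantial.  Grey
genes are pure noise, scaled so every gene shares the same marginal
variance.  All randomness flows from the single seed in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import GREY, ModulePartition
from .exprdata import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "corrupt"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module generator.

    Defaults describe a well-separated desk-scale instance: 300 genes in 5
    balanced modules of 54, 30 grey genes, factor loading 0.9 against noise
    sd 0.5 (signal-to-noise ~1.8), 60 samples.
    """

    n_genes: int = 300
    n_samples: int = 60
    n_modules: int = 5
    module_sizes: tuple | None = None
    loading: float = 0.9
    noise_sd: float = 0.5
    grey_fraction: float = 0.1
    nonlinear_fraction: float = 0.0
    anti_fraction: float = 0.0
    seed: int = 0

    def resolved_sizes(self) -> tuple:
        """Module sizes summing to n_genes * (1 - grey_fraction), rounded
        deterministically (remainder spread over the first modules)."""
        n_grey = int(round(self.grey_fraction * self.n_genes))
        n_assigned = self.n_genes - n_grey
        if self.module_sizes is not None:
            sizes = tuple(int(s) for s in self.module_sizes)
            if sum(sizes) != n_assigned:
                raise ValueError(
                    f"module_sizes sum {sum(sizes)} != assigned gene count {n_assigned}"
                )
            return sizes
        base, rem = divmod(n_assigned, self.n_modules)
        return tuple(base + (1 if i < rem else 0) for i in range(self.n_modules))

    def validate(self) -> None:
        if self.n_modules < 1 or self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("infeasible sizes")
        if not 0 < self.loading <= 1:
            raise ValueError("loading must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.grey_fraction < 1:
            raise ValueError("grey_fraction must lie in [0, 1)")
        for name in ("nonlinear_fraction", "anti_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        sizes = self.resolved_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError(f"infeasible module sizes {sizes}")


def generate(spec: SyntheticSpec):
    """Draw an expression matrix with planted modules.

    Returns ``(ExpressionMatrix, ModulePartition)`` — the data and the true
    labels (module genes first, in module order, grey genes last).  Fully
    reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.resolved_sizes()
    n_grey = spec.n_genes - sum(sizes)
    m = spec.n_samples
    factors = rng.standard_normal((spec.n_modules, m))
    rows = []
    labels = []
    for mod, size in enumerate(sizes, start=1):
        f = factors[mod - 1]
        n_nl = int(round(spec.nonlinear_fraction * size))
        n_anti = int(round(spec.anti_fraction * (size - n_nl)))
        signal = np.empty((size, m))
        signal[:n_nl] = spec.loading * (f**2 - 1.0) / np.sqrt(2.0)
        signal[n_nl:n_nl + n_anti] = -spec.loading * f
        signal[n_nl + n_anti:] = spec.loading * f
        rows.append(signal + spec.noise_sd * rng.standard_normal((size, m)))
        labels.extend([mod] * size)
    marginal_sd = np.sqrt(spec.loading**2 + spec.noise_sd**2)
    if n_grey:
        rows.append(marginal_sd * rng.standard_normal((n_grey, m)))
        labels.extend([GREY] * n_grey)
    values = np.vstack(rows)
    width = len(str(spec.n_genes))
    gene_ids = tuple(f"G{i + 1:0{width}d}" for i in range(spec.n_genes))
    sample_ids = tuple(f"S{j + 1:02d}" for j in range(m))
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = ModulePartition(gene_ids, np.array(labels, dtype=int))
    return expr, truth


def corrupt(partition: ModulePartition, fraction: float, seed: int) -> ModulePartition:
    """Reassign floor(fraction * n_non_grey) randomly chosen non-grey genes
    to random OTHER non-grey modules; deterministic per seed."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nongrey = np.flatnonzero(partition.labels != GREY)
    n_move = int(np.floor(fraction * nongrey.size))
    if n_move == 0:
        return ModulePartition(partition.gene_ids, partition.labels.copy())
    module_ids = np.array(partition.module_ids)
    if len(module_ids) < 2:
        raise ValueError("cannot corrupt a single-module partition")
    chosen = rng.choice(nongrey, size=n_move, replace=False)
    labels = partition.labels.copy()
    for i in chosen:
        others = module_ids[module_ids != labels[i]]
        labels[i] = rng.choice(others)
    return ModulePartition(partition.gene_ids, labels)
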