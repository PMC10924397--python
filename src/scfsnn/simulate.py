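"""Two-class scRNA-seq count simulator with ground-truth DE genes.

The generative model follows the Splatter family of simulators:

* baseline gene means  lambda_j ~ Gamma(mean_shape, rate=mean_rate);
* a fraction ``de_prop`` of genes is differentially expressed: class 2
  multiplies their mean by a log-normal fold change, up- or down-regulated
  with probability 1/2 each;
* expected library sizes  L_i ~ LogNormal(lib_loc, lib_scale); each cell's
  expected counts are its class's gene-mean profile renormalized to sum to
  L_i;
* biological noise: the per-cell-per-gene mean receives multiplicative Gamma
  noise with coefficient of variation ``bcv``, and counts are Poisson draws
  of the noisy mean — marginally a negative binomial, hence over-dispersed;
* optional dropout: entries are zeroed with a probability that decreases
  logistically in the log latent mean (midpoint ``dropout_mid``, steepness
  ``1 / dropout_shape``), mimicking technical zeros.

The returned bundle carries the true DE mask, so empirical false discovery
rate and power of any selection procedure can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .preprocess import CountMatrix, Labels

__all__ = ["SimParams", "SimTruth", "simulate_counts", "empirical_fdr", "empirical_power"]


@dataclass
class SimParams:
    n_cells: int = 2000
    n_genes: int = 10_000
    de_prop: float = 0.05
    n_classes: int = 2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    bcv: float = 0.18
    dropout_mid: float | None = None  # None disables dropout
    dropout_shape: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_prop <= 1.0:
            raise ValueError("de_prop must be in [0, 1]")
        if self.n_classes != 2:
            raise ValueError("only two-class simulation is supported")
        for name in ("mean_shape", "mean_rate", "lib_scale", "de_fac_scale", "bcv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimTruth:
    counts: CountMatrix
    labels: Labels
    de_mask: np.ndarray  # (n_genes,) bool, True for truly DE genes
    de_factors: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate_counts(params: SimParams, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw one two-class dataset; the DE mask marks exactly round(de_prop * p) genes."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, p = params.n_cells, params.n_genes

    lam = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, size=p)
    lam = np.maximum(lam, 1e-8)

    n_de = int(round(params.de_prop * p))
    de_idx = rng.choice(p, size=n_de, replace=False)
    de_mask = np.zeros(p, dtype=bool)
    de_mask[de_idx] = True
    fold = np.exp(rng.normal(params.de_fac_loc, params.de_fac_scale, size=n_de))
    fold = np.maximum(fold, 1.0 + 1e-6)  # a genuine change in either direction
    down = rng.random(n_de) < 0.5
    fold[down] = 1.0 / fold[down]
    factors = np.ones(p)
    factors[de_idx] = fold

    # class mean profiles, renormalized so library size is label-independent
    mean_c = np.vstack([lam, lam * factors])
    prop_c = mean_c / mean_c.sum(axis=1, keepdims=True)

    y = np.repeat(np.arange(2), [n - n // 2, n // 2])
    lib = np.exp(rng.normal(params.lib_loc, params.lib_scale, size=n))
    base_mean = lib[:, None] * prop_c[y]

    shape = 1.0 / params.bcv**2
    noisy_mean = rng.gamma(shape, base_mean / shape)
    counts = rng.poisson(noisy_mean)

    if params.dropout_mid is not None:
        # probability of a technical zero falls logistically with log latent mean
        p_drop = expit(-(np.log(noisy_mean + 1e-12) - params.dropout_mid) / params.dropout_shape)
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    gene_ids = np.array([f"gene_{j:05d}" for j in range(p)], dtype=object)
    cell_ids = np.array([f"cell_{i:05d}" for i in range(n)], dtype=object)
    return SimTruth(
        counts=CountMatrix(counts.astype(np.int64), gene_ids, cell_ids),
        labels=Labels(y, 2),
        de_mask=de_mask,
        de_factors=factors,
    )


def _selected_mask(selected_gene_ids, truth: SimTruth) -> np.ndarray:
    index = {g: j for j, g in enumerate(truth.counts.gene_ids)}
    mask = np.zeros(truth.counts.n_genes, dtype=bool)
    for g in selected_gene_ids:
        if g not in index:
            raise KeyError(f"selected gene {g!r} is not in the simulated gene set")
        mask[index[g]] = True
    return mask


def empirical_fdr(selected_gene_ids, truth: SimTruth) -> float:
    """Fraction of selected genes that are truly non-DE; 0 for an empty selection."""
    sel = _selected_mask(selected_gene_ids, truth)
    n_sel = int(sel.sum())
    if n_sel == 0:
        return 0.0
    return float((sel & ~truth.de_mask).sum() / n_sel)


def empirical_power(selected_gene_ids, truth: SimTruth) -> float:
    """Fraction of truly DE genes that were selected; 0 if there are no DE genes."""
    n_de = int(truth.de_mask.sum())
    if n_de == 0:
        return 0.0
    sel = _selected_mask(selected_gene_ids, truth)
    return float((sel & truth.de_mask).sum() / n_de)
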