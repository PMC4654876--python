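"""Genome-wise significance by phenotype permutation and significant-SNP
reporting.

The empirical threshold follows the shuffle-phenotypes procedure: adjusted
phenotypes are permuted against the intact genotypes, the whole-genome
regression is re-run on each permuted vector, the per-permutation maxima of
the posterior inclusion probability are sorted ascending, and the
ceil((1 - alpha) * n_perm)-th value is the genome-wise threshold — the
950th of 1000 at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayescpi import BayesCPi, ChainConfig
from .data import GenotypeMatrix
from .exceptions import ConfigError, DataError


def threshold_rank(alpha: float, n_perm: int) -> int:
    """1-based ascending rank of the permutation order statistic used as the
    genome-wise threshold: ceil((1 - alpha) * n_perm)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise ConfigError("n_perm must be positive")
    return int(math.ceil((1.0 - alpha) * n_perm))


@dataclass
class PermutationResult:
    max_ppi_per_perm: np.ndarray   # ascending order
    threshold: float
    alpha: float
    n_perm: int
    rank: int

    def __post_init__(self):
        if len(self.max_ppi_per_perm) != self.n_perm:
            raise DataError("one maximum per permutation required")


def permutation_threshold(y_star, genotypes, alpha: float = 0.05,
                          n_perm: int = 1000,
                          chain: ChainConfig | None = None,
                          seed: int = 0, **sampler_kwargs) -> PermutationResult:
    """Empirical genome-wise PPI threshold at level ``alpha``.

    Each permutation shuffles y* (genotypes intact), runs the sampler with a
    seed derived from ``seed``, and keeps max_j PPI_j.  ``sampler_kwargs``
    are forwarded to :class:`BayesCPi` (prior settings etc.).
    """
    if n_perm < 20:
        raise ConfigError("n_perm must be at least 20")
    rank = threshold_rank(alpha, n_perm)
    chain = chain or ChainConfig()
    y = np.asarray(y_star, dtype=float)
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        model = BayesCPi(y_perm, genotypes, **sampler_kwargs)
        res = model.fit(ChainConfig(chain.n_iter, chain.burn_in, chain.thin,
                                    int(chain_seeds[k])))
        maxima[k] = res.ppi.max()
    maxima = np.sort(maxima, kind="stable")
    return PermutationResult(
        max_ppi_per_perm=maxima,
        threshold=float(maxima[rank - 1]),
        alpha=alpha, n_perm=n_perm, rank=rank,
    )


def variance_explained(effect_mean: float, allele_freq: float,
                       sigma2_u_hat: float) -> float:
    """Percent of additive genetic variance explained by one SNP:
    100 * 2 p (1 - p) a^2 / sigma2_u_hat."""
    if sigma2_u_hat <= 0.0:
        raise DataError("variance explained undefined for sigma2_u_hat <= 0")
    p = float(allele_freq)
    return 100.0 * 2.0 * p * (1.0 - p) * float(effect_mean) ** 2 / sigma2_u_hat


def report_significant(posterior, threshold: float,
                       sigma2_u_hat: float | None = None,
                       allele_freqs=None,
                       annotation: pd.DataFrame | None = None,
                       window_kb: float = 500.0) -> pd.DataFrame:
    """Table of SNPs whose PPI reaches the genome-wise threshold.

    ``posterior`` is a BayesCPiResults (or any object with ``to_frame()``
    yielding snp_id/chrom/pos/effect_mean/ppi).  When ``sigma2_u_hat`` and
    ``allele_freqs`` are given, the percent of genetic variance explained
    per significant SNP is added.  When ``annotation`` is given (columns
    chrom, start, end, name; 1-based inclusive as returned by
    :func:`bovigen.io.read_bed` / ``read_gff3``), features overlapping the
    +/- ``window_kb`` window around each SNP are joined in a ``genes``
    column.
    """
    if not 0.0 <= threshold:
        raise ConfigError("threshold must be non-negative")
    tab = posterior.to_frame()
    hits = tab[tab["ppi"] >= threshold].reset_index(drop=True)
    if allele_freqs is not None:
        freqs = pd.Series(np.asarray(allele_freqs), index=tab.index)
        hit_freqs = freqs[tab["ppi"] >= threshold].to_numpy()
        if sigma2_u_hat is not None:
            hits["pct_genetic_variance"] = [
                variance_explained(a, p, sigma2_u_hat)
                for a, p in zip(hits["effect_mean"], hit_freqs)
            ]
    if annotation is not None:
        _check_annotation(annotation)
        half = int(window_kb * 1000)
        genes = []
        for _, row in hits.iterrows():
            lo, hi = row["pos"] - half, row["pos"] + half
            sel = annotation[
                (annotation["chrom"].astype(str) == str(row["chrom"]))
                & (annotation["start"] <= hi)
                & (annotation["end"] >= lo)
            ]
            genes.append(",".join(sel["name"].astype(str)))
        hits["genes"] = genes
    return hits


def _check_annotation(annotation: pd.DataFrame) -> None:
    needed = {"chrom", "start", "end", "name"}
    if not needed.issubset(annotation.columns):
        raise DataError(f"annotation needs columns {sorted(needed)}")
    if (annotation["end"] < annotation["start"]).any():
        raise DataError("annotation has intervals with end < start")
    if (annotation["start"] < 0).any():
        raise DataError("annotation has negative coordinates")
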