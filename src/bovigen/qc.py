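"""SNP quality control: missingness, MAF, Hardy-Weinberg and correlation
filters, followed by sporadic-missing imputation.

Filter order is fixed — missingness -> MAF -> HWE -> correlation — and the
QC report counts removals in that order, so a SNP failing several filters is
charged to the first one.  The MAF boundary follows "remove if MAF < 0.05":
a SNP at exactly the threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .data import GenotypeMatrix
from .exceptions import ConfigError, DataError


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.05
    missing_max: float = 0.20
    hwe_p_min: float = 1e-6
    corr_max: float = 0.95
    corr_window: int = 50  # retained-SNP window for the greedy pruner

    def validate(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min", "corr_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and not (name == "corr_max" and v == 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.corr_window < 1:
            raise ConfigError("corr_window must be >= 1")


@dataclass
class QCReport:
    n_input_snps: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_corr: int
    n_kept: int
    fraction_imputed: float

    def __post_init__(self):
        removed = (self.n_removed_missing + self.n_removed_maf
                   + self.n_removed_hwe + self.n_removed_corr)
        if self.n_input_snps != self.n_kept + removed:
            raise DataError("QC report counts are inconsistent")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one SNP from dosages in {0,1,2,NaN}.

    p is the coded-allele frequency over non-missing calls; returns
    min(p, 1-p).
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise DataError("MAF undefined: all calls missing")
    p = d[ok].sum() / (2.0 * ok.sum())
    return float(min(p, 1.0 - p))


def hwe_test(genotype_counts) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions at the observed allele frequency.

    Monomorphic SNPs return p = 1 (HWE trivially holds).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise DataError("HWE test needs at least one genotype")
    p = (2 * n_bb + n_ab) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over pairwise-complete observations."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def prune_correlated(genotypes: GenotypeMatrix, corr_max: float = 0.95,
                     window: int = 50) -> np.ndarray:
    """Greedy left-to-right correlation pruning within each chromosome.

    A SNP is dropped when its |Pearson r| with any of the previous ``window``
    retained SNPs on the same chromosome reaches ``corr_max``; the earlier
    SNP in map order wins ties.  Returns the kept column indices.
    """
    kept: list[int] = []
    X = genotypes.dosages
    complete = not genotypes.has_missing
    if complete:
        # standardised columns turn windowed correlations into one mat-vec
        Xc = X - X.mean(axis=0, keepdims=True)
        sd = Xc.std(axis=0)
        sd[sd == 0.0] = 1.0
        Z = Xc / (sd * np.sqrt(X.shape[0]))
    for _, grp in genotypes.snp_map.groupby("chrom", sort=False):
        chrom_kept: list[int] = []
        for j in grp.index:
            win = chrom_kept[-window:]
            if complete and win:
                r = Z[:, win].T @ Z[:, j]
                drop = bool((np.abs(r) >= corr_max - 1e-12).any())
            else:
                drop = any(
                    abs(_pairwise_corr(X[:, j], X[:, k])) >= corr_max
                    for k in win
                )
            if not drop:
                chrom_kept.append(j)
        kept.extend(chrom_kept)
    return np.array(sorted(kept), dtype=int)


def impute_sporadic(genotypes: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls with Binomial(2, p_hat) draws at each SNP's observed
    allele frequency.  Preserves allele frequencies in expectation;
    deterministic given the seed; observed cells are never changed."""
    if not genotypes.has_missing:
        return genotypes
    rng = np.random.default_rng(seed)
    X = genotypes.dosages.copy()
    freqs = genotypes.allele_freqs()
    for j in np.flatnonzero(np.isnan(X).any(axis=0)):
        miss = np.isnan(X[:, j])
        X[miss, j] = rng.binomial(2, freqs[j], size=miss.sum())
    return GenotypeMatrix(X, genotypes.snp_map, genotypes.animal_ids)


def run_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None,
           seed: int = 0):
    """Apply all filters in order, impute, and report.

    Returns (clean_genotypes, report).  Re-running on an already-clean
    matrix removes nothing.
    """
    thr = thresholds or QCThresholds()
    thr.validate()
    X = genotypes.dosages
    n, m0 = X.shape

    miss_rate = np.isnan(X).mean(axis=0)
    pass_miss = miss_rate <= thr.missing_max
    n_rm_miss = int((~pass_miss).sum())

    maf = np.full(m0, np.nan)
    idx_m = np.flatnonzero(pass_miss)
    for j in idx_m:
        maf[j] = compute_maf(X[:, j])
    pass_maf = pass_miss & (maf >= thr.maf_min)
    n_rm_maf = int(pass_miss.sum() - pass_maf.sum())

    pass_hwe = pass_maf.copy()
    for j in np.flatnonzero(pass_maf):
        d = X[:, j]
        d = d[~np.isnan(d)]
        counts = ((d == 0).sum(), (d == 1).sum(), (d == 2).sum())
        if hwe_test(counts) < thr.hwe_p_min:
            pass_hwe[j] = False
    n_rm_hwe = int(pass_maf.sum() - pass_hwe.sum())

    surviving = genotypes.subset_snps(np.flatnonzero(pass_hwe))
    kept_local = prune_correlated(surviving, thr.corr_max, thr.corr_window)
    n_rm_corr = int(surviving.n_snps - len(kept_local))
    filtered = surviving.subset_snps(kept_local)

    n_missing_cells = int(np.isnan(filtered.dosages).sum())
    clean = impute_sporadic(filtered, seed=seed)
    report = QCReport(
        n_input_snps=m0,
        n_removed_missing=n_rm_miss,
        n_removed_maf=n_rm_maf,
        n_removed_hwe=n_rm_hwe,
        n_removed_corr=n_rm_corr,
        n_kept=clean.n_snps,
        fraction_imputed=n_missing_cells / max(filtered.dosages.size, 1),
    )
    return clean, report
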