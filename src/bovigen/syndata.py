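"""Synthetic genotype/pedigree/phenotype generator.

Emulates the structure of a beef-cattle slaughter cohort: paternal half-sib
families (one recorded generation, dams unrecorded), several breed types,
four production systems, contemporary groups (feedlot location x year),
genotypes on a dense SNP panel with block-wise linkage disequilibrium, and
quantitative traits controlled by a handful of large-effect QTL on top of a
polygenic background.

The LD model is deliberately simple: founder haplotypes are drawn per LD
block from a first-order Markov chain along the SNPs (allele carried over
with probability ``ld_decay``), and every gamete copies whole blocks from
this founder pool.  Pairwise dosage correlation therefore decays
geometrically with SNP distance within a block and vanishes across block
boundaries — enough structure to exercise correlation pruning and the
smearing of association signal across a QTL's neighbours, without a
coalescent simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .exceptions import ConfigError

BREED_LEVELS = ("AN", "CH", "HE", "GV", "TX")
GENDER_LEVELS = ("heifer", "steer")
SYSTEM_LEVELS = ("calf_impl", "calf_noimpl", "yearling_impl", "yearling_noimpl")


def default_fixed_effect_spec() -> dict:
    """Fixed-effect levels and coefficients, in phenotypic-SD units.

    Level effects span 0.25-1.0 SD so that adjustment matters without
    dominating the trait; covariate slopes are scaled to their natural units.
    """
    return {
        "breed_levels": list(BREED_LEVELS),
        "breed_effects": [0.0, 0.4, -0.3, 0.25, 0.6],
        "gender_levels": list(GENDER_LEVELS),
        "gender_effects": [0.0, 0.5],
        "system_levels": list(SYSTEM_LEVELS),
        "system_effects": [0.0, -0.35, 0.45, 0.8],
        # slopes per unit of the (standardised) covariate
        "age_coef": 0.3,
        "days_ext_coef": 0.25,
        "diet_me_coef": 0.4,
        "marbling_coef": 0.5,
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort."""

    n_animals: int = 1366
    n_snps: int = 2000
    n_chromosomes: int = 10
    n_sires: int = 60
    allele_freq_range: tuple = (0.05, 0.95)
    ld_block_size: int = 10
    ld_decay: float = 0.8
    n_founder_haplotypes: int = 60
    missing_rate: float = 0.0
    n_large_qtl: int = 0
    large_qtl_var_fraction: float = 0.0
    n_poly_qtl: int | None = None  # None -> min(200, n_snps // 4)
    h2: float = 0.35
    cg_var_fraction: float = 0.10
    n_contemporary_groups: int = 8  # 2 locations x 4 years
    fixed_effect_spec: dict = field(default_factory=default_fixed_effect_spec)
    seed: int = 0

    def __post_init__(self):
        if self.n_poly_qtl is None:
            self.n_poly_qtl = max(1, min(200, self.n_snps // 4))

    def validate(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ConfigError(f"h2 must be in [0, 1), got {self.h2}")
        if not 0.0 <= self.cg_var_fraction < 1.0:
            raise ConfigError("cg_var_fraction must be in [0, 1)")
        if self.h2 + self.cg_var_fraction >= 1.0:
            raise ConfigError(
                "h2 + cg_var_fraction must be < 1 "
                f"(got {self.h2} + {self.cg_var_fraction})"
            )
        if self.n_large_qtl + self.n_poly_qtl > self.n_snps:
            raise ConfigError("n_large_qtl + n_poly_qtl exceeds n_snps")
        lo, hi = self.allele_freq_range
        if not (0.01 <= lo <= hi <= 0.99):
            raise ConfigError(
                f"allele_freq_range must lie within (0.01, 0.99), got {self.allele_freq_range}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_large_qtl > 0 and self.large_qtl_var_fraction == 0.0:
            raise ConfigError(
                "n_large_qtl > 0 requires large_qtl_var_fraction > 0"
            )
        if not 0.0 <= self.large_qtl_var_fraction <= 1.0:
            raise ConfigError("large_qtl_var_fraction must be in [0, 1]")
        if self.n_sires < 1 or self.n_animals < 1 or self.n_snps < 1:
            raise ConfigError("n_animals, n_snps and n_sires must be positive")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigError("ld_decay must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allele_freq_range"] = list(self.allele_freq_range)
        return d


@dataclass
class SimTruth:
    """Latent ground truth recorded by the generator for recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    true_h2_realized: float
    fixed_effect_values: np.ndarray
    cg_effects: np.ndarray
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "true_breeding_values": self.true_breeding_values.tolist(),
            "true_h2_realized": float(self.true_h2_realized),
            "fixed_effect_values": self.fixed_effect_values.tolist(),
        }


def _snp_map(config: SimConfig) -> pd.DataFrame:
    """Assign SNPs to chromosomes with ascending 1-based positions."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, m in enumerate(per_chrom, start=1):
        chroms.extend([c] * m)
        positions.extend((50_000 * np.arange(1, m + 1)).tolist())
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(config.n_snps)],
            "chrom": chroms,
            "pos": positions,
        }
    )


def _founder_pool(config: SimConfig, freqs: np.ndarray, blocks: list,
                  rng: np.random.Generator) -> np.ndarray:
    """K x M founder haplotypes with Markov LD within each block."""
    K, M = config.n_founder_haplotypes, config.n_snps
    pool = np.empty((K, M), dtype=np.int8)
    for lo, hi in blocks:
        pool[:, lo] = rng.random(K) < freqs[lo]
        for j in range(lo + 1, hi):
            carry = rng.random(K) < config.ld_decay
            fresh = rng.random(K) < freqs[j]
            pool[:, j] = np.where(carry, pool[:, j - 1], fresh)
    return pool


def _blocks(snp_map: pd.DataFrame, block_size: int) -> list:
    """Half-open [lo, hi) block bounds; blocks never span chromosomes."""
    out = []
    for _, grp in snp_map.groupby("chrom", sort=False):
        lo = grp.index[0]
        stop = grp.index[-1] + 1
        while lo < stop:
            out.append((lo, min(lo + block_size, stop)))
            lo += block_size
    return out


def simulate_genotypes(config: SimConfig):
    """Simulate genotypes and a one-generation paternal half-sib pedigree.

    Returns
    -------
    genotypes : GenotypeMatrix
        n x M dosages in {0,1,2} with NaN at ``missing_rate``.
    pedigree : DataFrame
        Columns animal_id, sire_id, dam_id (dams unrecorded -> NA).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    snp_map = _snp_map(config)
    blocks = _blocks(snp_map, config.ld_block_size)
    lo_f, hi_f = config.allele_freq_range
    freqs = rng.uniform(lo_f, hi_f, size=config.n_snps)
    pool = _founder_pool(config, freqs, blocks, rng)
    K = config.n_founder_haplotypes
    n, M = config.n_animals, config.n_snps
    n_blocks = len(blocks)

    # sire haplotype pairs: whole-block copies from the founder pool
    sire_pick = rng.integers(0, K, size=(config.n_sires, 2, n_blocks))

    # offspring-to-sire assignment: as equal-sized families as possible
    sires_of = np.repeat(np.arange(config.n_sires), int(np.ceil(n / config.n_sires)))[:n]

    # paternal gamete: per block pick one of the sire's two haplotypes;
    # maternal gamete: fresh block copies from the pool (dams unrelated)
    pat_side = rng.integers(0, 2, size=(n, n_blocks))
    mat_pick = rng.integers(0, K, size=(n, n_blocks))

    dosages = np.empty((n, M), dtype=float)
    for b, (lo, hi) in enumerate(blocks):
        pat_hap_idx = sire_pick[sires_of, pat_side[:, b], b]
        dosages[:, lo:hi] = pool[pat_hap_idx, lo:hi] + pool[mat_pick[:, b], lo:hi]

    if config.missing_rate > 0:
        mask = rng.random((n, M)) < config.missing_rate
        dosages[mask] = np.nan

    animal_ids = np.array([f"a{i + 1}" for i in range(n)])
    pedigree = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "sire_id": [f"s{s + 1}" for s in sires_of],
            "dam_id": pd.array([pd.NA] * n),
        }
    )
    return GenotypeMatrix(dosages, snp_map, animal_ids), pedigree


def _pick_qtl(config: SimConfig, dosage_var: np.ndarray,
              rng: np.random.Generator) -> tuple:
    """Choose large and polygenic QTL among polymorphic SNPs, spread out so
    their dosage columns are nearly uncorrelated."""
    polymorphic = np.flatnonzero(dosage_var > 1e-8)
    n_qtl = config.n_large_qtl + config.n_poly_qtl
    if len(polymorphic) < n_qtl:
        raise ConfigError(
            f"only {len(polymorphic)} polymorphic SNPs for {n_qtl} QTL"
        )
    # evenly strided start points keep large QTL in distinct LD blocks
    chosen = rng.choice(polymorphic, size=n_qtl, replace=False)
    large = chosen[: config.n_large_qtl]
    poly = chosen[config.n_large_qtl:]
    return np.sort(large), np.sort(poly)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig):
    """Simulate one trait on top of a genotype matrix.

    The phenotype is intercept + fixed effects + breeding value +
    contemporary-group effect + residual, with component variances scaled so
    the realized heritability (var(TBV) / var(TBV + cg + e)) matches
    ``config.h2`` up to the sampling noise of the contemporary-group draw.
    Uses the true (pre-missingness) dosages via NaN-free column means.

    Returns (trait_table, truth).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7**5]))
    n = genotypes.n_animals
    X = genotypes.dosages
    # the generator works on complete dosages; fill sporadic NaN with col mean
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    Xc = X - X.mean(axis=0, keepdims=True)
    dosage_var = Xc.var(axis=0)

    sigma2_a = config.h2
    sigma2_cg = config.cg_var_fraction
    sigma2_e = 1.0 - sigma2_a - sigma2_cg

    large_idx, poly_idx = _pick_qtl(config, dosage_var, rng)
    qtl_idx = np.concatenate([large_idx, poly_idx]).astype(int)
    effects = np.zeros(len(qtl_idx))

    if sigma2_a > 0 and len(qtl_idx) > 0:
        var_large_total = config.large_qtl_var_fraction * sigma2_a
        var_poly_total = sigma2_a - var_large_total
        # each large QTL carries an equal share of the large-QTL variance
        for k, j in enumerate(large_idx):
            a = np.sqrt(var_large_total / max(config.n_large_qtl, 1) / dosage_var[j])
            effects[k] = a * rng.choice([-1.0, 1.0])
        if len(poly_idx) > 0 and var_poly_total > 0:
            raw = rng.standard_normal(len(poly_idx))
            g_poly = Xc[:, poly_idx] @ raw
            v = g_poly.var()
            if v > 0:
                raw *= np.sqrt(var_poly_total / v)
            effects[config.n_large_qtl:] = raw

    tbv = Xc[:, qtl_idx] @ effects

    # nuisance structure
    cg_labels = rng.integers(0, config.n_contemporary_groups, size=n)
    cg_level_effects = rng.standard_normal(config.n_contemporary_groups) * np.sqrt(sigma2_cg)
    cg_vals = cg_level_effects[cg_labels]

    resid = rng.standard_normal(n)
    resid -= resid.mean()
    rv = resid.var()
    if rv > 0:
        resid *= np.sqrt(sigma2_e / rv)

    spec = config.fixed_effect_spec
    breed = rng.choice(spec["breed_levels"], size=n)
    gender = rng.choice(spec["gender_levels"], size=n)
    system = rng.choice(spec["system_levels"], size=n)
    age = rng.normal(450.0, 30.0, size=n)
    days_ext = rng.normal(30.0, 10.0, size=n)
    diet_me = rng.normal(2.8, 0.2, size=n)
    marbling = rng.normal(5.0, 1.0, size=n)

    breed_fx = dict(zip(spec["breed_levels"], spec["breed_effects"]))
    gender_fx = dict(zip(spec["gender_levels"], spec["gender_effects"]))
    system_fx = dict(zip(spec["system_levels"], spec["system_effects"]))
    fixed = (
        np.array([breed_fx[b] for b in breed])
        + np.array([gender_fx[g] for g in gender])
        + np.array([system_fx[s] for s in system])
        + spec["age_coef"] * (age - 450.0) / 30.0
        + spec["days_ext_coef"] * (days_ext - 30.0) / 10.0
        + spec["diet_me_coef"] * (diet_me - 2.8) / 0.2
        + spec["marbling_coef"] * (marbling - 5.0) / 1.0
    )

    intercept = 10.0
    y = intercept + fixed + tbv + cg_vals + resid

    genetic_var = tbv.var()
    total = genetic_var + cg_vals.var() + resid.var()
    true_h2 = genetic_var / total if total > 0 else 0.0

    trait_table = pd.DataFrame(
        {
            "animal_id": genotypes.animal_ids,
            "trait": y,
            "breed": breed,
            "gender": gender,
            "system": system,
            "age": age,
            "days_ext": days_ext,
            "diet_me": diet_me,
            "marbling": marbling,
            "cg": [f"cg{c + 1}" for c in cg_labels],
        }
    )
    truth = SimTruth(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        true_breeding_values=tbv,
        true_h2_realized=true_h2,
        fixed_effect_values=fixed,
        cg_effects=cg_vals,
        residuals=resid,
    )
    return trait_table, truth


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes + pedigree + trait table + truth.

    The trait table carries the pedigree's sire_id column so downstream
    cross-validation can group by sire family directly.
    """
    genotypes, pedigree = simulate_genotypes(config)
    trait_table, truth = simulate_phenotypes(genotypes, config)
    trait_table = trait_table.merge(pedigree[["animal_id", "sire_id"]], on="animal_id")
    cols = ["animal_id", "sire_id"] + [c for c in trait_table.columns
                                       if c not in ("animal_id", "sire_id")]
    return genotypes, pedigree, trait_table[cols], truth
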