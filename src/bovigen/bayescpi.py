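"""BayesC-pi whole-genome regression by Gibbs sampling.

Model: y_i = mu + sum_j x_ij a_j + e_i with the spike-and-slab mixture
prior (a_j | pi, sigma2_a) ~ (1 - pi) N(0, sigma2_a) + pi delta_0, latent
inclusion indicators gamma_j, scaled inverse chi-square priors on the
common effect variance sigma2_a (df v_a, scale S2_a) and residual variance
sigma2_e (df v_e, scale S2_e), and — in the full BayesC-pi — a uniform
prior on pi sampled through its Beta full conditional.  Fixing pi gives
plain BayesC; fixing pi = 0 together with the variances gives ridge
regression, which serves as a closed-form oracle in the test-suite.

The prior scales are tied to REML variance components of the same trait:

    S2_a = sigma2_u_hat (v_a - 2) / [v_a (1 - pi) sum_j 2 p_j (1 - p_j)]
    S2_e = sigma2_0_hat (v_e - 2) / v_e

with pi frozen at its initial value (the scale must be set before sampling
starts).  Posterior SNP effects are summarised by the unconditional mean
(zero draws included); the per-SNP association statistic is the posterior
inclusion probability (PPI), the post-burn-in mean of gamma_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _gibbs
from .data import GenotypeMatrix
from .exceptions import ConfigError, DataError


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings; defaults are the production-scale values."""

    n_iter: int = 45_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ConfigError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigError("seed must be a non-negative 31-bit integer")


def prior_scales(sigma2_u_hat: float, sigma2_0_hat: float,
                 v_a: float = 4.0, v_e: float = 10.0,
                 pi: float = 0.9, allele_freqs=None):
    """Prior scale parameters (S2_a, S2_e) from REML variance components."""
    if v_a <= 2 or v_e <= 2:
        raise ConfigError("prior degrees of freedom must exceed 2")
    if pi >= 1.0:
        raise ConfigError("pi = 1 makes the effect-variance scale undefined")
    p = np.asarray(allele_freqs, dtype=float)
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum2pq <= 0.0:
        raise ConfigError("sum of 2 p (1 - p) must be positive")
    s2_a = sigma2_u_hat * (v_a - 2.0) / (v_a * (1.0 - pi) * sum2pq)
    s2_e = sigma2_0_hat * (v_e - 2.0) / v_e
    return float(s2_a), float(s2_e)


def gebv_from_effects(effect_mean, genotypes) -> np.ndarray:
    """Genomic breeding values GEBV_i = sum_j x_ij a_j.

    ``effect_mean`` may be a pd.Series indexed by SNP id (aligned against a
    GenotypeMatrix's map) or a plain vector of matching length.
    """
    if isinstance(genotypes, GenotypeMatrix):
        X = genotypes.dosages
        if isinstance(effect_mean, pd.Series):
            ids = genotypes.snp_map["snp_id"]
            if not ids.isin(effect_mean.index).all():
                raise DataError("SNP ids in genotypes missing from effect vector")
            effect_mean = effect_mean.loc[ids].to_numpy()
    else:
        X = np.asarray(genotypes, dtype=float)
        effect_mean = np.asarray(effect_mean, dtype=float)
    effect_mean = np.asarray(effect_mean, dtype=float)
    if X.shape[1] != len(effect_mean):
        raise DataError(
            f"{X.shape[1]} genotype columns vs {len(effect_mean)} effects"
        )
    return X @ effect_mean


@dataclass
class BayesCPiResults:
    """Posterior summary of one chain."""

    effect_mean: np.ndarray        # unconditional mean of a_j (zeros included)
    ppi: np.ndarray                # posterior inclusion probability per SNP
    mu_chain: np.ndarray
    pi_chain: np.ndarray
    sigma2_a_chain: np.ndarray
    sigma2_e_chain: np.ndarray
    config: ChainConfig
    snp_map: pd.DataFrame | None = None
    model: "BayesCPi" = None

    @property
    def n_samples(self) -> int:
        return len(self.mu_chain)

    @property
    def pi_mean(self) -> float:
        return float(self.pi_chain.mean())

    def predict(self, genotypes) -> np.ndarray:
        """GEBVs for (possibly new) animals from the posterior-mean effects."""
        if self.snp_map is not None and isinstance(genotypes, GenotypeMatrix):
            eff = pd.Series(self.effect_mean,
                            index=self.snp_map["snp_id"].to_numpy())
            return gebv_from_effects(eff, genotypes)
        return gebv_from_effects(self.effect_mean, genotypes)

    def to_frame(self) -> pd.DataFrame:
        """Per-SNP table (snp_id, chrom, pos, effect_mean, ppi)."""
        if self.snp_map is not None:
            out = self.snp_map[["snp_id", "chrom", "pos"]].copy()
        else:
            out = pd.DataFrame({"snp_id": np.arange(len(self.ppi))})
        out["effect_mean"] = self.effect_mean
        out["ppi"] = self.ppi
        return out

    def summary(self) -> str:
        lines = [
            "BayesC-pi Gibbs sampler",
            "=" * 46,
            f"{'SNPs':<28}{len(self.ppi)}",
            f"{'chain length':<28}{self.config.n_iter}",
            f"{'burn-in':<28}{self.config.burn_in}",
            f"{'posterior samples':<28}{self.n_samples}",
            "-" * 46,
            f"{'E[mu | y]':<28}{self.mu_chain.mean():.6g}",
            f"{'E[pi | y]':<28}{self.pi_mean:.4f}",
            f"{'E[sigma2_a | y]':<28}{self.sigma2_a_chain.mean():.6g}",
            f"{'E[sigma2_e | y]':<28}{self.sigma2_e_chain.mean():.6g}",
            f"{'max PPI':<28}{self.ppi.max():.4f}",
            f"{'SNPs with PPI >= 0.5':<28}{int((self.ppi >= 0.5).sum())}",
        ]
        return "\n".join(lines)


class BayesCPi:
    """BayesC-pi model over adjusted phenotypes and complete dosages.

    Parameters
    ----------
    y : array
        Adjusted phenotypes y*.
    genotypes : GenotypeMatrix or (n, M) array
        Complete dosage codes {0, 1, 2}.
    sigma2_u_hat, sigma2_0_hat : float, optional
        REML additive and residual variances feeding the prior scales; if
        omitted each defaults to half the phenotypic variance.
    pi_mode : "sampled" or "fixed"
        Sample pi from its Beta full conditional, or hold it at
        ``pi_fixed`` (plain BayesC).
    fix_sigma2_a, fix_sigma2_e : float, optional
        Freeze a variance at the given value (oracle/diagnostic use).
    """

    def __init__(self, y, genotypes, sigma2_u_hat=None, sigma2_0_hat=None,
                 v_a: float = 4.0, v_e: float = 10.0, pi_init: float = 0.9,
                 pi_mode: str = "sampled", pi_fixed: float | None = None,
                 fix_sigma2_a: float | None = None,
                 fix_sigma2_e: float | None = None,
                 random_order: bool = False):
        self.y = np.asarray(y, dtype=float)
        if isinstance(genotypes, GenotypeMatrix):
            if genotypes.has_missing:
                raise DataError("BayesC-pi requires complete dosages; run QC first")
            self.X = np.asfortranarray(genotypes.dosages)
            self.snp_map = genotypes.snp_map
            freqs = genotypes.allele_freqs()
        else:
            self.X = np.asfortranarray(np.asarray(genotypes, dtype=float))
            if np.isnan(self.X).any():
                raise DataError("BayesC-pi requires complete dosages")
            self.snp_map = None
            freqs = self.X.mean(axis=0) / 2.0
        if self.X.shape[0] != len(self.y):
            raise DataError("genotype rows must match phenotype length")
        if len(self.y) < 30:
            raise DataError("need at least 30 phenotyped animals")
        if pi_mode not in ("sampled", "fixed"):
            raise ConfigError("pi_mode must be 'sampled' or 'fixed'")
        if pi_mode == "fixed" and pi_fixed is None:
            raise ConfigError("pi_mode='fixed' requires pi_fixed")

        vy = float(np.var(self.y))
        self.sigma2_u_hat = vy / 2.0 if sigma2_u_hat is None else float(sigma2_u_hat)
        self.sigma2_0_hat = vy / 2.0 if sigma2_0_hat is None else float(sigma2_0_hat)
        self.v_a, self.v_e = float(v_a), float(v_e)
        self.pi_mode = pi_mode
        self.pi_init = float(pi_fixed) if pi_mode == "fixed" else float(pi_init)
        self.random_order = bool(random_order)
        self.fix_sigma2_a = fix_sigma2_a
        self.fix_sigma2_e = fix_sigma2_e
        # the scale formula references pi; it is frozen at the initial value
        pi_for_scale = min(self.pi_init, 1.0 - 1e-12) if self.pi_init < 1.0 else 0.0
        self.s2_a, self.s2_e = prior_scales(
            self.sigma2_u_hat, self.sigma2_0_hat, self.v_a, self.v_e,
            pi=pi_for_scale, allele_freqs=freqs,
        )

    def fit(self, config: ChainConfig | None = None, *, n_iter=None,
            burn_in=None, thin=None, seed=None) -> BayesCPiResults:
        """Run the Gibbs chain and summarise the posterior."""
        if config is None:
            config = ChainConfig()
        overrides = {k: v for k, v in
                     dict(n_iter=n_iter, burn_in=burn_in, thin=thin,
                          seed=seed).items() if v is not None}
        if overrides:
            config = ChainConfig(**{**config.__dict__, **overrides})
        config.validate()

        sigma2_a0 = self.s2_a if self.fix_sigma2_a is None else float(self.fix_sigma2_a)
        if sigma2_a0 <= 0.0 and self.fix_sigma2_a is None:
            sigma2_a0 = 0.0
        sigma2_e0 = (self.sigma2_0_hat if self.fix_sigma2_e is None
                     else float(self.fix_sigma2_e))
        if sigma2_e0 <= 0.0:
            raise ConfigError("initial residual variance must be positive")

        out = _gibbs.run_chain(
            self.y, self.X,
            int(config.n_iter), int(config.burn_in), int(config.thin),
            int(config.seed),
            self.v_a, self.v_e, self.s2_a, self.s2_e,
            self.pi_init, self.pi_mode == "sampled",
            sigma2_a0, sigma2_e0,
            self.fix_sigma2_a is None, self.fix_sigma2_e is None,
            self.random_order,
        )
        effect_mean, ppi, mu_c, pi_c, s2a_c, s2e_c = out
        return BayesCPiResults(
            effect_mean=effect_mean, ppi=ppi, mu_chain=mu_c, pi_chain=pi_c,
            sigma2_a_chain=s2a_c, sigma2_e_chain=s2e_c, config=config,
            snp_map=self.snp_map, model=self,
        )
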