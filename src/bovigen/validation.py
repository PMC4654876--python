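"""Simulation studies validating the pipeline's statistical behaviour.

Each function runs a self-contained study on synthetic cohorts and returns
plain numbers: parameter recovery of the REML heritability, the contrast
between QTL-block and null-SNP posterior inclusion probabilities, the
genome-wise type-I error of the permutation threshold, the accuracy
comparison between BayesC-pi and GBLUP under contrasting genetic
architectures, agreement of independent algebraic routes (Gibbs sampler vs
ridge closed form, mixed-model equations vs kernel regression, AI-REML vs a
profile-likelihood grid), and the structural invariants of the VanRaden
genomic relationship matrix.

Problem sizes are chosen to finish on a single desktop CPU in minutes; the
heritability-recovery study runs at the full cohort scale (1500 animals,
2000 SNPs), the Monte-Carlo-heavy studies at reduced scale.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

from .bayescpi import BayesCPi, ChainConfig
from .gwas import permutation_threshold
from .kinship import grm_vanraden1
from .prediction import cross_validate, gblup_predict, make_folds
from .syndata import SimConfig, simulate_cohort, simulate_genotypes
from .varcomp import MixedREML


def reml_h2_recovery(n_seeds: int = 10, n_animals: int = 1500,
                     n_snps: int = 2000, h2: float = 0.5,
                     cg_var_fraction: float = 0.1, seed: int = 0) -> dict:
    """Mean REML heritability estimate over replicate cohorts simulated at a
    known h2 (fully adjusted model, cg variance in the denominator)."""
    values = []
    for i in range(n_seeds):
        cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, h2=h2,
                        cg_var_fraction=cg_var_fraction, seed=seed + i)
        geno, _, traits, _ = simulate_cohort(cfg)
        fit = MixedREML.from_trait_table(traits, grm_vanraden1(geno),
                                         marbling=True).fit()
        values.append(fit.h2)
    return {"h2_true": h2, "h2_hat_mean": float(np.mean(values)),
            "h2_hat_values": values, "n": n_animals}


def qtl_ppi_contrast(n_seeds: int = 5, n_animals: int = 1000,
                     n_snps: int = 2000, qtl_var_fraction: float = 0.25,
                     chain: ChainConfig | None = None, seed: int = 0) -> dict:
    """PPI of the LD block holding a large QTL (25% of genetic variance by
    default) versus the median PPI of SNPs in QTL-free blocks."""
    chain = chain or ChainConfig(n_iter=2000, burn_in=500)
    block_max, null_median = [], []
    for i in range(n_seeds):
        cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, h2=0.5,
                        cg_var_fraction=0.1, n_large_qtl=1,
                        large_qtl_var_fraction=qtl_var_fraction,
                        n_poly_qtl=100, seed=seed + i)
        geno, _, traits, truth = simulate_cohort(cfg)
        fit = MixedREML.from_trait_table(traits, grm_vanraden1(geno),
                                         marbling=True).fit()
        y = fit.adjust().to_numpy()
        post = BayesCPi(y, geno, sigma2_u_hat=fit.sigma2_a,
                        sigma2_0_hat=fit.sigma2_e).fit(
            ChainConfig(chain.n_iter, chain.burn_in, chain.thin,
                        seed + i + 10_000))
        q = truth.qtl_indices[np.argmax(np.abs(truth.qtl_effects))]
        bs = cfg.ld_block_size
        blk = (q // bs) * bs
        block_max.append(float(post.ppi[blk:blk + bs].max()))
        qtl_blocks = set(int(j) // bs for j in truth.qtl_indices)
        null = np.array([j // bs not in qtl_blocks for j in range(n_snps)])
        null_median.append(float(np.median(post.ppi[null])))
    return {"block_max_ppi_min": float(min(block_max)),
            "null_median_ppi_max": float(max(null_median)),
            "block_max_ppi": block_max, "null_median_ppi": null_median,
            "n": n_animals}


def permutation_type_i(n_replicates: int = 100, n_perm: int = 50,
                       n_animals: int = 200, n_snps: int = 100,
                       alpha: float = 0.05,
                       chain: ChainConfig | None = None,
                       seed: int = 0) -> dict:
    """Fraction of pure-noise phenotypes whose unpermuted max PPI exceeds
    the permutation-derived genome-wise threshold (nominal level alpha)."""
    chain = chain or ChainConfig(n_iter=500, burn_in=100)
    geno, _ = simulate_genotypes(
        SimConfig(n_animals=n_animals, n_snps=n_snps, n_sires=20, h2=0.0,
                  n_poly_qtl=1, seed=seed))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_replicates):
        y = rng.standard_normal(n_animals)
        perm = permutation_threshold(y, geno, alpha=alpha, n_perm=n_perm,
                                     chain=chain,
                                     seed=int(rng.integers(2**31)))
        obs = BayesCPi(y, geno).fit(
            ChainConfig(chain.n_iter, chain.burn_in, chain.thin,
                        int(rng.integers(2**31))))
        if obs.ppi.max() > perm.threshold:
            exceed += 1
    return {"rate": exceed / n_replicates, "nominal": alpha,
            "n": n_replicates}


def method_accuracy_comparison(architecture: str, n_seeds: int = 5,
                               n_animals: int = 600, n_snps: int = 600,
                               k: int = 5, chain: ChainConfig | None = None,
                               seed: int = 0) -> dict:
    """Mean realized accuracy of BayesC-pi and GBLUP under sire-family CV.

    ``architecture`` is "large_qtl" (two QTL carrying half the genetic
    variance) or "polygenic" (300 small QTL, no large effects).
    """
    if architecture == "large_qtl":
        arch = dict(n_large_qtl=2, large_qtl_var_fraction=0.5, n_poly_qtl=100)
    elif architecture == "polygenic":
        arch = dict(n_large_qtl=0, large_qtl_var_fraction=0.0, n_poly_qtl=300)
    else:
        raise ValueError(f"unknown architecture: {architecture}")
    chain = chain or ChainConfig(n_iter=2000, burn_in=400)
    acc = {"bayescpi": [], "gblup": []}
    for i in range(n_seeds):
        cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, n_sires=40,
                        h2=0.5, cg_var_fraction=0.1, seed=seed + i, **arch)
        geno, ped, traits, _ = simulate_cohort(cfg)
        G = grm_vanraden1(geno)
        fit = MixedREML.from_trait_table(traits, G, marbling=True).fit()
        y = fit.adjust().to_numpy()
        folds = make_folds(ped, traits["breed"].to_numpy(), k=k, seed=seed + i)
        rep = cross_validate(y, folds, h2=fit.h2, sigma2_a=fit.sigma2_a,
                             sigma2_e=fit.sigma2_e, grm=G, genotypes=geno,
                             methods=("gblup", "bayescpi"), chain=chain,
                             seed=seed + i + 500)
        agg = rep.aggregate().set_index("method")["accuracy_mean"]
        acc["bayescpi"].append(float(agg["bayescpi"]))
        acc["gblup"].append(float(agg["gblup"]))
    return {"architecture": architecture,
            "accuracy_bayescpi": float(np.mean(acc["bayescpi"])),
            "accuracy_gblup": float(np.mean(acc["gblup"])),
            "per_seed": acc, "n": n_animals}


def ridge_oracle_correlation(n_animals: int = 200, n_snps: int = 50,
                             n_iter: int = 6000, burn_in: int = 1000,
                             seed: int = 0) -> dict:
    """Correlation between BayesC posterior-mean effects (pi = 0, fixed
    variances) and the exact joint-normal (ridge with intercept) solution."""
    cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, n_sires=20, h2=0.5,
                    cg_var_fraction=0.0, n_poly_qtl=20, seed=seed)
    geno, _, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    sa, se = 0.02, 0.6
    post = BayesCPi(y, geno, pi_mode="fixed", pi_fixed=0.0,
                    fix_sigma2_a=sa, fix_sigma2_e=se).fit(
        ChainConfig(n_iter, burn_in, 1, seed + 1))
    X = geno.dosages
    n, M = X.shape
    lhs = np.zeros((M + 1, M + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = lhs[1:, 0] = X.sum(axis=0)
    lhs[1:, 1:] = X.T @ X + (se / sa) * np.eye(M)
    exact = np.linalg.solve(lhs, np.concatenate([[y.sum()], X.T @ y]))[1:]
    r = float(np.corrcoef(exact, post.effect_mean)[0, 1])
    return {"correlation": r, "n": n_animals}


def gblup_route_agreement(n_animals: int = 250, n_snps: int = 300,
                          seed: int = 0) -> dict:
    """Max relative difference between the MME and kernel GBLUP routes."""
    cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, n_sires=25, h2=0.5,
                    cg_var_fraction=0.0, seed=seed)
    geno, _, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    G = grm_vanraden1(geno)
    ti = np.arange(n_animals - 50)
    vi = np.arange(n_animals - 50, n_animals)
    e1 = gblup_predict(y[ti], G, ti, vi, 0.5, 0.5, route="kernel")
    e2 = gblup_predict(y[ti], G, ti, vi, 0.5, 0.5, route="mme")
    rel = float(np.abs(e1 - e2).max() / np.abs(e1).max())
    return {"max_rel_diff": rel, "n": n_animals}


def reml_grid_oracle_gap(n_animals: int = 300, n_snps: int = 400,
                         seed: int = 3) -> dict:
    """|h2| gap between the two-component AI-REML fit and an exhaustive 1-D
    profile-restricted-likelihood grid on the eigenbasis of G."""
    cfg = SimConfig(n_animals=n_animals, n_snps=n_snps, h2=0.4,
                    cg_var_fraction=0.0, n_poly_qtl=int(n_snps * 0.875),
                    seed=seed)
    geno, _, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    G = grm_vanraden1(geno)
    fit = MixedREML(y, np.ones((n_animals, 1)), None, G.values).fit()
    h2_fit = fit.heritability(include_cg=False)

    d, U = eigh(G.with_ridge(1e-6))
    ty = U.T @ y
    tX = U.T @ np.ones((n_animals, 1))
    n, p = n_animals, 1

    def rll(h2):
        lam = h2 * d + (1 - h2)
        Vi_y, Vi_X = ty / lam, tX / lam[:, None]
        XtViX = tX.T @ Vi_X
        beta = np.linalg.solve(XtViX, tX.T @ Vi_y)
        quad = float(ty @ (Vi_y - Vi_X[:, 0] * beta[0]))
        s_hat = quad / (n - p)
        return -0.5 * (np.log(lam).sum() + (n - p) * np.log(s_hat)
                       + np.linalg.slogdet(XtViX)[1] + (n - p))

    grid = np.linspace(1e-3, 0.999, 2000)
    h2_grid = grid[int(np.argmax([rll(h) for h in grid]))]
    return {"h2_fit": float(h2_fit), "h2_grid": float(h2_grid),
            "abs_gap": float(abs(h2_fit - h2_grid)), "n": n_animals}


def grm_invariants(n_animals: int = 2000, n_snps: int = 1000,
                   seed: int = 0) -> dict:
    """Row-sum and mean-diagonal invariants of VanRaden method-1 G on a
    cohort in Hardy-Weinberg proportions."""
    geno, _ = simulate_genotypes(
        SimConfig(n_animals=n_animals, n_snps=n_snps, seed=seed))
    G = grm_vanraden1(geno).values
    return {"max_abs_row_sum": float(np.abs(G.sum(axis=1)).max()),
            "mean_diagonal": float(np.diag(G).mean()), "n": n_animals}


def fold_structure(n_animals: int = 1366, n_sires: int = 60, k: int = 10,
                   seed: int = 0) -> dict:
    """Structural audit of the default cross-validation splitter on a
    cohort-sized synthetic pedigree: fold count, sire-family exclusivity,
    coverage, and balance."""
    cfg = SimConfig(n_animals=n_animals, n_snps=50, n_sires=n_sires,
                    seed=seed)
    geno, ped, traits, _ = simulate_cohort(cfg)
    folds = make_folds(ped, traits["breed"].to_numpy(), k=k, seed=seed)
    folds.validate()
    fam_folds = folds.fold_id.groupby(folds.sire_of).nunique()
    sizes = folds.fold_id.value_counts()
    return {
        "n_folds": int(folds.fold_id.nunique()),
        "n_animals_covered": int(folds.fold_id.notna().sum()),
        "max_folds_per_family": int(fam_folds.max()),
        "size_min": int(sizes.min()), "size_max": int(sizes.max()),
        "n": n_animals,
    }
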