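import numpy as np
import pytest

from bovigen import ConfigError, SimConfig, simulate_cohort, simulate_genotypes, \
    simulate_phenotypes


@pytest.mark.parametrize("bad", [
    dict(h2=0.7, cg_var_fraction=0.4),
    dict(n_poly_qtl=150),
    dict(allele_freq_range=(0.0, 0.5)),
    dict(missing_rate=1.0),
    dict(n_large_qtl=2, large_qtl_var_fraction=0.0),
    dict(h2=-0.1),
    dict(ld_block_size=0),
])
def test_invalid_config_raises(bad):
    with pytest.raises(ConfigError):
        SimConfig(n_animals=50, n_snps=100, **bad).validate()


def test_no_missing_when_rate_zero():
    geno, _ = simulate_genotypes(SimConfig(n_animals=80, n_snps=60,
                                           missing_rate=0.0, seed=1))
    assert not geno.has_missing
    assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}


def test_missing_rate_realised():
    geno, _ = simulate_genotypes(SimConfig(n_animals=400, n_snps=300,
                                           missing_rate=0.05, seed=2))
    assert np.isnan(geno.dosages).mean() == pytest.approx(0.05, abs=0.01)


def test_ld_block_one_gives_uncorrelated_adjacent_snps():
    """With single-SNP blocks, adjacent dosages are independent draws."""
    rs = []
    for seed in range(10):
        cfg = SimConfig(n_animals=300, n_snps=100, n_chromosomes=1,
                        ld_block_size=1, seed=seed)
        geno, _ = simulate_genotypes(cfg)
        X = geno.dosages
        sd = X.std(axis=0)
        r = [abs(np.corrcoef(X[:, j], X[:, j + 1])[0, 1])
             for j in range(99) if sd[j] > 0 and sd[j + 1] > 0]
        rs.append(np.mean(r))
    assert np.mean(rs) < 0.08


def test_ld_decays_within_block():
    cfg = SimConfig(n_animals=800, n_snps=200, n_chromosomes=1,
                    ld_block_size=20, ld_decay=0.9, seed=3)
    geno, _ = simulate_genotypes(cfg)
    X = geno.dosages
    r_adj, r_far = [], []
    for b in range(0, 200, 20):
        r_adj.append(abs(np.corrcoef(X[:, b], X[:, b + 1])[0, 1]))
        r_far.append(abs(np.corrcoef(X[:, b], X[:, b + 15])[0, 1]))
    assert np.mean(r_adj) > np.mean(r_far)
    assert np.mean(r_adj) > 0.3


def test_allele_frequency_targeting():
    # large founder pool and many small sire families make the observed
    # frequency an effectively binomial draw around the target
    cfg = SimConfig(n_animals=1000, n_snps=120, allele_freq_range=(0.3, 0.3),
                    n_founder_haplotypes=4000, ld_block_size=1, n_sires=500,
                    seed=4)
    geno, _ = simulate_genotypes(cfg)
    freqs = geno.allele_freqs()
    assert np.all(np.abs(freqs - 0.3) <= 0.05)
    assert np.abs(freqs - 0.3).mean() < 0.02


def test_half_sib_family_sizes_balanced():
    cfg = SimConfig(n_animals=200, n_snps=50, n_sires=10, seed=5)
    _, ped = simulate_genotypes(cfg)
    sizes = ped.groupby("sire_id").size()
    assert len(sizes) == 10
    assert sizes.min() >= 19 and sizes.max() <= 21
    assert ped["dam_id"].isna().all()


def test_simulation_bitwise_deterministic():
    cfg = SimConfig(n_animals=120, n_snps=80, missing_rate=0.01,
                    n_large_qtl=1, large_qtl_var_fraction=0.3, seed=11)
    g1, p1, t1, tr1 = simulate_cohort(cfg)
    g2, p2, t2, tr2 = simulate_cohort(cfg)
    assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)
    assert t1.equals(t2)
    assert np.array_equal(tr1.true_breeding_values, tr2.true_breeding_values)


def test_zero_heritability_gives_null_breeding_values():
    cfg = SimConfig(n_animals=200, n_snps=100, h2=0.0, seed=6)
    geno, _ = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(geno, cfg)
    assert np.all(truth.true_breeding_values == 0.0)
    assert truth.true_h2_realized == 0.0


def test_realized_h2_matches_config_at_large_n():
    cfg = SimConfig(n_animals=5000, n_snps=300, h2=0.5, cg_var_fraction=0.1,
                    n_poly_qtl=150, seed=7)
    geno, _ = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(geno, cfg)
    assert 0.45 <= truth.true_h2_realized <= 0.55


def test_breeding_values_equal_centred_dosage_times_effects(small_cohort):
    _, geno, _, _, truth = small_cohort
    X = geno.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    Xc = X - X.mean(axis=0)
    tbv = Xc[:, truth.qtl_indices] @ truth.qtl_effects
    np.testing.assert_allclose(tbv, truth.true_breeding_values, atol=1e-10)


def test_large_qtl_carries_requested_variance_share():
    cfg = SimConfig(n_animals=2000, n_snps=300, h2=0.5, cg_var_fraction=0.0,
                    n_large_qtl=1, large_qtl_var_fraction=0.25,
                    n_poly_qtl=100, seed=8)
    geno, _ = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(geno, cfg)
    k = np.argmax(np.abs(truth.qtl_effects))
    j = truth.qtl_indices[k]
    var_q = geno.dosages[:, j].var() * truth.qtl_effects[k] ** 2
    share = var_q / truth.true_breeding_values.var()
    assert share == pytest.approx(0.25, abs=0.05)


def test_phenotype_regression_on_tbv_has_unit_slope():
    cfg = SimConfig(n_animals=4000, n_snps=200, h2=0.4, cg_var_fraction=0.05,
                    n_poly_qtl=100, seed=9)
    geno, _ = simulate_genotypes(cfg)
    traits, truth = simulate_phenotypes(geno, cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    tbv = truth.true_breeding_values
    slope = np.cov(y, tbv)[0, 1] / np.cov(y, tbv)[1, 1]
    assert slope == pytest.approx(1.0, abs=0.1)


def test_pure_noise_without_genetic_or_cg_variance():
    cfg = SimConfig(n_animals=1500, n_snps=100, h2=0.0, cg_var_fraction=0.0,
                    seed=10)
    geno, _ = simulate_genotypes(cfg)
    traits, truth = simulate_phenotypes(geno, cfg)
    resid = traits["trait"].to_numpy() - truth.fixed_effect_values - 10.0
    assert resid.var() == pytest.approx(1.0, abs=0.02)
    np.testing.assert_allclose(resid, truth.residuals, atol=1e-10)
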