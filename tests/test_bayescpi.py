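import numpy as np
import pytest

from bovigen import (BayesCPi, ChainConfig, ConfigError, DataError,
                     SimConfig, gebv_from_effects, prior_scales,
                     simulate_cohort, simulate_genotypes)


def _freqs_sum2pq(target):
    """Allele-frequency vector with sum 2p(1-p) equal to ``target``."""
    k = int(round(target / 0.5))   # p = 0.5 contributes 0.5 each
    return np.full(k, 0.5)


@pytest.mark.parametrize("kw, expected", [
    # S2_a = 1 * (4-2) / (4 * 0.1 * 10) = 0.5
    (dict(sigma2_u_hat=1.0, sigma2_0_hat=1.0, v_a=4, v_e=10, pi=0.9,
          allele_freqs=_freqs_sum2pq(10.0)), (0.5, 0.8)),
    (dict(sigma2_u_hat=0.0, sigma2_0_hat=1.0, v_a=4, v_e=10, pi=0.9,
          allele_freqs=_freqs_sum2pq(10.0)), (0.0, 0.8)),
])
def test_prior_scale_formulas(kw, expected):
    s2a, s2e = prior_scales(**kw)
    assert s2a == pytest.approx(expected[0])
    assert s2e == pytest.approx(expected[1])


def test_prior_scales_pi_one_rejected():
    with pytest.raises(ConfigError):
        prior_scales(1.0, 1.0, pi=1.0, allele_freqs=_freqs_sum2pq(10.0))


def test_prior_scales_low_df_rejected():
    with pytest.raises(ConfigError):
        prior_scales(1.0, 1.0, v_a=2.0, allele_freqs=_freqs_sum2pq(10.0))


def test_gebv_hand_example_and_linearity():
    X = np.array([[2.0, 1.0], [0.0, 2.0]])
    eff = np.array([0.5, -0.2])
    gebv = gebv_from_effects(eff, X)
    assert gebv[0] == pytest.approx(0.8)
    np.testing.assert_allclose(gebv_from_effects(2 * eff, X), 2 * gebv)
    np.testing.assert_allclose(gebv_from_effects(np.zeros(2), X), 0.0)
    with pytest.raises(DataError):
        gebv_from_effects(np.zeros(3), X)


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = SimConfig(n_animals=200, n_snps=50, n_sires=20, h2=0.5,
                    cg_var_fraction=0.0, n_poly_qtl=20, seed=5)
    geno, ped, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    return geno, y


def test_forced_exclusion_pi_one(tiny_cohort):
    geno, y = tiny_cohort
    post = BayesCPi(y, geno, pi_mode="fixed", pi_fixed=1.0).fit(
        n_iter=300, burn_in=50, seed=1)
    assert np.all(post.ppi == 0.0)
    assert np.all(post.effect_mean == 0.0)
    assert np.all(post.predict(geno) == 0.0)


def test_bayesc_pi_zero_matches_ridge_oracle(tiny_cohort):
    """With pi = 0 and both variances fixed, the posterior mean effect is the
    joint normal (ridge-with-intercept) solution."""
    geno, y = tiny_cohort
    sa, se = 0.02, 0.6
    post = BayesCPi(y, geno, pi_mode="fixed", pi_fixed=0.0,
                    fix_sigma2_a=sa, fix_sigma2_e=se).fit(
        n_iter=6000, burn_in=1000, seed=9)
    X = geno.dosages
    n, M = X.shape
    lam = se / sa
    lhs = np.zeros((M + 1, M + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = lhs[1:, 0] = X.sum(axis=0)
    lhs[1:, 1:] = X.T @ X + lam * np.eye(M)
    rhs = np.concatenate([[y.sum()], X.T @ y])
    ridge = np.linalg.solve(lhs, rhs)[1:]
    assert np.corrcoef(ridge, post.effect_mean)[0, 1] > 0.99
    assert np.abs(ridge - post.effect_mean).max() < 0.05 * y.std()


def test_tiny_instance_matches_analytic_gaussian_posterior():
    """n = 50, M = 5, pi = 0, fixed variances: sampler mean equals the exact
    multivariate-normal posterior mean."""
    rng = np.random.default_rng(7)
    X = rng.binomial(2, 0.4, size=(50, 5)).astype(float)
    beta = np.array([0.5, -0.3, 0.0, 0.2, 0.0])
    y = X @ beta + rng.standard_normal(50) * 0.7
    sa, se = 0.3, 0.49
    post = BayesCPi(y, X, pi_mode="fixed", pi_fixed=0.0,
                    fix_sigma2_a=sa, fix_sigma2_e=se).fit(
        n_iter=20000, burn_in=2000, seed=3)
    lam = se / sa
    lhs = np.zeros((6, 6))
    lhs[0, 0] = 50
    lhs[0, 1:] = lhs[1:, 0] = X.sum(axis=0)
    lhs[1:, 1:] = X.T @ X + lam * np.eye(5)
    exact = np.linalg.solve(lhs, np.concatenate([[y.sum()], X.T @ y]))[1:]
    np.testing.assert_allclose(post.effect_mean, exact, atol=0.03)


def test_pure_noise_drives_pi_towards_one(tiny_cohort):
    geno, _ = tiny_cohort
    rng = np.random.default_rng(11)
    y = rng.standard_normal(geno.n_animals)
    post = BayesCPi(y, geno).fit(n_iter=2000, burn_in=500, seed=2)
    assert post.pi_mean > 0.8
    assert np.median(post.ppi) < 0.2


def test_chain_bitwise_reproducible(tiny_cohort):
    geno, y = tiny_cohort
    model = BayesCPi(y, geno)
    a = model.fit(n_iter=800, burn_in=200, seed=123)
    b = model.fit(n_iter=800, burn_in=200, seed=123)
    assert np.array_equal(a.effect_mean, b.effect_mean)
    assert np.array_equal(a.ppi, b.ppi)
    assert np.array_equal(a.sigma2_e_chain, b.sigma2_e_chain)
    c = model.fit(n_iter=800, burn_in=200, seed=124)
    assert not np.array_equal(a.sigma2_e_chain, c.sigma2_e_chain)


def test_chains_are_finite_and_positive(tiny_cohort):
    geno, y = tiny_cohort
    post = BayesCPi(y, geno).fit(n_iter=1000, burn_in=200, seed=6)
    for chain in (post.sigma2_a_chain, post.sigma2_e_chain):
        assert np.all(np.isfinite(chain))
        assert np.all(chain > 0)
    assert np.all((post.pi_chain >= 0) & (post.pi_chain <= 1))
    assert np.all((post.ppi >= 0) & (post.ppi <= 1))
    # zero PPI forces a zero posterior-mean effect
    assert np.all(post.effect_mean[post.ppi == 0.0] == 0.0)
    assert post.n_samples == 800


def test_large_qtl_is_detected():
    cfg = SimConfig(n_animals=400, n_snps=200, h2=0.5, cg_var_fraction=0.0,
                    n_large_qtl=1, large_qtl_var_fraction=0.5,
                    n_poly_qtl=50, seed=21)
    geno, _, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    post = BayesCPi(y, geno).fit(n_iter=2000, burn_in=500, seed=4)
    q = truth.qtl_indices[np.argmax(np.abs(truth.qtl_effects))]
    blk = (q // cfg.ld_block_size) * cfg.ld_block_size
    assert post.ppi[blk:blk + cfg.ld_block_size].max() > 0.8


def test_input_validation():
    X = np.random.default_rng(0).binomial(2, 0.5, (40, 10)).astype(float)
    y = np.zeros(40)
    with pytest.raises(DataError):
        BayesCPi(y[:20], X[:20])            # n < 30
    Xm = X.copy()
    Xm[0, 0] = np.nan
    with pytest.raises(DataError):
        BayesCPi(y, Xm)
    with pytest.raises(ConfigError):
        BayesCPi(y, X, pi_mode="fixed")     # missing pi_fixed
    with pytest.raises(ConfigError):
        BayesCPi(y, X).fit(ChainConfig(n_iter=100, burn_in=100))
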