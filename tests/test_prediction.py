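import numpy as np
import pandas as pd
import pytest

from bovigen import (ChainConfig, ConfigError, DataError, SimConfig,
                     cross_validate, evaluate, gblup_predict, grm_vanraden1,
                     make_folds, pblup_predict, a_matrix, simulate_cohort)


def _ped(animals, sires):
    return pd.DataFrame({"animal_id": animals, "sire_id": sires,
                         "dam_id": pd.NA})


def test_folds_sire_disjoint_balanced():
    animals = [f"a{i}" for i in range(500)]
    sires = [f"s{i // 10}" for i in range(500)]       # 50 families of 10
    breeds = np.array(["AN", "CH", "HE", "GV", "TX"])[
        np.arange(500) % 5]
    folds = make_folds(_ped(animals, sires), breeds, k=10, seed=1)
    sizes = folds.fold_id.value_counts()
    assert sorted(folds.fold_id.unique()) == list(range(1, 11))
    assert sizes.min() >= 35 and sizes.max() <= 65   # within +/-30% of 50
    # exhaustive overlap check: each family in exactly one fold
    fam_folds = folds.fold_id.groupby(folds.sire_of).nunique()
    assert (fam_folds == 1).all()
    folds.validate()


def test_folds_k_equals_number_of_families():
    animals = [f"a{i}" for i in range(40)]
    sires = [f"s{i // 8}" for i in range(40)]          # 5 families
    breeds = np.array(["X"] * 40)
    folds = make_folds(_ped(animals, sires), breeds, k=5, seed=0)
    for f in range(1, 6):
        fams = folds.sire_of[folds.fold_id == f].unique()
        assert len(fams) == 1


def test_folds_breed_too_small_named_in_error():
    animals = [f"a{i}" for i in range(100)]
    sires = [f"s{i // 5}" for i in range(100)]
    breeds = np.array(["common"] * 97 + ["rare"] * 3)
    with pytest.raises(ConfigError, match="rare"):
        make_folds(_ped(animals, sires), breeds, k=10, seed=0)


def test_folds_deterministic():
    animals = [f"a{i}" for i in range(200)]
    sires = [f"s{i // 8}" for i in range(200)]
    breeds = np.array(["A", "B"])[np.arange(200) % 2]
    f1 = make_folds(_ped(animals, sires), breeds, k=5, seed=9)
    f2 = make_folds(_ped(animals, sires), breeds, k=5, seed=9)
    assert f1.fold_id.equals(f2.fold_id)


# ---- BLUP routes --------------------------------------------------------


@pytest.fixture(scope="module")
def blup_instance():
    cfg = SimConfig(n_animals=250, n_snps=300, n_sires=25, h2=0.5,
                    cg_var_fraction=0.0, n_poly_qtl=100, seed=31)
    geno, ped, traits, truth = simulate_cohort(cfg)
    y = traits["trait"].to_numpy() - truth.fixed_effect_values
    G = grm_vanraden1(geno)
    idx = np.arange(250)
    return geno, ped, y, G, idx[:200], idx[200:]


def test_gblup_mme_equals_kernel_route(blup_instance):
    _, _, y, G, ti, vi = blup_instance
    e1 = gblup_predict(y[ti], G, ti, vi, 0.5, 0.5, route="kernel")
    e2 = gblup_predict(y[ti], G, ti, vi, 0.5, 0.5, route="mme")
    assert np.abs(e1 - e2).max() / np.abs(e1).max() < 1e-8


def test_gblup_unrelated_validation_gets_zero(blup_instance):
    _, _, y, G, ti, vi = blup_instance
    K = G.values.copy()
    K[np.ix_(vi, ti)] = 0.0
    K[np.ix_(ti, vi)] = 0.0
    ebv = gblup_predict(y[ti], K, ti, vi, 0.5, 0.5)
    np.testing.assert_allclose(ebv, 0.0, atol=1e-10)


def test_gblup_shrinkage_limit_duplicated_animal(blup_instance):
    """As lambda -> 0, a validation animal identical to a training animal
    inherits that animal's centred record."""
    _, _, y, G, ti, vi = blup_instance
    K = G.values.copy()
    dup_train, dup_val = ti[0], vi[0]
    K[dup_val, :] = K[dup_train, :]
    K[:, dup_val] = K[:, dup_train]
    K[dup_val, dup_val] = K[dup_train, dup_train]
    ebv = gblup_predict(y[ti], K, ti, vi, sigma2_a=1e4, sigma2_e=1.0)
    mu = y[ti].mean()
    assert ebv[0] == pytest.approx(y[ti][0] - mu, abs=0.05 * y.std())


def test_pblup_unknown_sire_zero_and_halfsib_informative():
    # two half-sib families plus one founder with no recorded sire
    animals = [f"k{i}" for i in range(6)] + [f"m{i}" for i in range(6)] + ["lone"]
    sires = ["s1"] * 6 + ["s2"] * 6 + [pd.NA]
    ped = _ped(animals, sires)
    A = a_matrix(ped)
    rng = np.random.default_rng(0)
    # family s1 phenotypically high, family s2 low
    y = np.concatenate([rng.standard_normal(5) + 1.0,
                        rng.standard_normal(5) - 1.0])
    ti = np.array([0, 1, 2, 3, 4, 6, 7, 8, 9, 10])
    vi = np.array([5, 12])         # k5 (half-sib of s1 records), lone founder
    ebv = pblup_predict(y, A, ti, vi, 0.5, 0.5)
    assert abs(ebv[0]) > 0.05      # pulled towards its family mean
    assert ebv[1] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_worked_examples():
    rng = np.random.default_rng(3)
    ebv = rng.standard_normal(50)
    m = evaluate(ebv, ebv, h2=0.36)
    assert m["r"] == pytest.approx(1.0)
    assert m["slope"] == pytest.approx(1.0)
    assert m["accuracy"] == pytest.approx(1.0 / 0.6)
    # r = 0.30, h2 = 0.36 -> accuracy 0.50 (construct exact correlation)
    y = 0.30 * (ebv - ebv.mean()) / ebv.std()
    resid = rng.standard_normal(50)
    resid -= np.polyval(np.polyfit(ebv, resid, 1), ebv)   # orthogonalise
    y = y + resid / resid.std() * np.sqrt(1 - 0.09)
    m = evaluate(ebv, y, h2=0.36)
    assert m["accuracy"] == pytest.approx(0.30 / 0.6, abs=1e-6)


def test_evaluate_degenerate_cases():
    y = np.arange(5.0)
    m = evaluate(np.ones(5), y, h2=0.4)
    assert m["degenerate"] and np.isnan(m["accuracy"])
    m = evaluate(y, y, h2=0.0)
    assert np.isnan(m["accuracy"]) and m["r"] == pytest.approx(1.0)
    with pytest.raises(DataError):
        evaluate(np.arange(2.0), np.arange(2.0), h2=0.4)


def test_random_predictor_has_null_accuracy(blup_instance):
    geno, ped, y, G, *_ = blup_instance
    traits_breed = np.array(["A", "B"])[np.arange(250) % 2]
    folds = make_folds(ped, traits_breed, k=5, seed=2)
    rng = np.random.default_rng(8)
    accs = []
    for f in range(1, 6):
        vi = folds.indices(f)
        m = evaluate(rng.standard_normal(len(vi)), y[vi], h2=0.5)
        accs.append(m["accuracy"])
    accs = np.array(accs)
    se = accs.std(ddof=1) / np.sqrt(len(accs))
    assert abs(accs.mean()) < 2 * se + 0.15


def test_bayescpi_pi0_gebv_converges_to_gblup(blup_instance):
    """Ridge regression on VanRaden-scaled dosages is GBLUP: with pi fixed
    at 0 and matched variances the two EBV vectors correlate > 0.99."""
    from bovigen import BayesCPi

    geno, _, y, G, ti, vi = blup_instance
    s2a_g, s2e = 0.5, 0.5
    gblup = gblup_predict(y[ti], G, ti, vi, s2a_g, s2e)
    p = geno.dosages.mean(axis=0) / 2.0
    sum2pq = float((2 * p * (1 - p)).sum())
    model = BayesCPi(y[ti], geno.subset_animals(ti), pi_mode="fixed",
                     pi_fixed=0.0, fix_sigma2_a=s2a_g / sum2pq,
                     fix_sigma2_e=s2e)
    post = model.fit(n_iter=4000, burn_in=800, seed=5)
    gebv = post.predict(geno.subset_animals(vi))
    assert np.corrcoef(gebv, gblup)[0, 1] > 0.99


def test_cross_validate_report_shape(blup_instance):
    geno, ped, y, G, *_ = blup_instance
    breeds = np.array(["A", "B"])[np.arange(250) % 2]
    folds = make_folds(ped, breeds, k=5, seed=4)
    rep = cross_validate(y, folds, h2=0.5, sigma2_a=0.5, sigma2_e=0.5,
                         grm=G, a_mat=a_matrix(ped), genotypes=geno,
                         methods=("pblup", "gblup", "bayescpi"),
                         chain=ChainConfig(n_iter=600, burn_in=150), seed=6)
    assert set(rep.per_fold["method"]) == {"pblup", "gblup", "bayescpi"}
    assert len(rep.per_fold) == 15
    agg = rep.aggregate()
    assert {"r_mean", "accuracy_mean", "slope_mean", "accuracy_se"} <= set(agg)
    gb = agg.set_index("method").loc["gblup"]
    assert np.isfinite(gb["accuracy_mean"])
    assert "cross-validation" in rep.summary()


def test_cross_validate_missing_inputs_rejected(blup_instance):
    geno, ped, y, G, *_ = blup_instance
    breeds = np.array(["A"] * 250)
    folds = make_folds(ped, breeds, k=5, seed=4)
    with pytest.raises(ConfigError):
        cross_validate(y, folds, 0.5, 0.5, 0.5, grm=None, methods=("gblup",))
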