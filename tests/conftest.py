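import numpy as np
import pytest

from bovigen import (MixedREML, SimConfig, grm_vanraden1, run_qc,
                     simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """One mid-sized cohort with a large QTL, shared across read-only tests."""
    cfg = SimConfig(n_animals=300, n_snps=400, n_chromosomes=5, n_sires=25,
                    h2=0.5, cg_var_fraction=0.1, n_large_qtl=1,
                    large_qtl_var_fraction=0.25, n_poly_qtl=80,
                    missing_rate=0.02, seed=42)
    geno, ped, traits, truth = simulate_cohort(cfg)
    return cfg, geno, ped, traits, truth


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    cfg, geno, ped, traits, truth = small_cohort
    clean, report = run_qc(geno, seed=7)
    return cfg, clean, ped, traits, truth, report


@pytest.fixture(scope="session")
def reml_fit(clean_cohort):
    cfg, geno, ped, traits, truth, _ = clean_cohort
    G = grm_vanraden1(geno)
    model = MixedREML.from_trait_table(traits, G, marbling=True)
    return model.fit(), G


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
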