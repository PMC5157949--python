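import numpy as np
import pytest

import ratesfs as r
from ratesfs.finite_sites import RateGrid


@pytest.fixture(scope="session")
def const_model():
    return r.preset_model("constant")


@pytest.fixture(scope="session")
def growth_model():
    return r.preset_model("modified_nelson_recent")


@pytest.fixture(scope="session")
def sim_grid(growth_model):
    """Small simulated finite-sites rate grid shared across the module tests
    (the acceptance suite builds its own full-scale grid)."""
    return r.estimate_grid(
        growth_model, 50,
        rates=r.default_rate_grid(10),
        min_biallelic=4000, seed=90210,
    )


def _toy_e_rare(x):
    """Smooth monotone-decreasing rare-fraction curve in log10 rate."""
    return 0.20 + 0.55 / (1.0 + np.exp((x + 6.0) / 0.6))


def _toy_p_biallelic(x):
    theta = 10.0 ** (x + 5.0)
    return 0.6 * theta / (1.0 + theta)


@pytest.fixture(scope="session")
def toy_grid():
    """Analytic stand-in grid with the qualitative shape of the simulated
    one (p rising and saturating, e_rare falling), wide enough in rate for
    large-sigma mixtures; noise-free so quadrature properties are exact."""
    rates = np.geomspace(1e-12, 1e-2, 201)
    x = np.log10(rates)
    return RateGrid(
        rates=rates,
        p_biallelic=_toy_p_biallelic(x),
        e_rare=_toy_e_rare(x),
        se_p=np.zeros_like(rates),
        se_e=np.zeros_like(rates),
        n_sites=np.full(rates.shape, 10**9),
        n_biallelic=np.full(rates.shape, 10**9),
        sample_size=0,
        model_name="synthetic-closed-form",
    )


@pytest.fixture(scope="session")
def synth_table():
    """Default desk-scale synthetic site table (no finite-sites grid)."""
    cfg = r.GeneratorConfig(seed=20240917)
    return r.generate_sites(cfg)


DESK_MEAN_RATES = {
    # Desk-scale rate map: at the small grid sample sizes used in tests the
    # recurrent-mutation regime starts at much higher per-site rates than in
    # a 100k-chromosome cohort, so the type means are scaled up to occupy the
    # same relative positions on the e_rare curve (CpG transitions well into
    # the recurrence zone, transversions near the infinite-sites limit).
    "CpG>TpG": 4e-5, "C>T": 2e-6, "A>G": 1.8e-6,
    "C>A": 5e-7, "C>G": 6e-7, "A>C": 4e-7, "A>T": 4e-7,
}

DESK_CPG_GRADIENT = {
    # steeper-than-default CpG gradient and balanced category sizes: at
    # desk-scale site counts the per-category binomial noise (~0.5pp) would
    # swamp the default gradient's sub-1pp rare-fraction spread
    "human_private": 0.05, "substituted_chimpanzee": 0.60,
    "substituted_gorilla": 0.45, "substituted_orangutan": 0.33,
    "substituted_gibbon": 0.20, "substituted_macaque": 0.10,
}

DESK_CATEGORY_PROPORTIONS = {
    "human_private": 0.40, "substituted_chimpanzee": 0.12,
    "substituted_gorilla": 0.12, "substituted_orangutan": 0.12,
    "substituted_gibbon": 0.12, "substituted_macaque": 0.12,
}


@pytest.fixture(scope="session")
def synth_table_grid(sim_grid):
    """Synthetic table whose rare/common draw is finite-sites aware, so the
    CpG-gradient composition translates into per-category SFS differences."""
    cfg = r.GeneratorConfig(seed=555, n_sites=60_000,
                            mean_rates=dict(DESK_MEAN_RATES),
                            cpg_fraction=dict(DESK_CPG_GRADIENT),
                            category_proportions=dict(DESK_CATEGORY_PROPORTIONS))
    return r.generate_sites(cfg, rate_grid=sim_grid), cfg
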