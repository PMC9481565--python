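import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from frailtygwas.genotype_io import GenotypeBlock
from frailtygwas.grm import GRMOperator
from frailtygwas.null_model import NullModelConfig, SurvivalPhenotype, fit_null
from frailtygwas.simulate import (
    SimConfig,
    draw_maf,
    simulate_cohort_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def unrelated_fit():
    """Cox-regime fixture: 400 unrelated samples, one covariate, tau = 0."""
    rng = np.random.default_rng(42)
    n = 400
    x = rng.standard_normal(n)
    eta = 0.5 * x
    lam = 1.0
    u = rng.uniform(size=n)
    t_fail = -np.log(u) / (lam * np.exp(eta))
    t_cens = rng.exponential(1.0, size=n)
    t = np.minimum(t_fail, t_cens)
    delta = (t_fail <= t_cens).astype(int)
    phen = SurvivalPhenotype([f"s{i}" for i in range(n)], t, delta, x[:, None])
    fit = fit_null(phen, None, NullModelConfig(fix_tau=0.0))
    return phen, fit


@pytest.fixture(scope="session")
def related_cohort():
    """Small related cohort (pedigrees + singletons, tau = 0.25) with a
    fitted null model, GRM operator and the GRM marker block."""
    cfg = SimConfig(
        n_families=40, n_singletons=200, m_grm=800, tau=0.25,
        target_censoring=0.5, seed=7,
    )
    rng = np.random.default_rng(cfg.seed)
    phen, _ = simulate_phenotypes(cfg, rng)
    mafs = draw_maf(rng, cfg.m_grm, *cfg.grm_maf_range)
    calls = simulate_cohort_genotypes(cfg, mafs, rng)
    block = GenotypeBlock.from_matrix(calls)
    grm = GRMOperator(block)
    fit = fit_null(phen, grm, NullModelConfig(seed=cfg.seed))
    return cfg, phen, fit, grm, block
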