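import numpy as np
import pytest

import recburden as rb
from recburden.synthetic_cohort import (
    simulate_disease_status,
    simulate_pedigree_genotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed trio/quartet/singleton cohort with default noise, seed-fixed."""
    cfg = rb.SimCohortConfig(n_trios=150, n_quartets=10, n_singletons=150, seed=42)
    return rb.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_trios():
    """500 complete trios without observation noise plus their truth table."""
    cfg = rb.SimCohortConfig(
        n_trios=500, n_quartets=0, n_singletons=0, seed=7,
        qc_noise=rb.QcNoise(p_het_to_hom=0.0, p_lowdepth=0.0),
    )
    rng = np.random.default_rng(cfg.seed)
    pedigree, matrix, truth = simulate_pedigree_genotypes(cfg, rng)
    return cfg, pedigree, matrix, truth


@pytest.fixture(scope="session")
def called_clean_trios(clean_trios):
    cfg, pedigree, matrix, truth = clean_trios
    mask = rb.build_class_mask(matrix, pedigree=pedigree)
    qualifying = rb.select_burden_variants(mask, matrix, class_set="plof_plus_pdns")
    calls, cascade, phase_log = rb.call_diplotypes(
        "NOD2", qualifying, matrix, pedigree=pedigree
    )
    return cfg, pedigree, matrix, truth, calls, cascade, phase_log
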