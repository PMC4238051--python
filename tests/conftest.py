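import numpy as np
import pytest

import primegem as pg


@pytest.fixture(scope="session")
def chain():
    return pg.make_toy_model("chain")


@pytest.fixture(scope="session")
def parallel():
    return pg.make_toy_model("parallel")


@pytest.fixture(scope="session")
def branched_atp():
    return pg.make_toy_model("branched-atp")


@pytest.fixture(scope="session")
def split_chain(chain):
    return pg.split_reversible(chain)


@pytest.fixture(scope="session")
def split_parallel(parallel):
    return pg.split_reversible(parallel)


@pytest.fixture(scope="session")
def tight_chain(split_chain):
    model, u = pg.tighten_global_bounds(split_chain)
    return model


@pytest.fixture(scope="session")
def cohort_model():
    return pg.make_cohort_model(19)


@pytest.fixture(scope="session")
def cohort(cohort_model):
    """Noise-free seeded cohort: 40 samples, 1 true + 19 decoy genes."""
    expr, pheno, truth = pg.make_cohort(cohort_model, pg.CohortSpec(seed=0))
    return expr, pheno, truth


@pytest.fixture(scope="session")
def cohort_mset(cohort_model, cohort):
    expr, pheno, _ = cohort
    return pg.build_models(cohort_model, expr, pheno)
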