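import warnings

import pytest

from gfrtraj import (
    apply_inclusion_filters,
    build_design,
    fit_lmm,
    generate_cohort,
    well_specified_config,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Well-specified three-country simulation, ~240 subjects."""
    config = well_specified_config(n_per_country=80, seed=11)
    baselines, visits, truth = generate_cohort(config)
    baselines, visits, _ = apply_inclusion_filters(baselines, visits)
    truth = truth[truth["subject_id"].isin(baselines["subject_id"])]
    return baselines, visits, truth, config


@pytest.fixture(scope="session")
def small_design(small_cohort):
    baselines, visits, _, _ = small_cohort
    return build_design(baselines, visits)


@pytest.fixture(scope="session")
def small_model(small_design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_lmm(small_design)
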