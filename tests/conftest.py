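import pytest

import gaitpath as gp


def small_counts(per_class: int = 12, typical: int = 20) -> dict:
    counts = {c: per_class for c in gp.PATHOLOGICAL_CONDITIONS}
    counts[gp.TYPICAL] = typical
    return counts


@pytest.fixture()
def tiny_cohort() -> gp.GaitCohort:
    """Six-per-class cohort with missing values; fast unit-test input."""
    cfg = gp.CohortConfig(class_counts=small_counts(6, 10), seed=11)
    cohort = gp.generate_cohort(cfg)
    return gp.inject_missingness(cohort, 0.02, seed=12)


@pytest.fixture(scope="session")
def small_cohort() -> gp.GaitCohort:
    cfg = gp.CohortConfig(class_counts=small_counts(), seed=21)
    cohort = gp.generate_cohort(cfg)
    return gp.inject_missingness(cohort, 0.02, seed=22)


def light_config(**overrides) -> gp.RunConfig:
    """Pipeline config with light search budgets for integration tests."""
    defaults = dict(tuning_budget=3, voting_budget=20, selection_trees=100,
                    rfe_step=10)
    defaults.update(overrides)
    return gp.RunConfig(**defaults)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    """One fitted pipeline on the small cohort, shared across tests."""
    return gp.GaitConditionModel(small_cohort, light_config()).fit()


@pytest.fixture(scope="session")
def default_results():
    """Full pipeline fitted on the default 348-subject cohort."""
    cohort = gp.generate_default_cohort(seed=0)
    return gp.GaitConditionModel(cohort, gp.RunConfig()).fit()
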