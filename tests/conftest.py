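import pytest

from immunosig.config import CohortConfig, SubsetSpec, default_sigma, default_study_config
from immunosig.signature import fit_signature_model, score_cohort
from immunosig.simulate import simulate_percentages


def make_small_config(
    seed: int = 0,
    n_sle: int = 6,
    n_hc: int = 6,
    n_subsets: int = 12,
    effect: float = 0.0,
    n_affected: int = 0,
    outlier_rate: float = 0.0,
) -> CohortConfig:
    """A compact cohort for fast tests; first ``n_affected`` subsets shifted."""
    panel = [
        SubsetSpec(
            name=f"subset{i:02d}",
            mu=5.0 + 3.0 * i,
            sigma=default_sigma(5.0 + 3.0 * i),
            delta=effect if i < n_affected else 0.0,
        )
        for i in range(n_subsets)
    ]
    return CohortConfig(
        n_sle=n_sle, n_hc=n_hc, panel=panel, seed=seed, outlier_rate=outlier_rate
    )


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return simulate_percentages(study_config)


@pytest.fixture(scope="session")
def study_model(study_cohort):
    model, warnings = fit_signature_model(study_cohort)
    return model


@pytest.fixture(scope="session")
def study_scores(study_cohort, study_model):
    return score_cohort(study_cohort, study_model)
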