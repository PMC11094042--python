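import hypothesis
import pytest

from missbench.simulate import CohortConfig, generate_cohort

hypothesis.settings.register_profile(
    "suite", deadline=None, max_examples=50, derandomize=True
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort shared across integration tests."""
    config = CohortConfig(n_proteins=8, length_min=120, length_max=250)
    return generate_cohort(config, seed=11)


@pytest.fixture(scope="session")
def separated_cohort():
    """Perfect concordance, well-separated scores: every metric should be 1."""
    config = CohortConfig(
        n_proteins=6,
        length_min=100,
        length_max=200,
        score_model="gaussian",
        benign_mu=0.05,
        pathogenic_mu=0.95,
        benign_sigma=0.02,
        pathogenic_sigma=0.02,
        concordance=1.0,
    )
    return generate_cohort(config, seed=23)
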