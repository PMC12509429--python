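import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def encode_with_outcome(dataset):
    """Model-ready numeric table: encoded predictors + the gap outcome."""
    from gapdml import measurement
    from gapdml.instruments import DEFAULT_SCHEMA, OUTCOME_COLUMN

    enc = measurement.encode_features(
        dataset.survey.drop(columns=[OUTCOME_COLUMN]), DEFAULT_SCHEMA)
    data = enc.model_matrix()
    data[OUTCOME_COLUMN] = dataset.survey[OUTCOME_COLUMN].to_numpy()
    return data


@pytest.fixture(scope="session")
def default_survey():
    """Default (non-linear) synthetic survey at a realistic sample size."""
    from gapdml import synthetic

    return synthetic.generate_survey(1200, seed=7)


@pytest.fixture(scope="session")
def linear_survey():
    """Purely linear structural design with known per-SD effects."""
    from gapdml import synthetic

    cfg = synthetic.SurveyConfig(structural=synthetic.linear_structural_spec())
    return synthetic.generate_survey(2000, seed=11, config=cfg)


@pytest.fixture(scope="session")
def encoded_linear(linear_survey):
    return encode_with_outcome(linear_survey)
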