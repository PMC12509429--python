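"""Shared helpers for the analysis drivers."""

from gapdml import measurement
from gapdml.instruments import DEFAULT_SCHEMA, OUTCOME_COLUMN


def encode_with_outcome(dataset):
    """Model-ready numeric table: encoded predictors + the gap outcome."""
    enc = measurement.encode_features(
        dataset.survey.drop(columns=[OUTCOME_COLUMN]), DEFAULT_SCHEMA)
    data = enc.model_matrix()
    data[OUTCOME_COLUMN] = dataset.survey[OUTCOME_COLUMN].to_numpy()
    return data
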