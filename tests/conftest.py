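import numpy as np
import pytest

from emrfuse.config import model_profile
from emrfuse.data_model import (CategoricalFeature, ContinuousFeature,
                                DatasetSchema, PatientRecord,
                                TemporalObservation)
from emrfuse.preprocessing import Preprocessor
from emrfuse.synthetic_ehr import SimConfig, default_schema, generate_cohort
from emrfuse.train_eval import tensorize


@pytest.fixture(scope="session")
def tiny_schema() -> DatasetSchema:
    """Two temporal features, one continuous + one categorical static feature."""
    return DatasetSchema(
        static_continuous=[ContinuousFeature("temperature", 36.0, 37.2)],
        static_categorical=[CategoricalFeature("sex", ["male", "female"])],
        temporal_features=["hr", "lactate"],
        note_vocab_size=50,
        horizon_days=30,
        window_days=3,
    )


def make_record(record_id="r1", los=10, obs=(), notes=(), static=None,
                mortality=0) -> PatientRecord:
    return PatientRecord(
        record_id=record_id,
        static_tabular=static or {"temperature": 36.5, "sex": "female"},
        static_notes=[("complaint", ["chest", "pain"])],
        temporal_tabular=[TemporalObservation(*o) for o in obs],
        temporal_notes=[(d, list(t)) for d, t in notes],
        length_of_stay=los,
        label_mortality=mortality,
        label_long_stay=int(los > 14),
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(n_patients=120, seed=11)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def cohort_schema(sim_config):
    return default_schema(sim_config)


@pytest.fixture(scope="session")
def fitted_preprocessor(cohort, cohort_schema):
    return Preprocessor(cohort_schema).fit(cohort)


@pytest.fixture(scope="session")
def windowed_cohort(fitted_preprocessor, cohort):
    return fitted_preprocessor.transform_all(cohort)


@pytest.fixture(scope="session")
def cohort_tensors(windowed_cohort, fitted_preprocessor):
    cfg = model_profile("desk")
    return tensorize(windowed_cohort, fitted_preprocessor.vocab, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
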