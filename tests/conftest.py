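import numpy as np
import pytest

from dietexpo import data_io, posterior_sampler, synthetic_data
from dietexpo.data_io import (
    BodyWeightRecord,
    Censor,
    DiaryEntry,
    OccurrenceRecord,
    PrevalenceSample,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_records():
    return [
        OccurrenceRecord("h", "f", Censor.EXACT, lod=0.5, loq=1.0, value=5.0),
        OccurrenceRecord("h", "f", Censor.INTERVAL, lod=0.5, loq=1.0),
        OccurrenceRecord("h", "f", Censor.BELOW_LOD, lod=0.5, loq=1.0),
    ]


@pytest.fixture
def simple_diary():
    diaries = [
        DiaryEntry("a", 1, (10.0, 0.0)),
        DiaryEntry("a", 2, (12.0, 5.0)),
        DiaryEntry("b", 1, (0.0, 0.0)),
        DiaryEntry("b", 2, (8.0, 3.0)),
    ]
    weights = [BodyWeightRecord("a", 70.0), BodyWeightRecord("b", 80.0)]
    return diaries, weights


@pytest.fixture(scope="session")
def chemical_fit():
    """A fitted chemical-like preset shared by read-only tests."""
    truth = synthetic_data.default_truth("chemical-like", seed=7)
    bundle = synthetic_data.make_bundle(truth)
    spec = data_io.build_model_spec(
        bundle.occ_records, bundle.prev_samples, bundle.diaries,
        occurrence_option=truth.occurrence_option,
        frequency_option=truth.frequency_option,
        hazard_types=truth.hazard_types, foods=truth.foods,
        chains=2, iterations=400, burnin=300, seed=7,
    )
    draws = posterior_sampler.sample_posterior(spec, bundle)
    return truth, bundle, spec, draws


@pytest.fixture(scope="session")
def micro_fit():
    """A fitted micro-like (zero-inflated, Markov) preset."""
    truth = synthetic_data.default_truth("micro-like", seed=11)
    bundle = synthetic_data.make_bundle(truth)
    spec = data_io.build_model_spec(
        bundle.occ_records, bundle.prev_samples, bundle.diaries,
        occurrence_option=truth.occurrence_option,
        frequency_option=truth.frequency_option,
        hazard_types=truth.hazard_types, foods=truth.foods,
        chains=2, iterations=400, burnin=300, seed=11,
    )
    draws = posterior_sampler.sample_posterior(spec, bundle)
    return truth, bundle, spec, draws
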