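import numpy as np
import pytest

from ecgluco import features
from ecgluco.pipeline import RunConfig, recordings_to_features
from ecgluco.preprocess import preprocess
from ecgluco.synthetic import RecordingConfig, generate_recording, make_dataset


def clean_config(**overrides) -> RecordingConfig:
    """A noiseless, jitter-free recording configuration."""
    params = dict(
        duration=40.0,
        mean_hr=60.0,
        hr_jitter_sd=0.0,
        baseline_wander_amp=0.0,
        white_noise_sd=0.0,
        beat_center_jitter_sd=0.0,
        beat_amplitude_jitter=0.0,
        seed=11,
    )
    params.update(overrides)
    return RecordingConfig(**params)


@pytest.fixture(scope="session")
def clean_recording():
    """40 s noiseless HR-60 recording with ground truth."""
    return generate_recording(clean_config())


@pytest.fixture(scope="session")
def filtered_recording(clean_recording):
    return preprocess(clean_recording, trim_seconds=5.0)


def build_matrix(n_subjects, seed, qt_effect=1.08, pr_effect=1.05):
    """Cohort -> outlier-removed beat-level feature matrix."""
    cfg = RunConfig(n_subjects=n_subjects, seed=seed)
    recs = make_dataset(
        n_subjects,
        qt_effect=qt_effect,
        pr_effect=pr_effect,
        seed=seed,
        config=RecordingConfig(seed=seed),
    )
    mat, counts = recordings_to_features(recs, cfg)
    bounds = features.fit_outlier_bounds(mat)
    kept, _ = features.remove_outliers(mat, bounds)
    return kept, counts


@pytest.fixture(scope="session")
def effect_matrix():
    """Default class effect (QT x1.08, PR x1.05), 200 subjects."""
    kept, _ = build_matrix(200, seed=0)
    return kept


@pytest.fixture(scope="session")
def null_matrix():
    """Zero class effect, 100 subjects."""
    kept, _ = build_matrix(100, seed=0, qt_effect=1.0, pr_effect=1.0)
    return kept


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
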