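import numpy as np
import pytest

from filmphysio import CohortConfig, FilmSpec, generate_cohort
from filmphysio.features import extract_cohort_features

SHORT_FILMS = (
    FilmSpec("f1", 35.0, "comedy"),
    FilmSpec("f2", 40.0, "comedy"),
    FilmSpec("f3", 32.0, "drama"),
    FilmSpec("f4", 38.0, "drama"),
)


def small_config(**overrides) -> CohortConfig:
    """Reduced-scale cohort used throughout the suite: 4 short films, 15-s
    rest baselines, full stream set unless narrowed by the caller."""
    kw = dict(n_subjects=4, films=SHORT_FILMS, rest_duration=15.0, seed=11)
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    trials, truth = generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, trials, _ = small_cohort
    return extract_cohort_features(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
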