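import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

import shellfingerprint as sf
from shellfingerprint.pipeline import preprocess, validate_config


@pytest.fixture(scope="session")
def fixture_tables():
    """The packaged deterministic dataset: brood and settler ablation tables."""
    return sf.generate_paper_like_fixture()


@pytest.fixture(scope="session")
def study_config():
    return validate_config({
        "bootstrap": {"seed": 11},
        "ordination": {"seed": 11},
        "assignment": {"seed": 11},
        "clustering": {"seed": 11},
    })


@pytest.fixture(scope="session")
def preprocessed(fixture_tables, study_config):
    """(sig_log, sig_z, params, info) for the fixture broods."""
    broods, _ = fixture_tables
    return preprocess(broods, study_config)


@pytest.fixture(scope="session")
def subset_search(preprocessed):
    """Exhaustive 511-subset search on the fixture (shared: it is the
    expensive step several tests build on)."""
    _, sig_z, _, _ = preprocessed
    return sf.exhaustive_subset_search(sig_z, "region")


@pytest.fixture(scope="session")
def region_model(preprocessed, subset_search):
    _, sig_z, params, _ = preprocessed
    return sf.fit_lda(sig_z.select_elements(subset_search.winner), "region",
                      transform_params=params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_region_specs(p=3, delta=2.0, n=(20, 20), noise=0.0):
    """Small two-region design used across tests."""
    panel = [f"E{i}" for i in range(p)]
    cov = np.eye(p) * 0.25
    mu = np.log(np.full(p, 100.0))
    shift = np.zeros(p)
    shift[0] = delta * 0.5
    return [
        sf.RegionSpec("A", mu - shift, cov, n[0], ablations_per_brood=3,
                      ablation_noise_sd=noise, elements=panel),
        sf.RegionSpec("B", mu + shift, cov, n[1], ablations_per_brood=3,
                      ablation_noise_sd=noise, elements=panel),
    ]
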