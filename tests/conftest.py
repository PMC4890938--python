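import pytest
from hypothesis import HealthCheck, settings

import anonprev as ap

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated two-hut campaign (430 samples, default panel)."""
    config = ap.mont_blanc_study_config(seed=42)
    dataset, truth = ap.simulate_study(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def study_statuses(study_dataset):
    config, dataset, _ = study_dataset
    substance_status, sample_status = ap.classify_dataset(dataset, config.panel)
    return substance_status, sample_status
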