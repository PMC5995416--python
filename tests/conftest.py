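import numpy as np
import pytest

from advafm import pipeline, synthetic
from advafm.config import PipelineConfig
from advafm.synthetic import CohortConfig, FibrilFieldSpec


@pytest.fixture(scope="session")
def rendered_image():
    """A noiseless default fibril field with its ground truth."""
    spec = FibrilFieldSpec(orientation_jitter_deg=2.0)
    return synthetic.render_fibril_image(spec, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced study configuration that keeps tests fast."""
    return PipelineConfig(
        seed=11,
        cohort=CohortConfig(
            n_low=3,
            n_high=3,
            images_per_patient=2,
            measurements_per_image=10,
            missing_rate=0.0,
        ),
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """A simulated small study directory shared across tests."""
    out = tmp_path_factory.mktemp("study")
    pipeline.simulate_study(small_config, out, force=True)
    return out


@pytest.fixture(scope="session")
def small_results(small_config, small_study, tmp_path_factory):
    """Full analysis results over the small study."""
    out = tmp_path_factory.mktemp("results")
    pipeline.run_study(small_study, out, small_config)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
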