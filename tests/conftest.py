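import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gcfusion import fusionnet, pipeline, synthdata

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_recordings():
    """8 channels, 12 trials of 10 s, planted 0->1 coupling, beta class effect."""
    spec = synthdata.small_test_spec(
        n_trials=12,
        coupling_edges=[(0, 1, 1, 0.6)],
        band_effects={1: ("beta", (0, 1, 2, 3), 2.0)},
        seed=7,
    )
    recordings, truth = synthdata.simulate_recordings(spec)
    return recordings, truth, spec


@pytest.fixture(scope="session")
def small_dataset(small_recordings):
    """Graph dataset built from the small synthetic study (60 segments)."""
    recordings, _, _ = small_recordings
    return pipeline.build_graph_dataset(recordings, pipeline.PipelineConfig(k=0.5))


@pytest.fixture(scope="session")
def fitted_small_model(small_dataset):
    model = fusionnet.FusionGCN(small_dataset, fusionnet.ModelConfig(epochs=20, seed=0))
    return model, model.fit()


def ar1_pair(rng, n=500, phi=0.5, coupling=0.0, lag=1):
    """Two AR(1) series, optionally with a directed x->y coupling."""
    x = np.zeros(n)
    y = np.zeros(n)
    ex, ey = rng.normal(size=(2, n))
    for t in range(max(1, lag), n):
        x[t] = phi * x[t - 1] + ex[t]
        y[t] = phi * y[t - 1] + coupling * x[t - lag] + ey[t]
    return x, y
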