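import numpy as np
import pytest

from gdi import ClassifierSpec, EstimatorConfig, GraphConfig, TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_classifier():
    """Small, fast classifier for unit tests (not for accuracy checks)."""
    return ClassifierSpec(hidden_layers=(16,), max_epochs=12, patience=3)


@pytest.fixture
def quick_estimator(quick_classifier):
    return EstimatorConfig(bootstrap_iters=2, seed=0, classifier=quick_classifier,
                           n_q_eval=2)


@pytest.fixture
def quick_graph_cfg(quick_estimator):
    return GraphConfig(M=1, estimator=quick_estimator)


@pytest.fixture
def white_noise_series(rng):
    return TimeSeriesSet(rng.normal(size=(600, 3)), channel_names=["a", "b", "c"])
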