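import numpy as np
import pytest

from eegcvae.cvae import CVAEConfig, train
from eegcvae.features import FeatureConfig
from eegcvae.pipeline import preprocess_recordings
from eegcvae.synthetic import SyntheticSpec, gen_two_class_recordings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feature_cfg():
    return FeatureConfig()


def make_separated_features(n=2000, d=88, scale=1.5, seed=42, symmetric=True):
    """Two Gaussian classes separated by a fixed +-scale shift pattern."""
    gen = np.random.default_rng(seed)
    shift = np.where(gen.random(d) < 0.5, scale, -scale)
    y = np.repeat([0, 1], n // 2)
    offset = (y - 0.5) if symmetric else y
    x = gen.standard_normal((n, d)) + np.outer(offset, shift)
    order = gen.permutation(n)
    return x[order], y[order], shift


@pytest.fixture(scope="session")
def separated_features():
    return make_separated_features()


@pytest.fixture(scope="session")
def trained_separated_model(separated_features):
    x, y, shift = separated_features
    model, traces = train(x[:1600], y[:1600], CVAEConfig(seed=7),
                          x_val=x[1600:], y_val=y[1600:])
    return model, traces, shift


@pytest.fixture(scope="session")
def small_cohort_windows():
    """QC'd windows from a compact two-class synthetic cohort."""
    spec = SyntheticSpec(n_subjects_per_class=2, n_runs=1, run_length=60.0,
                         artifact_rate=0.05, seed=11)
    recs = gen_two_class_recordings(spec)
    windows, counts = preprocess_recordings(recs)
    return windows, counts
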