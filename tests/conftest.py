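import numpy as np
import pytest

from eiic.benchmarks import (
    benchmark_train_config,
    scaled_network_spec,
    signal_benchmark_spec,
    simulate_features,
)
from eiic.features import FeatureVector


def make_separable_features(
    n: int = 60, dim: int = 10, n_sites: int = 2, gap: float = 2.0, seed: int = 0
) -> list[FeatureVector]:
    """Two Gaussian blobs separated along half the feature axes."""
    rng = np.random.default_rng(seed)
    feats = []
    for k in range(n):
        label = k % 2
        mean = np.zeros(dim)
        mean[: dim // 2] = gap * (1 if label == 1 else -1) / 2
        feats.append(
            FeatureVector(
                subject_id=f"S{k:03d}",
                site_id=f"SITE_{k % n_sites}",
                label=label,
                values=rng.normal(mean, 1.0),
            )
        )
    return feats


@pytest.fixture
def separable_features():
    return make_separable_features()


@pytest.fixture(scope="session")
def signal_features():
    """The 4-site, 200-subject, 20-ROI benchmark with a clean class effect."""
    return simulate_features(signal_benchmark_spec(seed=7))


@pytest.fixture(scope="session")
def two_site_signal_features():
    """A compact two-site slice of the clean-signal design (100 subjects)."""
    from eiic.simulate import SimSpec, SiteSpec

    sites = [
        SiteSpec(site_id=s, n_subjects=50, t_points=150, noise_scale=0.3, ar_coeff=0.3)
        for s in ("A", "B")
    ]
    return simulate_features(
        SimSpec(n_rois=20, sites=sites, effect_edges=0.2, effect_size=0.6, seed=1)
    )


@pytest.fixture(scope="session")
def benchmark_net_spec(signal_features):
    return scaled_network_spec(signal_features[0].values.shape[0])


@pytest.fixture
def quick_train_config():
    """Few-epoch settings for structural (non-convergence) assertions."""
    return benchmark_train_config(seed=0, max_epochs=3, patience=2)
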