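import numpy as np
import pandas as pd
import pytest

from gliomanet import (SynthClusterSpec, SynthGGMSpec, make_cluster_dataset,
                       make_joint_ggm, sample_ggm_classes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_matrix(rng):
    """600 x 50 standard-Gaussian expression matrix."""
    x = rng.standard_normal((600, 50))
    return pd.DataFrame(x, index=[f"s{i}" for i in range(600)],
                        columns=[f"g{j:03d}" for j in range(50)])


@pytest.fixture
def two_cluster_data():
    """Well-separated 2-cluster data with ground truth, no outliers."""
    spec = SynthClusterSpec(n_per_cluster=(50, 50), p=50, q=5, shift=6.0,
                            outlier_fraction=0.0, seed=11)
    return make_cluster_dataset(spec)


@pytest.fixture
def small_joint_ggm():
    spec = SynthGGMSpec(p=6, D=2, n_shared=2, n_exclusive=1, seed=7)
    return make_joint_ggm(spec)
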