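import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_simplex(rng, shape, k):
    """Random probability vectors with classes on the last axis."""
    v = rng.gamma(1.0, 1.0, size=(*shape, k))
    return v / v.sum(axis=-1, keepdims=True)


def random_distribution_matrix(rng, k, role):
    from codalign import ClassDistributionMatrix

    return ClassDistributionMatrix(random_simplex(rng, (k,), k), role)


@pytest.fixture
def tiny_bundle():
    """Small, cheap synthetic dataset reused across engine tests."""
    from codalign import SyntheticDatasetSpec, generate

    return generate(
        SyntheticDatasetSpec(num_images=16, image_size=(16, 16), labeled_fraction=0.25, seed=3)
    )


def bundle_to_xy(bundle):
    import numpy as np

    xl, yl = bundle.labeled_arrays()
    xu = bundle.unlabeled_images()
    X = np.concatenate([xl, xu])
    y = np.concatenate([yl.astype(np.int64), np.full(xu.shape, -1, dtype=np.int64)])
    return X, y
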