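import numpy as np
import pytest

from phytochunk import ClassScheme, LabeledPointCloud, PlantParams, generate_plant


@pytest.fixture(scope="session")
def scheme() -> ClassScheme:
    return ClassScheme()


@pytest.fixture(scope="session")
def small_plant() -> LabeledPointCloud:
    """A 5,000-point synthetic plant with the default imbalance profile."""
    return generate_plant(PlantParams(n_points=5_000, seed=42))


@pytest.fixture(scope="session")
def medium_plant() -> LabeledPointCloud:
    """A 20,000-point plant for tests that need minority classes well populated."""
    return generate_plant(PlantParams(n_points=20_000, seed=7))


@pytest.fixture()
def random_cloud(scheme) -> LabeledPointCloud:
    """A structureless random cloud with random labels (for geometry-only tests)."""
    rng = np.random.default_rng(123)
    n = 1_000
    return LabeledPointCloud(
        positions=rng.uniform(-100, 100, (n, 3)),
        colours=rng.integers(0, 256, (n, 3)),
        labels=rng.integers(0, scheme.n_classes, n),
        cloud_id="random",
        scheme=scheme,
    )
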