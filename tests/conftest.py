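import numpy as np
import pytest

from slidemil.bags import Bag
from slidemil.models import VARIANTS, build_model
from slidemil.synthetic import BagGenConfig, SlideGenConfig, gen_bags, gen_slide


@pytest.fixture(scope="session")
def random_bags() -> list[Bag]:
    """100 random unlabeled-structure bags for algebraic property checks."""
    rng = np.random.default_rng(42)
    bags = []
    for _ in range(100):
        n = int(rng.integers(1, 30))
        d = int(rng.integers(2, 16))
        bags.append(
            Bag(instances=rng.normal(size=(n, d)).astype(np.float32),
                label=int(rng.integers(0, 2)))
        )
    return bags


@pytest.fixture(scope="session")
def small_fixture_bags() -> list[Bag]:
    """A small separable bag set for fast training tests."""
    return gen_bags(BagGenConfig(n_bags=40, seed=11))


@pytest.fixture(scope="session")
def tiny_slide():
    """A small 3-level pyramid treated as 5x at its base, with ground truth."""
    cfg = SlideGenConfig(
        base_size=1024, n_levels=3, n_blobs=3,
        blob_radius_range=(0.18, 0.3), n_artifacts=1,
    )
    return gen_slide(cfg, seed=5)


def make_model(variant: str, d: int = 8, seed: int = 0, D: int = 16):
    return build_model(variant, d=d, seed=seed, D=D)


@pytest.fixture(params=VARIANTS)
def variant(request) -> str:
    return request.param
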