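import numpy as np
import pytest

from plumcma.cli import make_smoke_batch
from plumcma.data import ClassDistribution, Manifest
from plumcma.synthetic import generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """3 images per class at 64 px, written once per session."""
    root = tmp_path_factory.mktemp("corpus")
    manifest = generate_corpus({c: 3 for c in range(5)}, root, image_size=64, seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def smoke_batch():
    return make_smoke_batch(8, 64, seed=3)


@pytest.fixture()
def toy_manifest():
    return Manifest([(f"img_{c}_{i}.png", c, "unassigned") for c in range(5) for i in range(3)])


@pytest.fixture()
def paper_distribution():
    """The published initial per-class image counts."""
    return ClassDistribution({0: 1767, 1: 788, 2: 709, 3: 1524, 4: 1127})


def synthetic_manifest(counts: dict[int, int]) -> Manifest:
    return Manifest([
        (f"images/c{c}_{i:05d}.png", c, "unassigned")
        for c in sorted(counts) for i in range(counts[c])
    ])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
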