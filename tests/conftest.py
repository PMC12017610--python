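import numpy as np
import pytest

from moodspeech.langfeatures import EmbeddingTable
from moodspeech.synthdata import make_demo_dataset

TOY_WORDS = ["river", "storm", "bridge", "car", "doctor", "home"]


@pytest.fixture(scope="session")
def toy_embedding() -> EmbeddingTable:
    """Six-word embedding with fixed seeded 3-D vectors."""
    rng = np.random.default_rng(42)
    return EmbeddingTable({w: rng.standard_normal(3) for w in TOY_WORDS})


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """A six-participant synthetic study on disk (manifest path)."""
    out = tmp_path_factory.mktemp("demo_study")
    return make_demo_dataset(out, n=6, seed=11)
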