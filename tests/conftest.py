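import numpy as np
import pytest

from embedrepeat.embeddings import (ResidueEmbedding, SyntheticRepeatSpec,
                                    generate_background, generate_synthetic)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted():
    """A clean 4-copy planted repeat: 100 x 64, units of 20, flanks of 10."""
    spec = SyntheticRepeatSpec(unit_length=20, n_copies=4, flank_left=10,
                               flank_right=10, within_unit_cosine=0.9, seed=7,
                               sequence_id="planted")
    return generate_synthetic(spec)


@pytest.fixture
def background():
    return generate_background(120, 64, seed=99, sequence_id="bg")


def random_embedding(rng, length, dim=8, sequence_id="rnd") -> ResidueEmbedding:
    rows = rng.standard_normal((length, dim))
    return ResidueEmbedding(rows, sequence_id)
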