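import numpy as np
import pytest

from pausekit import Genome, PauseSite, generate_genome


@pytest.fixture
def toy_genome() -> Genome:
    # 50 A's: any window folds to nothing
    return Genome({"chr": "A" * 50}, id="toy")


@pytest.fixture
def random_genome() -> Genome:
    return generate_genome(20000, gc_fraction=0.5, seed=11, genome_id="rnd")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_site(position: int, strand: str = "+", seq: str = "chr", sid: str = "s") -> PauseSite:
    return PauseSite(seq, position, strand, sid)
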