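import numpy as np
import pytest
from hypothesis import settings

from npskit.io_formats import SequenceSet
from npskit.simulate import PlantedSignalSpec, generate_patterned_sequences

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def random_seqset(rng) -> SequenceSet:
    """50 i.i.d. uniform random 160 bp sequences."""
    letters = np.array(list("ACGT"))
    seqs = ["".join(letters[rng.integers(0, 4, 160)]) for _ in range(50)]
    return SequenceSet(tuple(f"s{i}" for i in range(50)), tuple(seqs))


@pytest.fixture(scope="session")
def planted_ww_seqset() -> SequenceSet:
    """2000 sequences with a planted WW sinusoid (period 10.2, amplitude 0.2)."""
    spec = PlantedSignalSpec(
        n_sequences=2000,
        width=146,
        period=10.2,
        amplitude=0.2,
        signal_class="WW",
        dyad_offset=0,
        seed=777,
    )
    return generate_patterned_sequences(spec)
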