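import numpy as np
import pytest

from fourcat import (
    FragmentCounts,
    GenomicInterval,
    LocusModel,
    Viewpoint,
    uniform_fragment_map,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def model() -> LocusModel:
    return LocusModel()


@pytest.fixture
def small_map():
    """A 100 kb locus with 100 uniform 1 kb fragments."""
    return uniform_fragment_map(GenomicInterval("chrT", 0, 100_000), 100)


@pytest.fixture
def small_counts(small_map, rng):
    """Random counts on the small map, viewpoint at 50 kb, 2 kb exclusion."""
    vp = Viewpoint.at(small_map, 50_000, exclusion_flank=2_000)
    counts = rng.integers(0, 100, size=len(small_map))
    return FragmentCounts(small_map, vp, "rand", counts)
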