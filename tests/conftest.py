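import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from refscaff import simulate as sim
from refscaff.genome import Genome
from refscaff.reads import LibrarySpec


@pytest.fixture(scope="session")
def small_reference() -> Genome:
    """40 kb two-scaffold reference with a Z-classed scaffold."""
    return sim.generate_reference(2, [25_000, 15_000], 0.45, seed=11,
                                  names=["chr1", "chrZ"],
                                  chrom_classes=["macro", "Z"])


@pytest.fixture(scope="session")
def evolved(small_reference):
    """Focal genome at 2% divergence with truth (includes indels)."""
    focal, truth = sim.evolve_genome(small_reference, 0.02, 2e-4,
                                     z_multiplier=1.5, seed=13)
    return focal, truth


@pytest.fixture(scope="session")
def diploid(evolved):
    focal, _ = evolved
    haps, het_truth = sim.make_diploid(focal, 0.001, seed=17)
    return haps, het_truth


@pytest.fixture(scope="session")
def se_library() -> LibrarySpec:
    return LibrarySpec(kind="single_end", read_length=75, coverage=20,
                       error_rate=0.001, name="se75")


@pytest.fixture(scope="session")
def mp_library() -> LibrarySpec:
    return LibrarySpec(kind="mate_pair", read_length=60, coverage=20,
                       insert_mean=2000, insert_sd=200,
                       error_rate=0.001, name="mp2k")


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
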