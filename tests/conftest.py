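import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bathyvir.records import Contig, GeneCall, GeneCategory
from bathyvir.synthetic import make_viral_genome


@pytest.fixture(scope="session")
def genome_20k() -> Contig:
    """A 20-kb, 45%-GC circular genome reused across tests."""
    return make_viral_genome(20_000, 0.45, seed=11, contig_id="g20k")


@pytest.fixture(scope="session")
def phage_with_integrase():
    """A 12-kb phage genome plus its integrase gene call."""
    phage = make_viral_genome(12_000, 0.45, seed=12, contig_id="phageA")
    calls = [GeneCall("phageA", 2_000, 2_900, "+", GeneCategory.INTEGRASE)]
    return phage, calls


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_aa(rng: np.random.Generator, n: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, n))
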