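from pathlib import Path

import pytest

from dlakit.allele_typing import AlleleLibrary, GenotypeCall

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def tiny_library() -> AlleleLibrary:
    """Two alleles at one 4-bp locus, differing at position 1."""
    lib = AlleleLibrary()
    lib.add("L", "X", "ACGT")
    lib.add("L", "Y", "AGGT")
    return lib


def make_call(dog: str, locus: str, a1: str, a2: str) -> GenotypeCall:
    """Definite genotype call shorthand used across test modules."""
    status = "homozygous" if a1 == a2 else "heterozygous"
    return GenotypeCall(dog, locus, status, (a1, a2))
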