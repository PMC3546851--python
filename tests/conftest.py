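import numpy as np
import pytest

from seqsuite.core import Alphabet, Sequence, SequenceCollection

# A small but structurally complete GCG Wisconsin codon usage fixture:
# header row, a fully covered Lys with a 75/25 split, single-codon Met/Trp,
# a two-codon Phe, and a stop (End) row.
GCG_FIXTURE = """\
AmAcid  Codon     Number    /1000     Fraction

Met     ATG       100.00    25.00     1.00
Lys     AAA        75.00    18.75     0.75
Lys     AAG        25.00     6.25     0.25
Phe     TTT        60.00    15.00     0.60
Phe     TTC        40.00    10.00     0.40
Trp     TGG        10.00     2.50     1.00
End     TAA         5.00     1.25     1.00
"""


@pytest.fixture(scope="session")
def gcg_table():
    from seqsuite.io import parse_codon_usage_gcg

    return parse_codon_usage_gcg(GCG_FIXTURE)


@pytest.fixture(scope="session")
def blosum62():
    from seqsuite.io import load_blosum62

    return load_blosum62()


def dna(text, ident="s"):
    return Sequence(ident, text, Alphabet.NUCLEIC)


def prot(text, ident="p"):
    return Sequence(ident, text, Alphabet.PROTEIN)


@pytest.fixture
def random_dna():
    def make(length, seed=0, ident="r"):
        rng = np.random.default_rng(seed)
        return dna("".join("ACGT"[k] for k in rng.integers(0, 4, length)), ident)

    return make


@pytest.fixture
def random_protein():
    def make(length, seed=0, ident="rp"):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        return prot("".join(aas[k] for k in rng.integers(0, 20, length)), ident)

    return make
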