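import numpy as np
import pytest

from mhcsel.alignment import GAP, NUCLEOTIDES, SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20230624)


def random_nt_alignment(rng, n_seqs, n_cols, gap_frac=0.0):
    """A random nucleotide alignment, optionally sprinkled with gaps."""
    alphabet = np.array(list(NUCLEOTIDES))
    mat = alphabet[rng.integers(0, 4, size=(n_seqs, n_cols))]
    if gap_frac:
        mat[rng.random(size=mat.shape) < gap_frac] = GAP
    return ["".join(row) for row in mat]


def random_sense_codon(rng):
    return SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
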