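import numpy as np
import pytest

from scelestial.genotype import MISSING, N_OBSERVED, CellSequence, GenotypeMatrix
from scelestial.genotype import sequences_from_strings


@pytest.fixture
def worked_sequences():
    """The four-cell worked example: CAC, GAG, GCC and XAC (X = missing),
    each base b coded as the homozygous genotype b/b."""
    return sequences_from_strings(["CAC", "GAG", "GCC", "XAC"], ["a", "b", "c", "d"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_matrix(rng, m, n, missing_rate=0.1):
    states = rng.integers(0, N_OBSERVED, size=(m, n)).astype(np.int8)
    states[rng.random((m, n)) < missing_rate] = MISSING
    return GenotypeMatrix(
        [f"locus{i}" for i in range(m)],
        [f"cell{j}" for j in range(n)],
        states,
    )


def random_sequences(rng, n, m, n_states=N_OBSERVED, missing_rate=0.0):
    seqs = []
    for i in range(n):
        s = rng.integers(0, n_states, size=m).astype(np.int8)
        s[rng.random(m) < missing_rate] = MISSING
        seqs.append(CellSequence(f"s{i}", s))
    return seqs
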