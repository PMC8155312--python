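import numpy as np
import pytest

from ambigram.alignment_stats import CodonAlignment


@pytest.fixture
def toy_alignment() -> CodonAlignment:
    """6 sequences x 3 codons with hand-placed variants.

    Locus 1 (consensus AGG, a double-synonym Arg codon): variants CGG
    (transversion, doubly synonymous) and AGA (transition, synonymous
    forward only at this consensus? AGA is Arg -> synonymous; its reverse
    complement UCU differs from AGG's CCU, so singly synonymous).
    Locus 2 (consensus CAA, double-synonym Gln): variants CAG (transition,
    doubly synonymous) and GAA (transversion, non-synonymous Glu).
    Locus 3 (consensus AAA, not a double-synonym codon): no variants.
    """
    seqs = [
        "AGGCAAAAA",
        "AGGCAAAAA",
        "AGGCAGAAA",
        "AGGGAAAAA",
        "CGGCAAAAA",
        "AGACAAAAA",
    ]
    return CodonAlignment(sequences=seqs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
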