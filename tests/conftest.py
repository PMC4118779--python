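import pytest

from alnviz.io_formats import AlignmentSet, Alphabet, SequenceRecord
from alnviz.variation import load_blosum80


def make_alignment(seqs, alphabet=Alphabet.DNA, labels=None):
    """Build an AlignmentSet from bare residue strings."""
    labels = labels or [f"s{i + 1}" for i in range(len(seqs))]
    return AlignmentSet(
        tuple(SequenceRecord(lbl, seq) for lbl, seq in zip(labels, seqs)),
        alphabet,
    )


@pytest.fixture(scope="session")
def blosum80():
    return load_blosum80()
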