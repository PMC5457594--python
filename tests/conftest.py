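import pytest

from ntacpred.seqdata import LabeledSequence, SequenceDataset, deduplicate
from ntacpred.synthetic import emulated_study_dataset


@pytest.fixture
def tiny_ds() -> SequenceDataset:
    """Six hand-written sequences, 3 acetylated / 3 unacetylated."""
    rows = [
        ("p1", "SDAAVAKLID", "positive"),
        ("p2", "ADKLMNQRST", "positive"),
        ("p3", "AEKLMNQRST", "positive"),
        ("n1", "GKKLMNQRST", "negative"),
        ("n2", "PKKLMNQRST", "negative"),
        ("n3", "VRKLMNQRST", "negative"),
    ]
    return SequenceDataset([LabeledSequence(*r) for r in rows])


@pytest.fixture(scope="session")
def study_ds() -> SequenceDataset:
    """Deduplicated emulated study set (411 acetylated + 400 unacetylated)."""
    return deduplicate(emulated_study_dataset(seed=11))
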