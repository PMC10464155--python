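import numpy as np
import pytest

from hybridseq.io_sequences import LabeledDataset, SequenceRecord
from hybridseq.synthetic_data import SyntheticSpec, generate_dataset, make_separable

TWO_RECORD_FASTA = """\
>geneA first test gene
ACGTACGTACGT
>geneB second test gene
acgtTTTT
GGGGacgt
"""


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(TWO_RECORD_FASTA)
    return path


@pytest.fixture
def labels_file(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text("id\tlabel\ngeneA\tcase\ngeneB\tcontrol\n")
    return path


@pytest.fixture
def tiny_dataset():
    """Four hand-written records, two classes."""
    records = [
        SequenceRecord("s1", "s1", "ACGTACGTACGTACGT"),
        SequenceRecord("s2", "s2", "ACGTACGAACGTACGA"),
        SequenceRecord("s3", "s3", "TTTTGGGGTTTTGGGG"),
        SequenceRecord("s4", "s4", "TTTTGGGATTTTGGGA"),
    ]
    labels = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
    return LabeledDataset(records=records, labels=labels)


@pytest.fixture
def separable_dataset():
    """A small well-separated two-class dataset (seeded)."""
    spec = SyntheticSpec(samples_per_subgroup=12, sequence_length=400, seed=7)
    spec = make_separable(spec, 0.3)
    dataset, subgroups = generate_dataset(spec)
    return dataset, subgroups


@pytest.fixture
def rng():
    return np.random.default_rng(0)
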