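"""Reading, writing and validation of FASTA sequence sets and label tables.

Sequences are stored uppercase so that k-mer identity is case-insensitive.
A record id is the FASTA header token before the first whitespace; the full
header line is kept as the description, which matches the common convention
for joining FASTA files against external annotation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: unambiguous nucleotide alphabet used throughout the package
DNA_ALPHABET = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: id, free-text description and an uppercase sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")


@dataclass
class LabeledDataset:
    """A set of sequence records paired with one categorical label each."""

    records: list[SequenceRecord]
    labels: dict[str, str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = sorted(set(self.labels.values()))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_list(self) -> list[str]:
        """Labels in record order."""
        return [self.labels[r.id] for r in self.records]

    def label_indices(self) -> list[int]:
        """Labels in record order, encoded as indices into ``class_names``."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return [index[self.labels[r.id]] for r in self.records]


def read_fasta(path: str | Path, strict: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Multi-line bodies are concatenated, record order is preserved and
    sequences are uppercased.  In strict mode an empty sequence body is an
    error; otherwise empty records are kept (they produce zero k-mer
    windows downstream).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise ValueError(
                f"{path}: not a FASTA file (content before the first '>' header)"
            )
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if strict and not seq:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(
                SequenceRecord(id=rec.id, description=rec.description, sequence=seq)
            )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA (the parser's round-trip peer)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=_strip_id(r))
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _strip_id(record: SequenceRecord) -> str:
    """Biopython prints `id description`; avoid doubling the id token."""
    desc = record.description
    if desc.startswith(record.id):
        desc = desc[len(record.id) :].strip()
    return desc


def read_labels(
    path: str | Path,
    records: Sequence[SequenceRecord],
    strict: bool = True,
) -> LabeledDataset:
    """Join a delimited ``id,label`` table (CSV or TSV) onto FASTA records.

    Duplicate ids in the table are always an error.  A table row whose id
    matches no record is an error in strict mode and a warning otherwise.
    Likewise a record with no label row.
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (id, label)")
    id_col, label_col = table.columns[:2]
    ids = table[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate ids in label table: {dupes}")
    labels = dict(zip(ids, table[label_col].astype(str)))

    record_ids = {r.id for r in records}
    unknown = [i for i in labels if i not in record_ids]
    if unknown:
        if strict:
            raise ValueError(f"{path}: label rows for unknown record ids: {unknown}")
        warnings.warn(f"skipping label rows for unknown ids: {unknown}")
        for i in unknown:
            del labels[i]

    unlabeled = [r.id for r in records if r.id not in labels]
    if unlabeled:
        if strict:
            raise ValueError(f"records without a label: {unlabeled}")
        warnings.warn(f"dropping records without a label: {unlabeled}")
    kept = [r for r in records if r.id in labels]
    return LabeledDataset(records=kept, labels=labels)


def validate_sequence(
    record: SequenceRecord, strict: bool = False
) -> tuple[SequenceRecord, dict]:
    """Count non-ACGT symbols; reject them in strict mode, keep them otherwise.

    Lenient mode retains ambiguity codes — downstream k-mer windows that
    contain them are skipped, so partially ambiguous records still
    contribute signal from their clean stretches.
    """
    bad_positions = [
        i for i, ch in enumerate(record.sequence) if ch not in DNA_ALPHABET
    ]
    report = {"ambiguous": len(bad_positions), "positions": bad_positions}
    if strict and bad_positions:
        raise ValueError(
            f"record {record.id!r}: non-ACGT symbols at positions {bad_positions}"
        )
    if strict and not record.sequence:
        raise ValueError(f"record {record.id!r}: empty sequence")
    return replace(record), report


def write_labels(labels: Mapping[str, str], path: str | Path, sep: str = "\t") -> None:
    """Write an ``id,label`` table next to a FASTA file."""
    frame = pd.DataFrame(
        {"id": list(labels.keys()), "label": list(labels.values())}
    )
    frame.to_csv(path, sep=sep, index=False)
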