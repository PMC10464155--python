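"""k-mer featurization of nucleotide sequences.

A sequence is encoded by the counts (or frequencies) of its length-k
substrings, extracted with a stride-1 sliding window.  Windows containing
symbols outside {A,C,G,T} are skipped rather than expanded or imputed, so
counts are unbiased over the unambiguous portion of a record.

An optional canonical mode collapses each k-mer with its reverse
complement (complementary-strand pairing), mapping mass onto the
lexicographically smaller member of each pair; for k=3 this reduces the
64 trigrams to 32 equivalence classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_sequences import DNA_ALPHABET, LabeledDataset

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

Mode = Literal["counts", "frequency"]


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered k-mer feature space for a fixed k.

    ``canonical=False`` enumerates all 4^k k-mers in lexicographic order;
    ``canonical=True`` enumerates the reverse-complement equivalence
    classes, each named by its lexicographically smaller representative.
    """

    k: int
    canonical: bool = False
    alphabet: tuple[str, ...] = DNA_ALPHABET
    feature_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        full = ["".join(p) for p in product(self.alphabet, repeat=self.k)]
        if self.canonical:
            names = sorted({min(m, reverse_complement(m)) for m in full})
        else:
            names = full
        object.__setattr__(self, "feature_names", tuple(names))

    def __len__(self) -> int:
        return len(self.feature_names)

    @property
    def index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.feature_names)}


@dataclass
class FeatureTable:
    """Samples × features matrix with ids, feature names and optional labels."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )
        frame.index.name = "id"
        if self.labels is not None:
            frame["label"] = self.labels
        return frame

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "FeatureTable":
        labels = None
        if "label" in frame.columns:
            labels = frame["label"].astype(str).tolist()
            frame = frame.drop(columns="label")
        return cls(
            sample_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            labels=labels,
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "FeatureTable":
        frame = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        return cls.from_dataframe(frame)


def enumerate_kmers(sequence: str, k: int) -> list[str]:
    """All valid stride-1 windows of length k, in position order.

    Windows containing symbols outside the ACGT alphabet are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = sequence.upper()
    valid = set(DNA_ALPHABET)
    return [
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if set(seq[i : i + k]) <= valid
    ]


def kmer_vector(
    sequence: str, vocab: KmerVocabulary, mode: Mode = "frequency"
) -> np.ndarray:
    """Count vector of a sequence over ``vocab``; frequency mode row-normalizes.

    A sequence with zero valid windows yields an all-zero row (with a
    warning in frequency mode) rather than NaNs.
    """
    row = np.zeros(len(vocab), dtype=float)
    index = vocab.index
    for kmer in enumerate_kmers(sequence, vocab.k):
        if vocab.canonical:
            kmer = min(kmer, reverse_complement(kmer))
        row[index[kmer]] += 1.0
    if mode == "frequency":
        total = row.sum()
        if total > 0:
            row /= total
        else:
            warnings.warn("sequence yielded zero valid k-mer windows; zero row")
    elif mode != "counts":
        raise ValueError(f"unknown mode {mode!r}")
    return row


def collapse_reverse_complement(
    vector: np.ndarray, vocab: KmerVocabulary
) -> tuple[np.ndarray, KmerVocabulary]:
    """Fold a full 4^k vector onto reverse-complement equivalence classes.

    Each k-mer's mass is added to the lexicographically smaller of the
    pair {kmer, revcomp(kmer)}; total mass is conserved.
    """
    if vocab.canonical:
        raise ValueError("input vocabulary is already canonical")
    canon = KmerVocabulary(k=vocab.k, canonical=True, alphabet=vocab.alphabet)
    out = np.zeros(len(canon), dtype=float)
    cidx = canon.index
    for name, value in zip(vocab.feature_names, np.asarray(vector, dtype=float)):
        out[cidx[min(name, reverse_complement(name))]] += value
    return out, canon


def featurize_dataset(
    dataset: LabeledDataset | Iterable,
    k: int = 3,
    mode: Mode = "frequency",
    canonical: bool = False,
) -> FeatureTable:
    """One feature row per record; deterministic column order; labels carried.

    Default k=3: the trigram spectrum, the sweep optimum among
    k ∈ {1, 2, 3, 5, 6} for gene-scale sequences, balancing resolution
    (4^k columns) against sampling noise per column.
    """
    if isinstance(dataset, LabeledDataset):
        records = dataset.records
        labels = dataset.label_list()
    else:
        records = list(dataset)
        labels = None
    vocab = KmerVocabulary(k=k, canonical=canonical)
    rows = np.zeros((len(records), len(vocab)), dtype=float)
    for i, rec in enumerate(records):
        try:
            rows[i] = kmer_vector(rec.sequence, vocab, mode=mode)
        except Exception as exc:  # pragma: no cover - context wrapper
            raise RuntimeError(f"featurizing record {rec.id!r} failed") from exc
    return FeatureTable(
        sample_ids=[r.id for r in records],
        feature_names=list(vocab.feature_names),
        values=rows,
        labels=labels,
    )


def save_vocabulary(vocab: KmerVocabulary, path: str | Path) -> None:
    payload = {
        "k": vocab.k,
        "canonical": vocab.canonical,
        "alphabet": list(vocab.alphabet),
        "feature_names": list(vocab.feature_names),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_vocabulary(path: str | Path) -> KmerVocabulary:
    payload = json.loads(Path(path).read_text())
    vocab = KmerVocabulary(
        k=payload["k"],
        canonical=payload["canonical"],
        alphabet=tuple(payload["alphabet"]),
    )
    if list(vocab.feature_names) != payload["feature_names"]:
        raise ValueError(f"{path}: stored feature names do not match k/alphabet")
    return vocab
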