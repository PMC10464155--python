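"""Synthetic labelled nucleotide datasets with planted class and subgroup
structure.

The generator emulates a curated gene-sequence collection in which each
disease class is internally heterogeneous: every class is a union of
latent subgroups whose base compositions differ.  Sequences are drawn
i.i.d. per position from a subgroup-specific composition (optionally an
order-1 Markov chain), so the expected k-mer spectrum of a subgroup is a
smooth, controllable function of its composition.

``make_separable`` plants the structure geometrically.  Compositions are
perturbations of the uniform distribution along a zero-sum class
direction ``u``; each subgroup's coefficient on ``u`` determines how
much (and with which sign) it expresses the class signal.

In the default ``aligned`` style the subgroups of a class differ in how
strongly they express the class signal (coefficients ±0.5δ and ±1.5δ),
which places the four subgroups at four distinct positions along the
class-discriminant axis — recoverable by clustering class-probability
vectors.  In the ``opposing`` style the second subgroup of each class
carries the class signal with *opposite sign* and reduced magnitude
(coefficients +1.0δ and −0.5δ): a partial XOR along ``u``.  A single
global linear rule then misclassifies one subgroup of each class,
while a model that first routes samples to subgroup-level clusters
can classify each cluster locally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io_sequences import (
    DNA_ALPHABET,
    LabeledDataset,
    SequenceRecord,
    write_fasta,
    write_labels,
)

_U = np.array([1.0, -1.0, 1.0, -1.0]) / 4.0  # class direction (zero-sum)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator.

    Defaults emulate the scale of a curated two-class gene collection:
    2 classes × 2 latent subgroups × 45 sequences of length 1000
    (180 records, gene-like length at tractable cost).
    """

    n_classes: int = 2
    subgroups_per_class: int = 2
    samples_per_subgroup: int = 45
    sequence_length: int = 1000
    compositions: tuple[tuple[float, ...], ...] | None = None
    markov: tuple | None = None  # optional per-subgroup 4x4 transition rows
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.subgroups_per_class, self.samples_per_subgroup) < 1:
            raise ValueError("all counts must be >= 1")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.compositions is not None:
            comps = np.asarray(self.compositions, dtype=float)
            expected = self.n_classes * self.subgroups_per_class
            if comps.shape != (expected, 4):
                raise ValueError(
                    f"need {expected} compositions of length 4, got {comps.shape}"
                )
            if np.any(comps < 0) or not np.allclose(comps.sum(axis=1), 1.0):
                raise ValueError("compositions must be probability vectors")

    @property
    def n_subgroups(self) -> int:
        return self.n_classes * self.subgroups_per_class

    @property
    def n_records(self) -> int:
        return self.n_subgroups * self.samples_per_subgroup

    def composition_matrix(self) -> np.ndarray:
        if self.compositions is None:
            return np.tile(np.full(4, 0.25), (self.n_subgroups, 1))
        return np.asarray(self.compositions, dtype=float)


def make_separable(
    spec: SyntheticSpec,
    divergence: float,
    style: str = "aligned",
    subgroup_scales: tuple[float, ...] = (0.5, 1.5),
) -> SyntheticSpec:
    """Plant class/subgroup structure of the given strength.

    ``divergence`` δ scales all composition perturbations; δ = 0 leaves
    every subgroup identical (classification is chance).  Perturbed
    compositions leaving the probability simplex are clipped and
    renormalized with a warning.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if style not in ("aligned", "opposing"):
        raise ValueError(f"unknown style {style!r}")
    comps = []
    clipped = False
    for c in range(spec.n_classes):
        class_sign = 1.0 if c % 2 == 0 else -1.0
        for s in range(spec.subgroups_per_class):
            base = np.full(4, 0.25)
            if style == "aligned":
                scale = subgroup_scales[s % len(subgroup_scales)]
            else:  # opposing: sign of the class signal flips by subgroup
                scale = 1.0 if s % 2 == 0 else -0.5
            comp = base + divergence * class_sign * scale * _U
            if np.any(comp < 0):
                clipped = True
                comp = np.clip(comp, 1e-9, None)
            comps.append(tuple(comp / comp.sum()))
    if clipped:
        warnings.warn("divergence pushed compositions out of the simplex; renormalized")
    return replace(spec, compositions=tuple(comps))


def _markov_sequence(rng: np.random.Generator, trans: np.ndarray, length: int) -> str:
    stationary = np.full(4, 0.25)
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(4, p=stationary)
    for i in range(1, length):
        states[i] = rng.choice(4, p=trans[states[i - 1]])
    return "".join(DNA_ALPHABET[s] for s in states)


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, dict[str, int]]:
    """Draw the dataset; returns (dataset, hidden subgroup id per record).

    Class label of a record is its subgroup's parent class; the hidden
    subgroup ids support cluster-recovery checks.  Fully deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    comps = spec.composition_matrix()
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    subgroups: dict[str, int] = {}
    idx = 0
    for c in range(spec.n_classes):
        for s in range(spec.subgroups_per_class):
            g = c * spec.subgroups_per_class + s
            for _ in range(spec.samples_per_subgroup):
                rid = f"seq{idx:05d}"
                if spec.markov is not None:
                    trans = np.asarray(spec.markov[g], dtype=float)
                    seq = _markov_sequence(rng, trans, spec.sequence_length)
                else:
                    draws = rng.choice(4, size=spec.sequence_length, p=comps[g])
                    seq = "".join(DNA_ALPHABET[b] for b in draws)
                records.append(
                    SequenceRecord(
                        id=rid,
                        description=f"{rid} class={c} subgroup={g}",
                        sequence=seq,
                    )
                )
                labels[rid] = f"class{c}"
                subgroups[rid] = g
                idx += 1
    dataset = LabeledDataset(records=records, labels=labels)
    return dataset, subgroups


def write_fixture(spec: SyntheticSpec, directory: str | Path) -> dict[str, Path]:
    """Materialize a dataset as FASTA + labels TSV + truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, subgroups = generate_dataset(spec)
    fasta = directory / "sequences.fasta"
    labels = directory / "labels.tsv"
    truth = directory / "truth.json"
    write_fasta(dataset.records, fasta)
    write_labels(dataset.labels, labels)
    truth.write_text(
        json.dumps(
            {
                "subgroups": subgroups,
                "n_subgroups": spec.n_subgroups,
                "n_classes": spec.n_classes,
                "seed": spec.seed,
            },
            indent=2,
        )
    )
    return {"fasta": fasta, "labels": labels, "truth": truth}
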