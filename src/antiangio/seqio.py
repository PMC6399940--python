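"""Peptide, label and feature-matrix I/O.

Sequences are restricted to the 20 canonical amino acids; ambiguous
residues (B, J, O, U, X, Z) are rejected rather than imputed because
every downstream encoder needs an exact per-residue property lookup.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = "positive"
NEGATIVE = "negative"

_POSITIVE_ALIASES = {"pos", "positive", "1"}
_NEGATIVE_ALIASES = {"neg", "negative", "0"}


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


class FastaParseError(ValueError):
    """The input file is not parseable as FASTA."""


class LabelParseError(ValueError):
    """A label table row could not be interpreted."""


@dataclass(frozen=True)
class Peptide:
    """A validated single-letter amino-acid sequence with an identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id:
            raise SequenceValidationError("peptide id must be non-empty")
        if not self.seq:
            raise SequenceValidationError(f"peptide {self.id!r}: empty sequence")
        bad = sorted(set(self.seq) - _AA_SET)
        if bad:
            raise SequenceValidationError(
                f"peptide {self.id!r}: invalid residue(s) {', '.join(bad)} "
                f"(allowed: {AMINO_ACIDS})"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Peptides plus a per-peptide class label (1 = positive, 0 = negative).

    ``labels`` may be None in prediction mode (unlabeled input).
    """

    peptides: list[Peptide]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide ids: {dupes}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != len(self.peptides):
                raise ValueError(
                    f"{len(self.peptides)} peptides but {len(self.labels)} labels"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 (negative) or 1 (positive)")

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def __len__(self) -> int:
        return len(self.peptides)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        peps = [self.peptides[i] for i in indices]
        labs = None if self.labels is None else self.labels[list(indices)]
        return LabeledDataset(peps, labs)


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from a FASTA file, uppercasing and validating sequences."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: no FASTA records found")
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        peptides.append(Peptide(id=record.id, seq=str(record.seq)))
    if not peptides:
        raise FastaParseError(f"{path}: no FASTA records found")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as two-line FASTA records (byte-deterministic)."""
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.seq}\n")


def parse_label(token: str) -> int:
    t = str(token).strip().lower()
    if t in _POSITIVE_ALIASES:
        return 1
    if t in _NEGATIVE_ALIASES:
        return 0
    raise LabelParseError(
        f"unrecognized label {token!r} (expected one of "
        f"{sorted(_POSITIVE_ALIASES)} / {sorted(_NEGATIVE_ALIASES)})"
    )


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) table; tab or comma delimited.

    A first row whose second field is not a parseable label is treated as
    a header and skipped.
    """
    path = Path(path)
    out: dict[str, int] = {}
    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    for i, row in enumerate(rows):
        fields = row.split("\t") if "\t" in row else row.split(",")
        if len(fields) != 2:
            raise LabelParseError(f"{path}: row {i + 1}: expected 2 columns, got {len(fields)}")
        pid, token = fields[0].strip(), fields[1]
        try:
            lab = parse_label(token)
        except LabelParseError:
            if i == 0:
                continue  # header row
            raise
        if pid in out:
            raise LabelParseError(f"{path}: duplicate id {pid!r}")
        out[pid] = lab
    return out


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for p, lab in zip(dataset.peptides, dataset.labels):
            fh.write(f"{p.id}\t{POSITIVE if lab else NEGATIVE}\n")


def attach_labels(peptides: list[Peptide], labels: dict[str, int]) -> LabeledDataset:
    missing = [p.id for p in peptides if p.id not in labels]
    if missing:
        raise LabelParseError(f"no label for peptide(s): {missing[:10]}")
    return LabeledDataset(peptides, np.array([labels[p.id] for p in peptides], dtype=np.int8))


def write_features(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as TSV (header row, first column = peptide id)."""
    if matrix.shape[0] < 1:
        raise ValueError("refusing to write an empty feature matrix")
    matrix.to_csv(path, sep="\t", index_label="id")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a TSV feature matrix written by :func:`write_features`."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.index.name = None
    return m
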