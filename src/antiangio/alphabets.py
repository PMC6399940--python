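"""Reduced amino-acid alphabet and per-residue property tables.

Holds three lookup structures the encoders depend on:

* :class:`ReducedAlphabet` — the 8-class partition of the 20 residues
  used for reduced-alphabet k-mer counting;
* :class:`IndexTable` — physico-chemical indices (AAIndex-style: one
  numeric value per residue per index), with correlation-based pruning
  to a non-redundant subset;
* :class:`AtomicTable` — per-residue C/H/N/O/S atom counts.

Bundled defaults: a curated 10-index table of widely used published
scales, and atom counts from free-amino-acid molecular formulas
(e.g. Gly = C2H5NO2). Both are replaceable by user-supplied delimited
text tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from antiangio.seqio import AMINO_ACIDS, Peptide

logger = logging.getLogger(__name__)

ATOMS: tuple[str, ...] = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ReducedAlphabet:
    """A partition of the 20 residues into classes with one symbol each."""

    classes: tuple[frozenset, ...]
    class_symbols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        classes = tuple(frozenset(c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        symbols = self.class_symbols or tuple(str(i + 1) for i in range(len(classes)))
        object.__setattr__(self, "class_symbols", tuple(symbols))
        if len(self.class_symbols) != len(classes):
            raise ValueError("one symbol per class required")
        if len(set(self.class_symbols)) != len(self.class_symbols):
            raise ValueError("class symbols must be distinct")
        union = set().union(*classes) if classes else set()
        total = sum(len(c) for c in classes)
        if union != set(AMINO_ACIDS) or total != 20:
            raise ValueError("classes must partition the 20-letter amino-acid alphabet")

    @property
    def mapping(self) -> dict[str, str]:
        return {
            residue: symbol
            for cls, symbol in zip(self.classes, self.class_symbols)
            for residue in cls
        }

    def __len__(self) -> int:
        return len(self.classes)


#: Default 8-class partition derived from clustering 544 physico-chemical
#: and biochemical indices: {A,E} {I,L,F,M,V} {N,D,T,S} {G} {P} {R,K,Q,H} {Y,W} {C}.
DEFAULT_REDUCED_ALPHABET = ReducedAlphabet(
    classes=(
        frozenset("AE"),
        frozenset("ILFMV"),
        frozenset("NDTS"),
        frozenset("G"),
        frozenset("P"),
        frozenset("RKQH"),
        frozenset("YW"),
        frozenset("C"),
    )
)


def reduce_sequence(peptide: Peptide | str, alphabet: ReducedAlphabet) -> str:
    """Map a sequence onto the reduced alphabet, one class symbol per residue."""
    seq = peptide.seq if isinstance(peptide, Peptide) else str(peptide)
    mapping = alphabet.mapping
    try:
        return "".join(mapping[r] for r in seq)
    except KeyError as exc:  # unreachable for a valid partition + valid peptide
        raise RuntimeError(f"residue {exc} not covered by the reduced alphabet") from exc


class IndexTable:
    """Physico-chemical indices: rows = index ids, columns = the 20 residues."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table.columns = [str(c).upper() for c in table.columns]
        if set(table.columns) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(table.columns))
            extra = sorted(set(table.columns) - set(AMINO_ACIDS))
            raise ValueError(
                f"index table must have exactly the 20 residue columns "
                f"(missing: {missing}, unexpected: {extra})"
            )
        table = table[list(AMINO_ACIDS)].astype(float)
        if table.index.duplicated().any():
            dupes = sorted(set(table.index[table.index.duplicated()]))
            raise ValueError(f"duplicate index ids: {dupes}")
        if not np.isfinite(table.to_numpy()).all():
            raise ValueError("index table contains non-finite values")
        self.table = table

    @property
    def index_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def values_for(self, index_id: str) -> pd.Series:
        if index_id not in self.table.index:
            raise KeyError(f"no such index: {index_id!r}")
        return self.table.loc[index_id]

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, index_id: str) -> bool:
        return index_id in self.table.index

    @classmethod
    def from_file(cls, path: str | Path) -> "IndexTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_file(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="index_id")


class AtomicTable:
    """Per-residue atom counts: rows = residues, columns = C, H, N, O, S."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        table.index = [str(i).upper() for i in table.index]
        if set(table.index) != set(AMINO_ACIDS):
            raise ValueError("atomic table must cover exactly the 20 residues")
        if list(table.columns) != list(ATOMS):
            try:
                table = table[list(ATOMS)]
            except KeyError as exc:
                raise ValueError(f"atomic table needs columns {ATOMS}") from exc
        table = table.loc[list(AMINO_ACIDS)]
        arr = table.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any() or (arr != arr.astype(int)).any():
            raise ValueError("atom counts must be non-negative integers")
        table = table.astype(int)
        if (table["C"] < 1).any() or (table["N"] < 1).any():
            raise ValueError("every residue must contain at least one C and one N atom")
        self.table = table

    def counts_for(self, residue: str) -> np.ndarray:
        return self.table.loc[residue].to_numpy(dtype=float)

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomicTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def default_index_table() -> IndexTable:
    """The bundled curated index table (10 widely used published scales)."""
    ref = resources.files("antiangio").joinpath("data/physchem_indices.tsv")
    with resources.as_file(ref) as path:
        return IndexTable.from_file(path)


def default_atomic_table() -> AtomicTable:
    """The bundled atom-count table (free amino-acid molecular formulas)."""
    ref = resources.files("antiangio").joinpath("data/atomic_composition.tsv")
    with resources.as_file(ref) as path:
        return AtomicTable.from_file(path)


def prune_indices_by_correlation(table: IndexTable, threshold: float = 0.8) -> IndexTable:
    """Greedily drop indices until no retained pair has \\|Pearson r\\| >= threshold.

    Correlation is computed over the 20 per-residue values. Zero-variance
    indices (correlation undefined) are excluded first with a warning.
    While a violating pair exists, the pair with the largest \\|r\\| is
    located and its member with the higher mean absolute correlation to
    all remaining indices is dropped (ties: the later row). Deterministic
    for a fixed input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(table) < 1:
        raise ValueError("index table is empty")

    values = table.table.to_numpy(dtype=float)
    ids = table.index_ids
    variances = values.var(axis=1)
    flat = [ids[i] for i in range(len(ids)) if variances[i] == 0.0]
    if flat:
        warnings.warn(
            f"excluding zero-variance index(es) before pruning: {flat}", stacklevel=2
        )
    alive = [i for i in range(len(ids)) if variances[i] > 0.0]

    if len(alive) >= 2:
        corr = np.abs(np.corrcoef(values[alive]))
        np.fill_diagonal(corr, 0.0)
        while True:
            if corr.max() < threshold:
                break
            a, b = np.unravel_index(np.argmax(corr), corr.shape)
            mean_a, mean_b = corr[a].mean(), corr[b].mean()
            drop = b if mean_b >= mean_a else a
            corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
            del alive[drop]

    kept_ids = [ids[i] for i in sorted(alive)]
    return IndexTable(table.table.loc[kept_ids])
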