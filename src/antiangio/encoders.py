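"""The five peptide feature encoders and their concatenation.

Feature blocks, in the frozen column order produced by :func:`encode_all`:

1. ``pse_*``      — type-I pseudo amino acid composition (20 + lambda values)
2. ``k{k}_*``     — k-mer composition over the 20-letter alphabet, ascending k
3. ``rk{k}_*``    — k-mer composition over the reduced 8-class alphabet
4. ``pc_p{i}_*``  — physico-chemical profile of the terminal windows
5. ``at_p{i}_*``  — atomic (C,H,N,O,S) profile of the terminal windows

The terminal profiles read the five C-terminal residues (positions 1-5,
N-to-C order, i.e. residues L-4..L) followed by the five N-terminal
residues (positions 6-10, residues 1..5). Feature names are stable so a
trained model can validate the schema of any matrix it is asked to score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from antiangio.alphabets import ATOMS, AtomicTable, IndexTable, ReducedAlphabet, reduce_sequence
from antiangio.seqio import AMINO_ACIDS, Peptide

logger = logging.getLogger(__name__)

#: index ids the PseAAC encoder looks up in its property table
PSEAAC_PROPERTIES: tuple[str, str, str] = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


class EncodingError(ValueError):
    """A peptide violates a hard precondition of an encoder."""


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable parameters shared by the encoders.

    ``pseaac_lambda`` is the number of sequence-order correlation tiers
    (lambda); ``pseaac_weight`` the weight w balancing composition against
    order terms; ``kmer_ks`` the word lengths counted on both alphabets;
    ``terminal_window`` the number of residues profiled at each terminus;
    ``atom_mode`` selects raw atom counts or per-residue atom fractions.
    """

    pseaac_lambda: int = 6
    pseaac_weight: float = 0.05
    kmer_ks: tuple[int, ...] = (2, 3, 4)
    terminal_window: int = 5
    atom_mode: str = "count"

    def __post_init__(self) -> None:
        object.__setattr__(self, "kmer_ks", tuple(sorted(set(int(k) for k in self.kmer_ks))))
        if self.pseaac_lambda < 1:
            raise ValueError("pseaac_lambda must be >= 1")
        if self.pseaac_weight <= 0:
            raise ValueError("pseaac_weight must be positive")
        if not self.kmer_ks:
            raise ValueError("kmer_ks must be non-empty")
        if any(k < 1 for k in self.kmer_ks):
            raise ValueError("every k must be >= 1")
        if self.terminal_window < 1:
            raise ValueError("terminal_window must be >= 1")
        if self.atom_mode not in ("count", "fraction"):
            raise ValueError("atom_mode must be 'count' or 'fraction'")


# ---------------------------------------------------------------------------
# PseAAC

def _standardize(values: np.ndarray) -> np.ndarray:
    # Chou's convention: zero mean, unit population standard deviation
    std = values.std()
    if std == 0:
        raise ValueError("property has zero variance across residues")
    return (values - values.mean()) / std


def encode_pseaac(
    peptide: Peptide,
    cfg: EncoderConfig,
    props: IndexTable,
    property_ids: Sequence[str] = PSEAAC_PROPERTIES,
) -> np.ndarray:
    """Type-I pseudo amino acid composition: 20 composition + lambda order terms.

    The three classic properties (hydrophobicity, hydrophilicity,
    side-chain mass) are standardized over the 20 residues; the
    correlation factor between two residues is the mean squared
    difference of their standardized property values; theta_k averages
    that factor over all residue pairs k apart. All 20 + lambda
    components share the denominator 1 + w * sum(theta), so they are
    non-negative and sum to one.
    """
    lam, w = cfg.pseaac_lambda, cfg.pseaac_weight
    L = len(peptide)
    if L < lam + 1:
        raise EncodingError(
            f"peptide {peptide.id!r}: length {L} < minimum {lam + 1} "
            f"required for PseAAC with lambda={lam}"
        )
    prop_rows = []
    for pid in property_ids:
        if pid not in props:
            raise KeyError(f"PseAAC property {pid!r} missing from index table")
        prop_rows.append(_standardize(props.values_for(pid).to_numpy(dtype=float)))
    prop = np.vstack(prop_rows)  # (n_props, 20)

    pos = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    idxs = np.array([pos[r] for r in peptide.seq])

    comp = np.bincount(idxs, minlength=20) / L

    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = prop[:, idxs[k:]] - prop[:, idxs[:-k]]
        theta[k - 1] = np.mean(diffs**2)

    denom = 1.0 + w * theta.sum()
    return np.concatenate([comp, w * theta]) / denom


def pseaac_feature_names(cfg: EncoderConfig) -> list[str]:
    return [f"pse_{aa}" for aa in AMINO_ACIDS] + [
        f"pse_theta{i}" for i in range(1, cfg.pseaac_lambda + 1)
    ]


# ---------------------------------------------------------------------------
# k-mer composition

def kmer_words(symbols: Sequence[str], k: int) -> list[str]:
    """All |symbols|**k words in lexicographic (product) order."""
    return ["".join(w) for w in itertools.product(symbols, repeat=k)]


def _kmer_symbols(alphabet: str | ReducedAlphabet) -> tuple[str, tuple[str, ...]]:
    if isinstance(alphabet, ReducedAlphabet):
        return "reduced", alphabet.class_symbols
    return "full", tuple(alphabet)


def encode_kmer(peptide: Peptide, k: int, alphabet: str | ReducedAlphabet = AMINO_ACIDS) -> np.ndarray:
    """Fraction of each possible k-length word among the L-k+1 windows.

    With a :class:`ReducedAlphabet` the sequence is first mapped to class
    symbols. Peptides shorter than k yield an all-zero vector (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(alphabet, ReducedAlphabet):
        seq = reduce_sequence(peptide, alphabet)
        symbols = alphabet.class_symbols
    else:
        seq = peptide.seq
        symbols = tuple(alphabet)
    n = len(symbols)
    vec = np.zeros(n**k)
    L = len(seq)
    if L < k:
        logger.warning(
            "peptide %r: length %d < k=%d; k-mer block is all-zero", peptide.id, L, k
        )
        return vec
    digit = {s: i for i, s in enumerate(symbols)}
    code = np.array([digit[c] for c in seq])
    weights = n ** np.arange(k - 1, -1, -1)
    window_idx = np.lib.stride_tricks.sliding_window_view(code, k) @ weights
    np.add.at(vec, window_idx, 1.0)
    return vec / (L - k + 1)


def kmer_feature_names(k: int, alphabet: str | ReducedAlphabet = AMINO_ACIDS) -> list[str]:
    kind, symbols = _kmer_symbols(alphabet)
    prefix = f"rk{k}_" if kind == "reduced" else f"k{k}_"
    return [prefix + w for w in kmer_words(symbols, k)]


# ---------------------------------------------------------------------------
# terminal-window profiles

def _terminal_residues(seq: str, window: int, peptide_id: str) -> list[str | None]:
    """Residues at profile positions 1..2*window; None marks a missing position.

    Positions 1..window: the C-terminal window, residues L-window+1..L in
    N-to-C order. Positions window+1..2*window: the N-terminal window,
    residues 1..window. For window <= L < 2*window the windows simply
    overlap; for L < window the out-of-range positions are zero-filled.
    """
    L = len(seq)
    ct = [seq[i - 1] if i >= 1 else None for i in range(L - window + 1, L + 1)]
    nt = [seq[i - 1] if i <= L else None for i in range(1, window + 1)]
    if L < window:
        logger.warning(
            "peptide %r: length %d < terminal window %d; missing positions zero-filled",
            peptide_id, L, window,
        )
    return ct + nt


def encode_physchem_profile(peptide: Peptide, idx: IndexTable, cfg: EncoderConfig) -> np.ndarray:
    """Per-position physico-chemical values of the two terminal windows.

    Output is position-major: for each of the 2*window positions, the
    value of every index for the residue at that position. With a
    191-index table and the default window this is the 10 x 191 = 1910
    dimensional profile.
    """
    if len(idx) < 1:
        raise ValueError("index table is empty")
    residues = _terminal_residues(peptide.seq, cfg.terminal_window, peptide.id)
    cols = idx.table  # rows = indices, columns = residues
    blocks = [
        np.zeros(len(idx)) if r is None else cols[r].to_numpy(dtype=float)
        for r in residues
    ]
    return np.concatenate(blocks)


def physchem_feature_names(idx: IndexTable, cfg: EncoderConfig) -> list[str]:
    return [
        f"pc_p{pos}_{index_id}"
        for pos in range(1, 2 * cfg.terminal_window + 1)
        for index_id in idx.index_ids
    ]


def encode_atomic_profile(peptide: Peptide, at: AtomicTable, cfg: EncoderConfig) -> np.ndarray:
    """Per-position C,H,N,O,S atom counts (or fractions) of the terminal windows.

    Same 2*window position layout as the physico-chemical profile; the
    default window gives a 10 x 5 = 50 dimensional vector. In
    ``fraction`` mode each residue's counts are divided by its total
    atom count.
    """
    residues = _terminal_residues(peptide.seq, cfg.terminal_window, peptide.id)
    blocks = []
    for r in residues:
        if r is None:
            blocks.append(np.zeros(len(ATOMS)))
            continue
        counts = at.counts_for(r)
        if cfg.atom_mode == "fraction":
            counts = counts / counts.sum()
        blocks.append(counts)
    return np.concatenate(blocks)


def atomic_feature_names(cfg: EncoderConfig) -> list[str]:
    return [
        f"at_p{pos}_{atom}"
        for pos in range(1, 2 * cfg.terminal_window + 1)
        for atom in ATOMS
    ]


# ---------------------------------------------------------------------------
# concatenation

def feature_names(cfg: EncoderConfig, idx: IndexTable, ra: ReducedAlphabet) -> list[str]:
    """The full frozen column schema for :func:`encode_all`."""
    names = pseaac_feature_names(cfg)
    for k in cfg.kmer_ks:
        names += kmer_feature_names(k, AMINO_ACIDS)
    for k in cfg.kmer_ks:
        names += kmer_feature_names(k, ra)
    names += physchem_feature_names(idx, cfg)
    names += atomic_feature_names(cfg)
    return names


def encode_all(
    peptides: Sequence[Peptide],
    cfg: EncoderConfig,
    idx: IndexTable,
    at: AtomicTable,
    ra: ReducedAlphabet,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Encode peptides into the concatenated feature matrix.

    Column blocks in fixed order: PseAAC | k-mer (20-letter, ascending k)
    | k-mer (reduced, ascending k) | physico-chemical profile | atomic
    profile. A peptide failing a hard precondition (too short for
    PseAAC) aborts the batch naming the offender, unless ``skip_invalid``
    is set, in which case it is dropped with a warning.
    """
    ids = [p.id for p in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peptide ids in encode_all input")

    kept: list[Peptide] = []
    for p in peptides:
        if len(p) < cfg.pseaac_lambda + 1:
            if skip_invalid:
                logger.warning(
                    "skipping peptide %r: length %d < %d required for PseAAC",
                    p.id, len(p), cfg.pseaac_lambda + 1,
                )
                continue
            raise EncodingError(
                f"peptide {p.id!r}: length {len(p)} < minimum "
                f"{cfg.pseaac_lambda + 1} for PseAAC (use skip_invalid to drop it)"
            )
        kept.append(p)
    if not kept:
        raise EncodingError("no encodable peptides")

    blocks: list[np.ndarray] = []
    blocks.append(np.vstack([encode_pseaac(p, cfg, idx) for p in kept]))
    for k in cfg.kmer_ks:
        blocks.append(np.vstack([encode_kmer(p, k, AMINO_ACIDS) for p in kept]))
    for k in cfg.kmer_ks:
        blocks.append(np.vstack([encode_kmer(p, k, ra) for p in kept]))
    blocks.append(np.vstack([encode_physchem_profile(p, idx, cfg) for p in kept]))
    blocks.append(np.vstack([encode_atomic_profile(p, at, cfg) for p in kept]))

    matrix = np.hstack(blocks)
    return pd.DataFrame(matrix, index=[p.id for p in kept], columns=feature_names(cfg, idx, ra))
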