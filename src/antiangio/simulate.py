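"""Synthetic labeled peptide datasets with a controllable class signal.

Negatives are drawn i.i.d. from a background residue distribution
(uniform by default, so k-mer expectations stay analytically simple; a
natural-frequency mode is available). Positives share the background
but up-weight a chosen residue set by an enrichment factor, and can
additionally carry a fixed residue somewhere in one terminal window.
This mimics the two handles real anti-angiogenic peptides offer a
classifier — biased global composition and terminal motifs — without
pretending to reproduce true biological motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from antiangio.seqio import AMINO_ACIDS, LabeledDataset, Peptide

#: approximate natural amino-acid frequencies (Swiss-Prot composition, %)
NATURAL_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic dataset generator.

    ``signal_residues`` are up-weighted by ``enrichment`` (>= 1) in
    positive peptides; ``terminal_signal`` optionally forces a residue
    at a random position of the N- or C-terminal window of positives.
    The default length range [7, 30] keeps every peptide long enough
    for PseAAC with the default lambda of 6.
    """

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (7, 30)
    signal_residues: frozenset = frozenset()
    enrichment: float = 1.0
    terminal_signal: Optional[tuple[str, str]] = None  # (residue, "N" | "C")
    terminal_window: int = 5
    seed: int = 0
    background: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"impossible length range {self.length_range}")
        object.__setattr__(self, "signal_residues", frozenset(str(r).upper() for r in self.signal_residues))
        if not self.signal_residues <= set(AMINO_ACIDS):
            raise ValueError("signal residues must be standard amino acids")
        if self.enrichment < 1:
            raise ValueError("enrichment factor must be >= 1")
        if self.terminal_signal is not None:
            residue, end = self.terminal_signal
            if residue.upper() not in AMINO_ACIDS or end.upper() not in ("N", "C"):
                raise ValueError("terminal_signal must be (residue, 'N'|'C')")
            object.__setattr__(self, "terminal_signal", (residue.upper(), end.upper()))
        if self.background not in ("uniform", "natural"):
            raise ValueError("background must be 'uniform' or 'natural'")


def _background_probs(spec: SimSpec) -> np.ndarray:
    if spec.background == "natural":
        p = np.array([NATURAL_FREQUENCIES[a] for a in AMINO_ACIDS])
    else:
        p = np.ones(20)
    return p / p.sum()


def generate_dataset(spec: SimSpec) -> LabeledDataset:
    """Draw ``n_pos`` positive and ``n_neg`` negative peptides, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    base = _background_probs(spec)
    enriched = base.copy()
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in spec.signal_residues:
            enriched[i] *= spec.enrichment
    enriched /= enriched.sum()

    lo, hi = spec.length_range
    alphabet = np.array(list(AMINO_ACIDS))
    peptides: list[Peptide] = []
    labels: list[int] = []

    def draw(n: int, probs: np.ndarray, prefix: str, positive: bool) -> None:
        for i in range(n):
            L = int(rng.integers(lo, hi + 1))
            residues = rng.choice(alphabet, size=L, p=probs).tolist()
            if positive and spec.terminal_signal is not None:
                residue, end = spec.terminal_signal
                w = min(spec.terminal_window, L)
                offset = int(rng.integers(0, w))
                pos = offset if end == "N" else L - 1 - offset
                residues[pos] = residue
            peptides.append(Peptide(id=f"{prefix}{i + 1:04d}", seq="".join(residues)))
            labels.append(1 if positive else 0)

    draw(spec.n_pos, enriched, "pos", True)
    draw(spec.n_neg, base, "neg", False)
    return LabeledDataset(peptides, np.array(labels, dtype=np.int8))
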