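"""Shared fixtures: default tables, random peptide factories, synthetic index tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from antiangio.alphabets import (
    DEFAULT_REDUCED_ALPHABET,
    AtomicTable,
    IndexTable,
    default_atomic_table,
    default_index_table,
)
from antiangio.seqio import AMINO_ACIDS, Peptide

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def index_table() -> IndexTable:
    return default_index_table()


@pytest.fixture(scope="session")
def atomic_table() -> AtomicTable:
    return default_atomic_table()


@pytest.fixture(scope="session")
def reduced_alphabet():
    return DEFAULT_REDUCED_ALPHABET


def random_peptide(rng: np.random.Generator, length: int, pid: str = "p") -> Peptide:
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return Peptide(id=pid, seq=seq)


def synthetic_index_table(n_indices: int, seed: int = 0) -> IndexTable:
    """A synthetic stand-in index table with random per-residue values."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_indices, 20))
    return IndexTable(
        pd.DataFrame(data, index=[f"syn{i:03d}" for i in range(n_indices)], columns=list(AMINO_ACIDS))
    )
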