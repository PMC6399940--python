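"""The five feature encoders: worked examples, oracles and invariants."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antiangio.alphabets import ATOMS, DEFAULT_REDUCED_ALPHABET, reduce_sequence
from antiangio.encoders import (
    EncoderConfig,
    EncodingError,
    atomic_feature_names,
    encode_all,
    encode_atomic_profile,
    encode_kmer,
    encode_physchem_profile,
    encode_pseaac,
    feature_names,
    kmer_feature_names,
    physchem_feature_names,
    pseaac_feature_names,
)
from antiangio.seqio import AMINO_ACIDS, Peptide

from conftest import random_peptide, synthetic_index_table

peptide_texts = st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=40)


# ---------------------------------------------------------------------------
# independent single-pass PseAAC oracle (plain loops, no numpy vector tricks)

def pseaac_oracle(seq: str, lam: int, w: float, props) -> list[float]:
    aa_order = list(AMINO_ACIDS)
    standardized = []
    for pid in ("hydrophobicity", "hydrophilicity", "side_chain_mass"):
        raw = [props.values_for(pid)[aa] for aa in aa_order]
        mean = sum(raw) / 20
        sd = math.sqrt(sum((x - mean) ** 2 for x in raw) / 20)
        standardized.append({aa: (x - mean) / sd for aa, x in zip(aa_order, raw)})

    def corr_factor(a: str, b: str) -> float:
        return sum((p[b] - p[a]) ** 2 for p in standardized) / len(standardized)

    L = len(seq)
    freqs = [seq.count(aa) / L for aa in aa_order]
    thetas = []
    for k in range(1, lam + 1):
        thetas.append(sum(corr_factor(seq[i], seq[i + k]) for i in range(L - k)) / (L - k))
    denom = 1.0 + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


class TestPseAAC:
    def test_dimension_is_twenty_plus_lambda(self, index_table):
        p = Peptide("p", "ACDEFGHIKLMNPQRSTVWY")
        for lam in (1, 4, 6):
            cfg = EncoderConfig(pseaac_lambda=lam)
            assert len(encode_pseaac(p, cfg, index_table)) == 20 + lam
        assert len(pseaac_feature_names(EncoderConfig())) == 26

    def test_homopolymer_has_zero_order_terms(self, index_table):
        cfg = EncoderConfig(pseaac_lambda=6)
        v = encode_pseaac(Peptide("p", "AAAAAAAA"), cfg, index_table)
        np.testing.assert_allclose(v[20:], 0.0)
        assert v[0] == pytest.approx(1.0)  # A component carries all the weight
        np.testing.assert_allclose(v[1:20], 0.0)

    def test_too_short_peptide_names_minimum_length(self, index_table):
        with pytest.raises(EncodingError, match="minimum 7"):
            encode_pseaac(Peptide("p", "ACDEFG"), EncoderConfig(pseaac_lambda=6), index_table)

    def test_worked_example_matches_oracle(self, index_table):
        cfg = EncoderConfig(pseaac_lambda=2, pseaac_weight=0.05)
        got = encode_pseaac(Peptide("p", "ACDEFGHIK"), cfg, index_table)
        expected = pseaac_oracle("ACDEFGHIK", 2, 0.05, index_table)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_oracle_agreement_on_random_peptides(self, index_table):
        rng = np.random.default_rng(11)
        for i in range(100):
            lam = int(rng.integers(1, 7))
            length = int(rng.integers(lam + 1, 35))
            p = random_peptide(rng, length, f"p{i}")
            cfg = EncoderConfig(pseaac_lambda=lam, pseaac_weight=0.05)
            np.testing.assert_allclose(
                encode_pseaac(p, cfg, index_table),
                pseaac_oracle(p.seq, lam, 0.05, index_table),
                rtol=1e-10,
            )

    @given(seq=peptide_texts)
    def test_components_form_a_distribution(self, seq, index_table):
        v = encode_pseaac(Peptide("p", seq), EncoderConfig(), index_table)
        assert np.all(v >= 0) and np.all(v <= 1)
        assert v.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# k-mer composition

def kmer_oracle(seq: str, k: int, symbols: tuple[str, ...]) -> np.ndarray:
    """Brute-force window slicing + dictionary counting."""
    import itertools
    from collections import Counter

    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    all_words = ["".join(w) for w in itertools.product(symbols, repeat=k)]
    total = max(len(seq) - k + 1, 1)
    return np.array([counts.get(w, 0) / total for w in all_words])


class TestKmer:
    def test_single_window(self):
        v = encode_kmer(Peptide("p", "AA"), 2)
        words = kmer_feature_names(2, AMINO_ACIDS)
        assert v[words.index("k2_AA")] == 1.0
        assert v.sum() == 1.0

    def test_two_window_enumeration(self):
        v = encode_kmer(Peptide("p", "ACA"), 2)
        words = kmer_feature_names(2, AMINO_ACIDS)
        assert v[words.index("k2_AC")] == 0.5
        assert v[words.index("k2_CA")] == 0.5
        assert v.sum() == 1.0

    def test_reduced_alphabet_path(self):
        # ILA reduces to 221: windows 22 and 21
        p = Peptide("p", "ILA")
        assert reduce_sequence(p, DEFAULT_REDUCED_ALPHABET) == "221"
        v = encode_kmer(p, 2, DEFAULT_REDUCED_ALPHABET)
        words = kmer_feature_names(2, DEFAULT_REDUCED_ALPHABET)
        assert v[words.index("rk2_22")] == 0.5
        assert v[words.index("rk2_21")] == 0.5

    def test_peptide_shorter_than_k_gives_zero_vector(self, caplog):
        with caplog.at_level(logging.WARNING):
            v = encode_kmer(Peptide("p", "AC"), 3)
        assert not v.any()
        assert "all-zero" in caplog.text

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for i in range(200):
            p = random_peptide(rng, int(rng.integers(max(k, 5), 40)), f"p{i}")
            np.testing.assert_allclose(
                encode_kmer(p, k), kmer_oracle(p.seq, k, tuple(AMINO_ACIDS))
            )
            reduced = reduce_sequence(p, DEFAULT_REDUCED_ALPHABET)
            np.testing.assert_allclose(
                encode_kmer(p, k, DEFAULT_REDUCED_ALPHABET),
                kmer_oracle(reduced, k, DEFAULT_REDUCED_ALPHABET.class_symbols),
            )

    @given(peptide_texts, st.integers(min_value=1, max_value=4))
    def test_composition_sums_to_one(self, seq, k):
        v = encode_kmer(Peptide("p", seq), k)
        assert np.all(v >= 0)
        assert v.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# terminal profiles

class TestPhyschemProfile:
    def test_homopolymer_repeats_the_residue_column(self, index_table):
        cfg = EncoderConfig()
        v = encode_physchem_profile(Peptide("p", "A" * 10), index_table, cfg)
        a_col = index_table.table["A"].to_numpy()
        for pos in range(10):
            np.testing.assert_allclose(v[pos * len(index_table) : (pos + 1) * len(index_table)], a_col)

    def test_position_layout_c_terminus_first(self, index_table):
        # length-12 peptide: positions 1-5 read residues 8..12, 6-10 read residues 1..5
        seq = "ACDEFGHIKLMN"
        cfg = EncoderConfig()
        v = encode_physchem_profile(Peptide("p", seq), index_table, cfg)
        n = len(index_table)
        expected_residues = list(seq[7:12]) + list(seq[0:5])
        for pos, residue in enumerate(expected_residues):
            np.testing.assert_allclose(
                v[pos * n : (pos + 1) * n], index_table.table[residue].to_numpy()
            )

    def test_width_scales_with_index_count(self):
        syn = synthetic_index_table(191, seed=3)
        cfg = EncoderConfig()
        v = encode_physchem_profile(Peptide("p", "ACDEFGHIKLMN"), syn, cfg)
        assert len(v) == 1910
        assert physchem_feature_names(syn, cfg)[:2] == ["pc_p1_syn000", "pc_p1_syn001"]

    def test_short_peptide_overlapping_windows(self, index_table):
        # L=7: C-terminal window reads residues 3..7, N-terminal reads 1..5
        seq = "ACDEFGH"
        v = encode_physchem_profile(Peptide("p", seq), index_table, EncoderConfig())
        n = len(index_table)
        expected = list(seq[2:7]) + list(seq[0:5])
        for pos, residue in enumerate(expected):
            np.testing.assert_allclose(v[pos * n : (pos + 1) * n], index_table.table[residue].to_numpy())

    def test_very_short_peptide_zero_fills_missing_positions(self, index_table, caplog):
        n = len(index_table)
        with caplog.at_level(logging.WARNING):
            v = encode_physchem_profile(Peptide("p", "ACD"), index_table, EncoderConfig())
        # C-terminal block: positions 1-2 missing (residues -1, 0), then A, C, D
        np.testing.assert_allclose(v[: 2 * n], 0.0)
        np.testing.assert_allclose(v[2 * n : 3 * n], index_table.table["A"].to_numpy())
        # N-terminal block: A C D then two zero positions
        np.testing.assert_allclose(v[8 * n :], 0.0)
        assert "zero-filled" in caplog.text


class TestAtomicProfile:
    def test_glycine_homopolymer_counts(self, atomic_table):
        v = encode_atomic_profile(Peptide("p", "G" * 10), atomic_table, EncoderConfig())
        np.testing.assert_allclose(v, np.tile([2, 5, 1, 2, 0], 10))

    def test_fraction_mode_normalizes_each_position(self, atomic_table):
        cfg = EncoderConfig(atom_mode="fraction")
        v = encode_atomic_profile(Peptide("p", "ACDEFGHIKL"), atomic_table, cfg)
        sums = v.reshape(10, 5).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_counts_match_table_lookup_oracle(self, atomic_table):
        rng = np.random.default_rng(8)
        for i in range(50):
            p = random_peptide(rng, 10, f"p{i}")
            v = encode_atomic_profile(p, atomic_table, EncoderConfig())
            expected_residues = list(p.seq[5:10]) + list(p.seq[0:5])
            expected = np.concatenate(
                [atomic_table.table.loc[r].to_numpy(dtype=float) for r in expected_residues]
            )
            np.testing.assert_allclose(v, expected)

    def test_feature_names_are_position_major(self):
        names = atomic_feature_names(EncoderConfig())
        assert names[:5] == ["at_p1_C", "at_p1_H", "at_p1_N", "at_p1_O", "at_p1_S"]
        assert len(names) == 50


@pytest.fixture(scope="module")
def small_cfg():
    return EncoderConfig(kmer_ks=(2,))


class TestEncodeAll:
    def test_column_schema_and_block_order(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        m = encode_all(
            [Peptide("p1", "ACDEFGHIKLMN")], small_cfg, index_table, atomic_table, reduced_alphabet
        )
        names = list(m.columns)
        n_idx = len(index_table)
        assert names == feature_names(small_cfg, index_table, reduced_alphabet)
        assert len(names) == 26 + 400 + 64 + 10 * n_idx + 50
        # block boundaries
        assert names[0].startswith("pse_")
        assert names[26].startswith("k2_")
        assert names[26 + 400].startswith("rk2_")
        assert names[26 + 400 + 64].startswith("pc_p1_")
        assert names[-1] == "at_p10_S"

    def test_total_width_under_default_config(self, atomic_table, reduced_alphabet):
        # defaults (lambda=6, k=2,3,4, window 5) with a 191-index table
        syn = synthetic_index_table(191, seed=1)
        names = feature_names(EncoderConfig(), syn, reduced_alphabet)
        assert len(names) == 26 + 400 + 8000 + 160000 + 64 + 512 + 4096 + 1910 + 50
        assert len(names) == 175058

    def test_rows_share_one_schema(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        m = encode_all(
            [Peptide("a", "ACDEFGHIKLMN"), Peptide("b", "KKKKRRRRKKRR")],
            small_cfg, index_table, atomic_table, reduced_alphabet,
        )
        assert m.shape[0] == 2
        assert list(m.index) == ["a", "b"]
        assert np.isfinite(m.to_numpy()).all()

    def test_kmer_blocks_sum_to_one_per_row(self, index_table, atomic_table, reduced_alphabet):
        cfg = EncoderConfig(kmer_ks=(2, 3, 4))
        m = encode_all(
            [Peptide("a", "ACDEFGHIKLMNPQ")], cfg, index_table, atomic_table, reduced_alphabet
        )
        for prefix in ("k2_", "k3_", "k4_", "rk2_", "rk3_", "rk4_"):
            block = m.loc[:, [c for c in m.columns if c.startswith(prefix)]]
            assert block.to_numpy().sum() == pytest.approx(1.0), prefix

    def test_interior_substitution_leaves_profiles_unchanged(
        self, index_table, atomic_table, reduced_alphabet, small_cfg
    ):
        # positions 6-7 of a length-12 peptide lie in neither terminal window
        a = Peptide("a", "ACDEFGHIKLMN")
        b = Peptide("a", "ACDEFWHIKLMN")
        ma = encode_all([a], small_cfg, index_table, atomic_table, reduced_alphabet)
        mb = encode_all([b], small_cfg, index_table, atomic_table, reduced_alphabet)
        profile_cols = [c for c in ma.columns if c.startswith(("pc_", "at_"))]
        pd.testing.assert_frame_equal(ma[profile_cols], mb[profile_cols])

    def test_short_peptide_aborts_naming_id(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        with pytest.raises(EncodingError, match="tiny"):
            encode_all(
                [Peptide("ok", "ACDEFGHIKLMN"), Peptide("tiny", "ACD")],
                small_cfg, index_table, atomic_table, reduced_alphabet,
            )

    def test_skip_invalid_drops_short_peptides(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        m = encode_all(
            [Peptide("ok", "ACDEFGHIKLMN"), Peptide("tiny", "ACD")],
            small_cfg, index_table, atomic_table, reduced_alphabet, skip_invalid=True,
        )
        assert list(m.index) == ["ok"]

    def test_duplicate_ids_rejected(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        with pytest.raises(ValueError, match="duplicate"):
            encode_all(
                [Peptide("a", "ACDEFGHIKLMN"), Peptide("a", "ACDEFGHIKLMN")],
                small_cfg, index_table, atomic_table, reduced_alphabet,
            )

    def test_deterministic(self, index_table, atomic_table, reduced_alphabet, small_cfg):
        p = [Peptide("a", "ACDEFGHIKLMN")]
        m1 = encode_all(p, small_cfg, index_table, atomic_table, reduced_alphabet)
        m2 = encode_all(p, small_cfg, index_table, atomic_table, reduced_alphabet)
        pd.testing.assert_frame_equal(m1, m2)
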