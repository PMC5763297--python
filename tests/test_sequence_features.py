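import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gruf.containers import FeatureMatrix
from gruf.sequence_features import (
    AMINO_ACIDS,
    PROTEIN_GROUPS,
    ProteinSequence,
    RnaSequence,
    encode_protein_sequence,
    kmer_frequency,
    pca_reduce,
    protein_kmer_features,
    segmented_kmer_features,
    similarity_from_features,
    zscore_columns,
)

RNA = "ACGU"


def brute_kmer(seq: str, k: int, alphabet: str) -> np.ndarray:
    """Independent sliding-window oracle with explicit lexicographic slots."""
    from itertools import product

    slots = ["".join(p) for p in product(alphabet, repeat=k)]
    counts = np.array([sum(seq[i : i + k] == s for i in range(len(seq) - k + 1))
                       for s in slots], dtype=float)
    return counts / (len(seq) - k + 1)


class TestKmerFrequency:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAAA", 1, [1, 0, 0, 0]),
            ("ACGU", 1, [0.25, 0.25, 0.25, 0.25]),
        ],
    )
    def test_single_letter_compositions(self, seq, k, expected):
        np.testing.assert_allclose(kmer_frequency(seq, k, RNA), expected)

    def test_dimer_counts_match_sliding_window(self):
        got = kmer_frequency("ACGUACG", 2, RNA)
        np.testing.assert_allclose(got, brute_kmer("ACGUACG", 2, RNA), atol=1e-15)
        # AC and CG occur twice among 6 windows
        assert got[1] == pytest.approx(2 / 6)  # AC
        assert got[6] == pytest.approx(2 / 6)  # CG

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError, match="shorter than k"):
            kmer_frequency("AC", 3, RNA)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=3, max_size=60),
        st.integers(min_value=1, max_value=3),
    )
    def test_frequencies_sum_to_one_and_match_oracle(self, seq, k):
        got = kmer_frequency(seq, k, RNA)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(got, brute_kmer(seq, k, RNA), atol=1e-12)


class TestSegmentedKmer:
    def test_standard_lncrna_feature_dimension(self, rng):
        seq = RnaSequence("x", "".join(rng.choice(list(RNA), size=200)))
        assert segmented_kmer_features(seq, k=4, n_segments=35).shape == (8960,)

    def test_single_segment_degenerates_to_plain_kmer(self):
        seq = RnaSequence("x", "ACGUACGUAC")
        np.testing.assert_allclose(
            segmented_kmer_features(seq, 2, 1), kmer_frequency(seq, 2, RNA)
        )

    def test_segment_lengths_and_per_segment_counts(self):
        # length 10, 3 segments -> (4, 3, 3); 1-mer frequencies by hand
        seq = RnaSequence("x", "AACCGGUUAC")
        got = segmented_kmer_features(seq, 1, 3)
        np.testing.assert_allclose(got[:4], [0.5, 0.5, 0, 0])        # AACC
        np.testing.assert_allclose(got[4:8], [0, 0, 2 / 3, 1 / 3])   # GGU
        np.testing.assert_allclose(got[8:], [1 / 3, 1 / 3, 0, 1 / 3])  # UAC

    def test_each_segment_block_sums_to_one(self, rng):
        seq = RnaSequence("x", "".join(rng.choice(list(RNA), size=173)))
        got = segmented_kmer_features(seq, 4, 35).reshape(35, -1)
        np.testing.assert_allclose(got.sum(axis=1), 1.0, atol=1e-12)

    def test_too_short_error_names_sequence(self):
        with pytest.raises(ValueError, match="shorty"):
            segmented_kmer_features(RnaSequence("shorty", "ACGUACGU"), 4, 35)

    def test_dna_style_input_is_normalized(self):
        assert RnaSequence("x", "acgt").residues == "ACGU"
        with pytest.raises(ValueError, match="invalid symbols"):
            RnaSequence("x", "ACGN")


class TestProteinEncoding:
    @pytest.mark.parametrize("seq,encoded", [("AGV", "111"), ("CRKDE", "75566")])
    def test_printed_group_examples(self, seq, encoded):
        assert encode_protein_sequence(seq) == encoded

    def test_groups_partition_the_twenty_amino_acids(self):
        assert sum(len(g) for g in PROTEIN_GROUPS) == 20
        assert len(set("".join(PROTEIN_GROUPS))) == 20
        image = {encode_protein_sequence(aa) for aa in AMINO_ACIDS}
        assert image == set("1234567")

    def test_invalid_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 1"):
            encode_protein_sequence("XAA")
        with pytest.raises(ValueError, match="position 3"):
            ProteinSequence("p", "AABCD")

    def test_triad_features(self):
        f = protein_kmer_features("AAA", 3)
        assert f.shape == (343,)
        assert f[0] == 1.0 and f.sum() == 1.0  # the "111" slot
        # AGVIL -> "11122": 3-mers 111, 112, 122 each once
        f = protein_kmer_features("AGVIL", 3)
        nz = np.nonzero(f)[0]
        np.testing.assert_array_equal(nz, [0, 1, 8])  # base-7 digits 000,001,011
        np.testing.assert_allclose(f[nz], 1 / 3)


class TestZscore:
    def test_hand_zscore_with_sample_std(self):
        fm = zscore_columns(FeatureMatrix(("a", "b"), [[1.0], [3.0]]))
        np.testing.assert_allclose(
            fm.values.ravel(), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_constant_column_maps_to_zero(self):
        fm = zscore_columns(FeatureMatrix(("a", "b", "c"), [[5.0], [5.0], [5.0]]))
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_idempotence(self, rng):
        fm = FeatureMatrix([f"r{i}" for i in range(8)], rng.normal(size=(8, 3)))
        once = zscore_columns(fm)
        twice = zscore_columns(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)
        assert np.abs(once.values.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(once.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_single_row_errors(self):
        with pytest.raises(ValueError, match="at least 2 rows"):
            zscore_columns(FeatureMatrix(("a",), [[1.0, 2.0]]))


class TestPca:
    def test_distances_preserved_when_nothing_dropped(self, rng):
        from scipy.spatial.distance import pdist

        x = rng.normal(size=(10, 4))
        fm = FeatureMatrix([f"r{i}" for i in range(10)], x)
        red = pca_reduce(fm)
        np.testing.assert_allclose(
            pdist(x - x.mean(0)), pdist(red.values), atol=1e-8
        )

    def test_duplicated_column_is_removed(self, rng):
        x = rng.normal(size=(12, 3))
        x = np.column_stack([x, x[:, 0]])
        red = pca_reduce(FeatureMatrix([f"r{i}" for i in range(12)], x))
        assert red.dim <= 3

    def test_rank_two_matrix_keeps_two_components(self, rng):
        basis = rng.normal(size=(2, 6))
        coef = rng.normal(size=(9, 2))
        red = pca_reduce(FeatureMatrix([f"r{i}" for i in range(9)], coef @ basis))
        assert red.dim == 2


class TestSimilarityFromFeatures:
    def test_closed_form_values(self):
        fm = FeatureMatrix(("a", "b", "c"), [[0.0, 0.0], [3.0, 4.0], [0.0, 1.0]])
        s = similarity_from_features(fm)
        assert s.values[0, 1] == pytest.approx(1 / 6)   # dist 5
        assert s.values[0, 2] == pytest.approx(0.5)     # dist 1
        assert s.values[0, 0] == 1.0

    def test_identical_rows_have_similarity_one(self):
        fm = FeatureMatrix(("a", "b"), [[1.0, 2.0], [1.0, 2.0]])
        assert similarity_from_features(fm).values[0, 1] == 1.0

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(30, 5))
        s = similarity_from_features(FeatureMatrix([f"r{i}" for i in range(30)], x))
        oracle = np.empty((30, 30))
        for i in range(30):
            for j in range(30):
                oracle[i, j] = 1.0 / (1.0 + np.linalg.norm(x[i] - x[j]))
        np.testing.assert_allclose(s.values, oracle, atol=1e-12)

    def test_row_permutation_permutes_ids_consistently(self, rng):
        x = rng.normal(size=(7, 3))
        ids = tuple(f"r{i}" for i in range(7))
        s = similarity_from_features(FeatureMatrix(ids, x))
        perm = rng.permutation(7)
        sp = similarity_from_features(
            FeatureMatrix(tuple(ids[i] for i in perm), x[perm])
        )
        np.testing.assert_allclose(sp.values, s.values[np.ix_(perm, perm)], atol=1e-12)
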