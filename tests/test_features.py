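"""TNF, abundance and augmentation: oracles and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcbin.features import (
    abundance_matrix,
    augment_contig,
    build_canonical_index,
    compute_abundance,
    compute_tnf,
    featurize_views,
)
from gcbin.io import ContigRecord, DepthTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


dna = st.text(alphabet="ACGT", min_size=4, max_size=60)


class TestCanonicalIndex:
    def test_136_classes_for_k4(self):
        assert build_canonical_index(4).n_classes == 136

    def test_revcomp_pairs_share_class_exhaustively(self):
        idx = build_canonical_index(4)
        for kmer in map("".join, itertools.product("ACGT", repeat=4)):
            assert idx.class_index(kmer) == idx.class_index(revcomp(kmer))

    def test_k1_two_classes(self):
        idx = build_canonical_index(1)
        assert idx.n_classes == 2
        assert idx.class_index("A") == idx.class_index("T")
        assert idx.class_index("C") == idx.class_index("G")
        assert idx.class_index("A") != idx.class_index("C")

    def test_palindromes_are_singletons(self):
        idx = build_canonical_index(4)
        pals = [
            k
            for k in map("".join, itertools.product("ACGT", repeat=4))
            if k == revcomp(k)
        ]
        assert len(pals) == 16
        # each palindrome's class contains only itself
        classes = {}
        for k in map("".join, itertools.product("ACGT", repeat=4)):
            classes.setdefault(idx.class_index(k), set()).add(k)
        for k in pals:
            assert classes[idx.class_index(k)] == {k}


class TestTnf:
    def test_printed_window_example(self):
        idx = build_canonical_index(4)
        t = compute_tnf("ATGCATG", idx)
        assert t.counts.sum() == 4
        expected = np.zeros(136, dtype=int)
        for w in ["ATGC", "TGCA", "GCAT", "CATG"]:
            expected[idx.class_index(w)] += 1
        np.testing.assert_array_equal(t.counts, expected)

    @settings(max_examples=50, derandomize=True)
    @given(dna)
    def test_strand_invariance_exact(self, seq):
        idx = build_canonical_index(4)
        np.testing.assert_array_equal(
            compute_tnf(seq, idx).counts, compute_tnf(revcomp(seq), idx).counts
        )

    @settings(max_examples=50, derandomize=True)
    @given(dna)
    def test_window_count_conservation_and_prob_sum(self, seq):
        idx = build_canonical_index(4)
        t = compute_tnf(seq, idx)
        assert t.counts.sum() == len(seq) - 3
        assert abs(t.probs.sum() - 1.0) < 1e-9
        assert (t.probs > 0).all()  # smoothing guarantees

    def test_brute_force_dictionary_oracle(self, rng):
        idx = build_canonical_index(4)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            naive = np.zeros(136, dtype=int)
            for i in range(len(seq) - 3):
                naive[idx.class_index(seq[i : i + 4])] += 1
            np.testing.assert_array_equal(compute_tnf(seq, idx).counts, naive)

    def test_poly_a_laplace_worked_value(self):
        idx = build_canonical_index(4)
        t = compute_tnf("A" * 100, idx)
        aaaa = idx.class_index("AAAA")
        assert t.counts[aaaa] == 97
        assert t.probs[aaaa] == pytest.approx(98 / 233, abs=1e-12)
        others = np.delete(t.probs, aaaa)
        np.testing.assert_allclose(others, 1 / 233, atol=1e-12)

    def test_n_windows_skipped_but_count_length(self):
        idx = build_canonical_index(4)
        t = compute_tnf("ACGTNACGT", idx)  # windows overlapping N skipped
        assert t.counts.sum() == 2  # ACGT at both ends only

    def test_too_short_and_all_n_errors(self):
        idx = build_canonical_index(4)
        with pytest.raises(ValueError):
            compute_tnf("ACG", idx)
        with pytest.raises(ValueError):
            compute_tnf("NNNNNNNN", idx)

    def test_freq_smoothing_variant_flattens(self):
        idx = build_canonical_index(4)
        c = compute_tnf("A" * 100, idx, smoothing="counts").probs
        f = compute_tnf("A" * 100, idx, smoothing="freq").probs
        # literal frequency-level smoothing collapses toward uniform
        assert f.max() - f.min() < 0.02 < c.max() - c.min()


def _table():
    return DepthTable(
        ["c1", "c2", "c3"],
        np.array([[10.0, 1.0], [5.0, 4.0], [0.0, 2.0]]),
        np.array([[1.0, 0.2], [0.5, 0.4], [0.0, 0.1]]),
        ["S1", "S2"],
    )


class TestAbundance:
    def test_max_contig_normalizes_to_one(self):
        prof = compute_abundance(_table(), "c1")
        assert prof.vector[0] == pytest.approx(1.0)

    def test_zero_coverage_smoothed_to_epsilon(self):
        prof = compute_abundance(_table(), "c3", epsilon=1e-5)
        assert prof.smoothed_mean[0] == pytest.approx(1e-5)
        assert prof.vector[0] == pytest.approx(1e-5 / (10 + 1e-5))

    def test_vector_is_2m_dimensional(self):
        assert len(compute_abundance(_table(), "c2").vector) == 4

    def test_monotone_in_raw_coverage(self):
        t = _table()
        a = compute_abundance(t, "c1").vector
        b = compute_abundance(t, "c2").vector
        assert a[0] > b[0] and a[1] < b[1]  # order preserved per sample

    def test_all_zero_sample_warns_column_of_ones(self):
        t = DepthTable(
            ["c1", "c2"],
            np.zeros((2, 1)),
            np.zeros((2, 1)),
            ["S1"],
        )
        with pytest.warns(UserWarning):
            m = abundance_matrix(t, ["c1", "c2"])
        np.testing.assert_allclose(m[:, 0], 1.0)

    def test_matrix_matches_single_profiles(self):
        t = _table()
        m = abundance_matrix(t, ["c1", "c3"])
        np.testing.assert_allclose(m[0], compute_abundance(t, "c1").vector)
        np.testing.assert_allclose(m[1], compute_abundance(t, "c3").vector)


class TestAugmentation:
    def test_six_views_default(self, rng):
        c = ContigRecord("c", "ACGT" * 1000)
        vs = augment_contig(c, n_views=5, rng=rng)
        assert len(vs.views) == 6
        assert vs.views[0] == c.sequence

    def test_crops_are_substrings_matching_spans(self, rng):
        c = ContigRecord("c", "".join(rng.choice(list("ACGT"), size=5000)))
        vs = augment_contig(c, n_views=5, rng=rng)
        for view, (s, e) in zip(vs.views, vs.crop_spans):
            assert view == c.sequence[s:e]

    def test_crop_length_bounds(self, rng):
        c = ContigRecord("c", "A" * 4000)
        vs = augment_contig(c, n_views=20, min_frac=0.5, max_frac=0.9, rng=rng)
        for s, e in vs.crop_spans[1:]:
            assert 2000 <= e - s <= 3600

    def test_same_seed_identical(self):
        c = ContigRecord("c", "ACGT" * 500)
        a = augment_contig(c, rng=np.random.default_rng(5))
        b = augment_contig(c, rng=np.random.default_rng(5))
        assert a.crop_spans == b.crop_spans

    def test_short_contig_crops_fall_back_to_self(self, rng):
        c = ContigRecord("c", "ACGTACGTAC")  # 10 bp < 1000 bp floor
        vs = augment_contig(c, n_views=3, rng=rng)
        assert all(v == c.sequence for v in vs.views)


class TestFeaturizeViews:
    def test_dimension_is_136_plus_2m(self, rng):
        t = DepthTable(
            ["c1"], np.ones((1, 4)), np.ones((1, 4)), list("abcd")
        )
        c = ContigRecord("c1", "ACGT" * 600)
        vs = augment_contig(c, n_views=2, rng=rng)
        mat = featurize_views(vs, abundance_matrix(t, ["c1"])[0])
        assert mat.shape == (3, 136 + 8)

    def test_views_share_abundance_differ_in_tnf(self, rng):
        t = _table()
        c = ContigRecord("c1", "".join(rng.choice(list("ACGT"), size=3000)))
        vs = augment_contig(c, n_views=2, rng=rng)
        mat = featurize_views(vs, abundance_matrix(t, ["c1"])[0])
        np.testing.assert_array_equal(mat[0, 136:], mat[1, 136:])
        assert not np.array_equal(mat[0, :136], mat[1, :136])
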