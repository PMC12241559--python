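"""Contact-map pipeline: I/O, balancing, scaling, subtraction, quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svlocus import contacts, simulate
from svlocus.contacts import ContactMatrix
from svlocus.errors import ConfigurationError, ParseError
from svlocus.genome import AlleleSpec, GenomicInterval
from svlocus.simulate import CellStateTopology, SimParams

from conftest import random_symmetric_counts
from test_simulate import toy_landmarks


def make_matrix(values, state="raw", mask=(), bin_size=5_000, **meta):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    region = GenomicInterval("chrT", 1, n * bin_size)
    return ContactMatrix(region=region, bin_size=bin_size,
                         values=np.asarray(values, dtype=float), state=state,
                         mask=frozenset(mask), metadata=meta)


class TestContactMatrixInvariants:
    def test_asymmetric_values_rejected(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ConfigurationError, match="symmetric"):
            make_matrix(vals)

    def test_negative_values_rejected(self):
        vals = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ConfigurationError):
            make_matrix(vals)

    def test_shape_must_match_region(self):
        region = GenomicInterval("chrT", 1, 20_000)
        with pytest.raises(ConfigurationError):
            ContactMatrix(region=region, bin_size=5_000,
                          values=np.zeros((3, 3)))


class TestCooRoundTrip:
    def test_header_only_file_is_zero_matrix(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("#chrom=chrT\n#start=1\n#end=20000\n#bin_size=5000\n")
        M = contacts.read_coo(p)
        assert M.n_bins == 4 and M.values.sum() == 0

    def test_triplet_is_mirrored(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("#chrom=chrT\n#start=1\n#end=30000\n#bin_size=5000\n"
                     "2\t5\t7\n")
        M = contacts.read_coo(p)
        assert M.values[2, 5] == 7 and M.values[5, 2] == 7

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_write_read_identity(self, seed):
        import tempfile
        from pathlib import Path

        rng = np.random.default_rng(seed)
        vals = random_symmetric_counts(rng, 20).astype(float)
        vals[3, 7] = vals[7, 3] = np.pi  # exercise float formatting
        M = make_matrix(vals, allele="toy", population="pos")
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "rt.tsv"
            contacts.write_coo(M, path)
            back = contacts.read_coo(path)
        np.testing.assert_array_equal(back.values, M.values)
        assert back.region.start == M.region.start
        assert back.metadata["allele"] == "toy"

    @pytest.mark.parametrize("body,match", [
        ("9\t1\t2\n", "out of range"),
        ("1\t2\t-3\n", "negative"),
        ("1\t2\t4\n2\t1\t5\n", "duplicate"),
        ("1\t2\n", "3 tab-separated"),
    ])
    def test_malformed_triplets_name_the_line(self, tmp_path, body, match):
        p = tmp_path / "bad.tsv"
        p.write_text("#chrom=chrT\n#start=1\n#end=20000\n#bin_size=5000\n"
                     + body)
        with pytest.raises(ParseError, match=match) as err:
            contacts.read_coo(p)
        assert "line" in str(err.value)

    def test_missing_header_field_rejected(self, tmp_path):
        p = tmp_path / "nohdr.tsv"
        p.write_text("#chrom=chrT\n#start=1\n#end=20000\n")
        with pytest.raises(ParseError, match="bin_size"):
            contacts.read_coo(p)


class TestKRBalance:
    def test_two_by_two_closed_form(self):
        M = make_matrix([[0.0, 4.0], [4.0, 0.0]])
        bal, bias = contacts.kr_balance(M, target=1.0)
        np.testing.assert_allclose(bal.values, [[0.0, 1.0], [1.0, 0.0]],
                                   atol=1e-9)
        assert bias[0] == pytest.approx(bias[1], rel=1e-9)

    def test_doubly_balanced_matrix_has_equal_biases(self):
        vals = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
        # symmetric circulant-like: rows already sum to 3,4,3 -> balance it
        bal, bias = contacts.kr_balance(make_matrix(vals), tol=1e-10)
        rs = bal.values.sum(axis=1)
        assert np.max(np.abs(rs / bal.metadata["kr_target"] - 1)) < 1e-10

    def test_poisson_decay_rows_hit_target_and_rebalance_is_fixed_point(self):
        lm = toy_landmarks(n_bins=50)
        params = SimParams(region=lm.region, total_reads=5e5)
        E = simulate.expected_matrix(AlleleSpec("id"),
                                     CellStateTopology("inactive", []),
                                     params, lm)
        counts = simulate.sample_contact_map(E, seed=11)
        M = ContactMatrix(region=lm.region, bin_size=lm.bin_size,
                          values=counts)
        bal, _ = contacts.kr_balance(M, tol=1e-8)
        keep = bal.unmasked()
        rs = bal.values.sum(axis=1)[keep]
        T = bal.metadata["kr_target"]
        assert np.max(np.abs(rs / T - 1)) < 1e-8
        # rebalancing the balanced values changes nothing appreciably
        M2 = ContactMatrix(region=lm.region, bin_size=lm.bin_size,
                           values=bal.values, mask=bal.mask)
        bal2, _ = contacts.kr_balance(M2, tol=1e-8, target=T)
        nz = bal.values > 0
        assert np.max(np.abs(bal2.values[nz] / bal.values[nz] - 1)) < 1e-6

    def test_zero_coverage_bins_are_masked_and_untouched(self):
        vals = np.array([[0.0, 3.0, 0.0], [3.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        bal, bias = contacts.kr_balance(make_matrix(vals))
        assert 2 in bal.mask
        assert np.all(bal.values[2] == 0) and np.all(bal.values[:, 2] == 0)
        assert np.isnan(bias[2])

    def test_fully_zero_matrix_rejected(self):
        with pytest.raises(ConfigurationError, match="zero"):
            contacts.kr_balance(make_matrix(np.zeros((4, 4))))

    def test_balanced_input_state_rejected(self):
        M = make_matrix([[0.0, 1.0], [1.0, 0.0]], state="balanced")
        with pytest.raises(ConfigurationError, match="raw"):
            contacts.kr_balance(M)


def scaled_pair(valsA, valsB, **kw):
    A = make_matrix(valsA, state="balanced", population="pos", **kw)
    B = make_matrix(valsB, state="balanced", population="neg", **kw)
    return contacts.subdiagonal_scale_pair(A, B)


class TestSubdiagonalScaling:
    def test_hand_computed_three_by_three(self):
        """Offset-1 diagonals [2,2] vs [1,1] both scale to [1.5,1.5]."""
        A = [[0.0, 2.0, 0.0], [2.0, 0.0, 2.0], [0.0, 2.0, 0.0]]
        B = [[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
        sa, sb = scaled_pair(A, B)
        np.testing.assert_allclose(np.diagonal(sa.values, 1), [1.5, 1.5])
        np.testing.assert_allclose(np.diagonal(sb.values, 1), [1.5, 1.5])

    def test_identical_inputs_are_unchanged(self):
        rng = np.random.default_rng(5)
        vals = random_symmetric_counts(rng, 8).astype(float) + 1.0
        vals = (vals + vals.T) / 2
        sa, sb = scaled_pair(vals, vals.copy())
        np.testing.assert_allclose(sa.values, vals, rtol=1e-12)
        np.testing.assert_allclose(sb.values, vals, rtol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_per_diagonal_sums_equalised(self, seed):
        rng = np.random.default_rng(seed)
        a = random_symmetric_counts(rng, 12).astype(float) + 0.5
        b = random_symmetric_counts(rng, 12).astype(float) + 0.5
        a, b = (a + a.T) / 2, (b + b.T) / 2
        sa, sb = scaled_pair(a, b)
        for d in range(12):
            assert np.diagonal(sa.values, d).sum() == pytest.approx(
                np.diagonal(sb.values, d).sum(), abs=1e-9)

    def test_idempotent_on_already_scaled_pair(self):
        rng = np.random.default_rng(6)
        a = random_symmetric_counts(rng, 10).astype(float) + 1.0
        b = random_symmetric_counts(rng, 10).astype(float) + 1.0
        a, b = (a + a.T) / 2, (b + b.T) / 2
        sa, sb = scaled_pair(a, b)
        sa2, sb2 = contacts.subdiagonal_scale_pair(sa, sb)
        np.testing.assert_allclose(sa2.values, sa.values, rtol=1e-12)
        np.testing.assert_allclose(sb2.values, sb.values, rtol=1e-12)

    def test_one_sided_diagonal_scaled_to_average(self, caplog):
        A = [[0.0, 2.0], [2.0, 0.0]]
        B = [[0.0, 0.0], [0.0, 0.0]]
        Bm = make_matrix(B, state="balanced")
        Am = make_matrix(A, state="balanced")
        with caplog.at_level("WARNING"):
            sa, sb = contacts.subdiagonal_scale_pair(Am, Bm)
        assert np.diagonal(sa.values, 1).sum() == pytest.approx(1.0)
        assert np.all(sb.values == 0)
        assert any("only one map" in r.message for r in caplog.records)

    def test_raw_inputs_rejected(self):
        A = make_matrix([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ConfigurationError, match="balanced"):
            contacts.subdiagonal_scale_pair(A, A)


class TestSubtractionMap:
    def _pair(self, seed=7, n=10):
        rng = np.random.default_rng(seed)
        a = random_symmetric_counts(rng, n).astype(float) + 1.0
        b = random_symmetric_counts(rng, n).astype(float) + 1.0
        return scaled_pair((a + a.T) / 2, (b + b.T) / 2)

    def test_self_subtraction_is_zero(self):
        sa, sb = self._pair()
        S = contacts.subtraction_map(sa, sa)
        assert np.all(S.values == 0)

    def test_swapping_inputs_negates_exactly(self):
        sa, sb = self._pair()
        S1 = contacts.subtraction_map(sa, sb)
        S2 = contacts.subtraction_map(sb, sa)
        np.testing.assert_array_equal(S1.values, -S2.values)

    def test_per_diagonal_sums_vanish(self):
        sa, sb = self._pair()
        S = contacts.subtraction_map(sa, sb)
        for d in range(S.n_bins):
            assert abs(np.diagonal(S.values, d).sum()) <= 1e-9

    def test_unscaled_inputs_rejected(self):
        A = make_matrix([[0.0, 1.0], [1.0, 0.0]], state="balanced")
        with pytest.raises(ConfigurationError, match="subdiag_scaled"):
            contacts.subtraction_map(A, A)


class TestTruncatePercentile:
    def test_q100_and_constant_are_identity(self):
        rng = np.random.default_rng(8)
        vals = random_symmetric_counts(rng, 10).astype(float)
        M = make_matrix(vals)
        np.testing.assert_array_equal(
            contacts.truncate_percentile(M, 100.0).values, vals)
        C = make_matrix(np.full((6, 6), 4.0))
        np.testing.assert_array_equal(
            contacts.truncate_percentile(C, 99.0).values, C.values)

    def test_clip_matches_direct_percentile(self):
        rng = np.random.default_rng(9)
        vals = random_symmetric_counts(rng, 15).astype(float)
        M = make_matrix(vals)
        out = contacts.truncate_percentile(M, 99.0)
        iu = np.triu_indices(15)
        cut = np.percentile(vals[iu], 99.0)
        assert out.values.max() == pytest.approx(cut)
        below = vals <= cut
        np.testing.assert_array_equal(out.values[below], vals[below])

    def test_subtraction_map_clipped_by_magnitude_with_sign(self):
        sa, sb = scaled_pair(
            np.full((6, 6), 2.0) + np.eye(6) * 5,
            np.full((6, 6), 2.0))
        S = contacts.subtraction_map(sa, sb)
        out = contacts.truncate_percentile(S, 90.0)
        iu = np.triu_indices(6)
        cut = np.percentile(np.abs(S.values[iu]), 90.0)
        assert np.max(np.abs(out.values)) == pytest.approx(cut)
        assert np.all(np.sign(out.values) == np.sign(S.values))
        assert out.truncation_percentile == 90.0


class TestVirtual4C:
    def test_constant_matrix_gives_flat_profile(self):
        M = make_matrix(np.full((6, 6), 3.0))
        prof = contacts.virtual_4c(M, GenomicInterval("chrT", 1, 5_000))
        np.testing.assert_allclose(prof.values, 3.0)

    def test_single_bin_anchor_returns_its_row(self):
        rng = np.random.default_rng(10)
        vals = random_symmetric_counts(rng, 6).astype(float)
        M = make_matrix(vals)
        anchor = GenomicInterval("chrT", 10_001, 15_000)  # bin 2
        prof = contacts.virtual_4c(M, anchor)
        np.testing.assert_array_equal(prof.values, vals[2])

    def test_two_bin_anchor_is_row_mean(self):
        rng = np.random.default_rng(11)
        vals = random_symmetric_counts(rng, 6).astype(float)
        M = make_matrix(vals)
        anchor = GenomicInterval("chrT", 5_001, 15_000)  # bins 1-2
        prof = contacts.virtual_4c(M, anchor)
        np.testing.assert_allclose(prof.values, vals[1:3].mean(axis=0))

    def test_masked_bins_reported_missing(self):
        vals = np.full((5, 5), 2.0)
        vals[4, :] = 0
        vals[:, 4] = 0
        M = make_matrix(vals, mask=[4])
        prof = contacts.virtual_4c(M, GenomicInterval("chrT", 1, 5_000))
        assert np.isnan(prof.values[4])
        assert not np.any(np.isnan(prof.values[:4]))

    def test_anchor_outside_region_rejected(self):
        M = make_matrix(np.zeros((4, 4)))
        with pytest.raises(ConfigurationError, match="outside"):
            contacts.virtual_4c(M, GenomicInterval("chrT", 50_000, 60_000))


class TestQuantifyPair:
    def test_constant_matrix_returns_constant(self):
        M = make_matrix(np.full((6, 6), 2.5))
        a = GenomicInterval("chrT", 1, 10_000)
        b = GenomicInterval("chrT", 20_001, 30_000)
        assert contacts.quantify_pair(M, a, b) == pytest.approx(2.5)

    def test_symmetric_in_anchors(self):
        rng = np.random.default_rng(12)
        vals = random_symmetric_counts(rng, 8).astype(float)
        M = make_matrix(vals)
        a = GenomicInterval("chrT", 1, 10_000)
        b = GenomicInterval("chrT", 25_001, 40_000)
        assert contacts.quantify_pair(M, a, b) == pytest.approx(
            contacts.quantify_pair(M, b, a))

    def test_fully_masked_rectangle_is_missing(self):
        vals = np.zeros((4, 4))
        M = make_matrix(vals, mask=[0, 1])
        a = GenomicInterval("chrT", 1, 5_000)
        b = GenomicInterval("chrT", 5_001, 10_000)
        assert np.isnan(contacts.quantify_pair(M, a, b))
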