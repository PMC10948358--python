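"""Contact-map container, I/O and preprocessing."""

import numpy as np
import pytest

from tidmap.contact_map import (
    ContactMap,
    correlation_matrix,
    detect_white_lines,
    distance_decay,
    downsample,
    ice_balance,
    log2_ratio,
    read_map,
    rebin,
    write_map,
)
from tests.conftest import random_symmetric_map, toeplitz_map


class TestIO:
    def test_triplet_mirroring(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "#bin_size=1000\n#genome_length=3000\n#circular=false\n"
            "0\t0\t2\n0\t1\t1\n1\t2\t4\n"
        )
        cmap = read_map(str(path))
        expected = np.array([[2, 1, 0], [1, 0, 4], [0, 4, 0]], dtype=float)
        np.testing.assert_array_equal(cmap.matrix, expected)
        assert not cmap.circular

    @pytest.mark.parametrize("fmt", ["triplet", "dense"])
    def test_round_trip(self, tmp_path, fmt):
        cmap = random_symmetric_map(n=12, seed=5)
        cmap = ContactMap(cmap.matrix, 1000, 12_000, circular=True,
                          mask=frozenset({3}), balanced=False)
        path = tmp_path / "rt.tsv"
        write_map(cmap, str(path), format=fmt)
        back = read_map(str(path))
        np.testing.assert_allclose(back.matrix, cmap.matrix)
        assert back.mask == cmap.mask
        assert back.bin_size == cmap.bin_size
        assert back.circular == cmap.circular

    def test_asymmetric_dense_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#bin_size=1000\n#genome_length=2000\n#circular=false\n"
            "0\t1\n5\t0\n"
        )
        with pytest.raises(ValueError, match="asymmetric"):
            read_map(str(path))

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text(
            "#bin_size=1000\n#genome_length=2000\n#circular=true\n"
            "0\t1\t-3\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_map(str(path))


class TestIceBalance:
    def test_two_bin_map_balances_immediately(self):
        cmap = ContactMap(np.array([[0.0, 4.0], [4.0, 0.0]]), 1000, 2000)
        bal = ice_balance(cmap)
        sums = bal.matrix.sum(axis=1)
        assert np.allclose(sums, sums[0])
        assert bal.balanced

    def test_row_sum_cv_below_tolerance(self, small_map):
        bal = ice_balance(small_map, tol=1e-8)
        sums = bal.matrix.sum(axis=1)
        assert sums.std() / sums.mean() < 1e-6

    def test_idempotent_up_to_scale(self, small_map):
        bal = ice_balance(small_map, tol=1e-10)
        again = ice_balance(bal, tol=1e-10)
        ratio = again.matrix[bal.matrix > 0] / bal.matrix[bal.matrix > 0]
        assert np.ptp(ratio) < 1e-6 * ratio.mean()

    def test_symmetry_preserved_and_mask_grows_on_zero_row(self):
        m = random_symmetric_map(n=10, seed=2).matrix
        m[4, :] = 0.0
        m[:, 4] = 0.0
        cmap = ContactMap(m, 1000, 10_000)
        with pytest.warns(UserWarning, match="zero"):
            bal = ice_balance(cmap)
        assert 4 in bal.mask
        np.testing.assert_allclose(bal.matrix, bal.matrix.T)


class TestWhiteLines:
    def test_worked_example(self):
        # median 10, MAD 1, threshold 7: only the 0 is below
        cov = [0, 8, 9, 10, 11, 12, 10, 10]
        assert detect_white_lines(cov) == frozenset({0})

    def test_constant_coverage_empty(self):
        with pytest.warns(UserWarning, match="MAD"):
            assert detect_white_lines([5.0] * 8) == frozenset()

    def test_degenerate_mad(self):
        # MAD 0 degenerates to "< median": threshold 10 flags only the 0
        with pytest.warns(UserWarning, match="MAD"):
            assert detect_white_lines([10, 10, 10, 10, 0]) == frozenset({4})


class TestDownsample:
    def test_exact_total_and_symmetry(self, small_map):
        out = downsample(small_map, 5000, seed=1)
        assert out.total_contacts() == 5000
        np.testing.assert_array_equal(out.matrix, out.matrix.T)

    def test_identity_at_full_depth(self, small_map):
        total = int(small_map.total_contacts())
        out = downsample(small_map, total, seed=1)
        np.testing.assert_array_equal(out.matrix, small_map.matrix)

    def test_deterministic(self, small_map):
        a = downsample(small_map, 4000, seed=7)
        b = downsample(small_map, 4000, seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_exceeding_total_rejected(self, small_map):
        with pytest.raises(ValueError):
            downsample(small_map, 10**9, seed=0)

    def test_expected_proportions(self):
        # mean downsampled entry tracks n * p_entry over repeated draws
        cmap = random_symmetric_map(n=10, seed=3)
        iu = np.triu_indices(10)
        upper = cmap.matrix[iu]
        p_entry = upper / upper.sum()
        n_keep = 500
        draws = np.array(
            [downsample(cmap, n_keep, seed=s).matrix[iu] for s in range(200)]
        )
        mean = draws.mean(axis=0)
        expect = n_keep * p_entry
        se = np.sqrt(n_keep * p_entry * (1 - p_entry) / 200)
        assert np.all(np.abs(mean - expect) <= 3 * np.maximum(se, 1e-9))


class TestLog2Ratio:
    def test_equal_maps_zero(self, small_map):
        assert np.allclose(log2_ratio(small_map, small_map, 1.0), 0.0)

    def test_doubling_gives_one(self):
        a = random_symmetric_map(n=6, seed=4)
        b = ContactMap(a.matrix * 2, 1000, 6000)
        np.testing.assert_allclose(log2_ratio(b, a, 0.0), 1.0)

    def test_scalar_example(self):
        a = ContactMap(np.array([[4.0]]), 1000, 1000)
        b = ContactMap(np.array([[1.0]]), 1000, 1000)
        assert log2_ratio(a, b, 0.0)[0, 0] == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self, small_map):
        other = random_symmetric_map(n=10)
        with pytest.raises(ValueError):
            log2_ratio(small_map, other)

    def test_mask_propagates(self):
        a = random_symmetric_map(n=6, seed=4)
        masked = ContactMap(a.matrix, 1000, 6000, mask=frozenset({2}))
        out = log2_ratio(masked, a, 1.0)
        assert np.all(np.isnan(out[2, :])) and np.all(np.isnan(out[:, 2]))


class TestDistanceDecay:
    def test_linear_three_bin_example(self):
        cmap = ContactMap(np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
                          1000, 3000, circular=False)
        p = distance_decay(cmap)
        np.testing.assert_allclose(p.values, [0.0, 1.0, 2.0])

    def test_circular_uniform(self):
        m = 1.0 - np.eye(4)
        cmap = ContactMap(m, 1000, 4000, circular=True)
        p = distance_decay(cmap)
        assert p.values[1] == pytest.approx(1.0)
        assert p.values[2] == pytest.approx(1.0)

    def test_exact_recovery_of_planted_decay(self, decay_map):
        p = distance_decay(decay_map)
        s = np.arange(len(p.values))
        np.testing.assert_allclose(p.values, (s + 1.0) ** -0.8, rtol=1e-12)

    def test_masked_separation_interpolated(self):
        # mask enough bins that no valid pair remains at the largest
        # separation of a tiny linear genome; the value is interpolated
        m = random_symmetric_map(n=4, seed=0, circular=False).matrix
        cmap = ContactMap(m, 1000, 4000, circular=False, mask=frozenset({0}))
        p = distance_decay(cmap)
        assert np.all(np.isfinite(p.values))


class TestRebin:
    def test_factor_one_identity(self, small_map):
        np.testing.assert_array_equal(rebin(small_map, 1).matrix,
                                      small_map.matrix)

    def test_block_sum(self):
        cmap = ContactMap(np.ones((4, 4)), 1000, 4000)
        out = rebin(cmap, 2)
        np.testing.assert_allclose(out.matrix, 4.0)
        assert out.bin_size == 2000

    def test_total_preserved(self, small_map):
        assert rebin(small_map, 3).matrix.sum() == pytest.approx(
            small_map.matrix.sum()
        )

    def test_mask_majority_rule(self):
        cmap = ContactMap(np.ones((4, 4)), 1000, 4000,
                          mask=frozenset({0, 1, 2}))
        out = rebin(cmap, 2)
        assert out.mask == frozenset({0})  # bins {0,1} fully masked


class TestCorrelationMatrix:
    def test_unit_diagonal_and_range(self, small_map):
        corr = correlation_matrix(ice_balance(small_map))
        assert np.allclose(np.diag(corr), 1.0)
        assert np.nanmax(corr) <= 1.0 + 1e-12
        assert np.nanmin(corr) >= -1.0 - 1e-12

    def test_matches_numpy_corrcoef(self, small_map):
        bal = ice_balance(small_map)
        corr = correlation_matrix(bal)
        ref = np.corrcoef(bal.matrix)
        np.testing.assert_allclose(corr, ref, atol=1e-10)

    def test_checkerboard_blocks(self):
        # two-block plaid: within-block correlation positive, cross negative
        n = 8
        block = np.array([0] * 4 + [1] * 4)
        m = np.where(block[:, None] == block[None, :], 5.0, 1.0)
        m += np.random.default_rng(0).normal(0, 0.01, (n, n))
        m = (m + m.T) / 2
        cmap = ContactMap(m, 1000, 8000, balanced=True)
        corr = correlation_matrix(cmap)
        assert corr[0, 3] > 0 > corr[0, 5]
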