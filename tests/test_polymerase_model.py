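"""Occupancy normalization, model weights, Sinkhorn and epsilon fitting."""

import numpy as np
import pytest

from tidmap.contact_map import ContactMap, DistanceDecay
from tidmap.polymerase_model import (
    compare_variants,
    doubly_stochastic,
    expected_map,
    fit_epsilon,
    model_map,
    model_weights,
    normalize_chip,
    _intervening_sum,
)


def brute_force_weights(c, variant, circular):
    """Literal double-loop evaluation of both model formulas."""
    n = len(c)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if variant == 1:
                m = 1.0
            else:
                lo, hi = min(i, j), max(i, j)
                inner = sum(c[lo + 1 : hi])
                if circular and (n - (hi - lo)) < (hi - lo):
                    m = sum(c) - inner - c[lo] - c[hi]
                else:
                    m = inner
            out[i, j] = (m if variant == 2 else 1.0) * c[i] * c[j] + (
                (1 - c[i]) * (1 - c[j])
            )
    return out


def power_law_decay(n, alpha=0.8, circular=True):
    s_max = n // 2 if circular else n - 1
    s = np.arange(s_max + 1)
    return DistanceDecay(separations=s, values=(s + 1.0) ** -alpha,
                         bin_size=1000)


class TestNormalizeChip:
    def test_linear_scaling(self):
        occ = normalize_chip(np.array([200.0, 100.0, 0.0]), 0.15)
        np.testing.assert_allclose(occ.values, [0.15, 0.075, 0.0])

    def test_already_unit_max(self):
        chip = np.array([0.2, 1.0, 0.5])
        occ = normalize_chip(chip, 1.0)
        np.testing.assert_allclose(occ.values, chip)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            occ = normalize_chip(np.zeros(5), 0.3)
        assert np.all(occ.values == 0)


class TestModelWeights:
    def test_zero_occupancy_collapses_both_variants(self):
        c = np.zeros(10)
        np.testing.assert_allclose(model_weights(c, 1), 1.0)
        np.testing.assert_allclose(model_weights(c, 2), 1.0)

    def test_variant1_opposite_extremes_cancel(self):
        c = np.array([1.0, 0.0])
        assert model_weights(c, 1)[0, 1] == pytest.approx(0.0)

    def test_variant2_worked_example(self):
        # linear 3-bin genome, C = 0.5 everywhere:
        # pair (0,2): m = 0.5 -> 0.5*0.25 + 0.25; pair (0,1): m = 0 -> 0.25
        w = model_weights(np.array([0.5, 0.5, 0.5]), 2, circular=False)
        assert w[0, 2] == pytest.approx(0.375)
        assert w[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize("variant", [1, 2])
    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_double_loop(self, variant, circular):
        rng = np.random.default_rng(42)
        for _ in range(5):
            c = rng.uniform(0, 0.4, size=30)
            got = model_weights(c, variant, circular)
            want = brute_force_weights(c, variant, circular)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_intervening_sum_symmetric_zero_diagonal(self):
        c = np.random.default_rng(0).uniform(0, 1, 15)
        m = _intervening_sum(c, circular=True)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-15)


class TestDoublyStochastic:
    def test_two_by_two_example(self):
        out = doubly_stochastic(np.array([[1.0, 3.0], [3.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.25, 0.75], [0.75, 0.25]],
                                   atol=1e-10)

    def test_permutation_matrix_unchanged(self):
        p = np.eye(5)[[2, 0, 4, 1, 3]]
        p = (p + p.T) / 2  # symmetrize support
        out = doubly_stochastic(np.eye(4))
        np.testing.assert_allclose(out, np.eye(4))

    def test_row_and_column_sums(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = rng.uniform(0.1, 2.0, size=(30, 30))
            m = (m + m.T) / 2
            out = doubly_stochastic(m)
            np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-8)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)

    def test_zero_row_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ValueError):
            doubly_stochastic(m)


class TestModelMap:
    def test_zero_occupancy_gives_normalized_toeplitz(self):
        p = power_law_decay(40)
        with pytest.warns(UserWarning, match="all-zero"):
            occ = normalize_chip(np.zeros(40), 0.15)
        mm = model_map(p, occ, variant=2)
        # entries depend only on separation
        d = mm.separation_matrix()
        for s in (1, 5, 10):
            vals = mm.matrix[d == s]
            assert np.ptp(vals) < 1e-9 * vals.mean()

    def test_output_doubly_stochastic_and_symmetric(self):
        p = power_law_decay(30)
        rng = np.random.default_rng(1)
        occ = normalize_chip(rng.uniform(0, 1, 30), 0.3)
        mm = model_map(p, occ, variant=2)
        np.testing.assert_allclose(mm.matrix, mm.matrix.T, atol=1e-12)
        np.testing.assert_allclose(mm.matrix.sum(axis=1), 1.0, atol=1e-7)


class TestFitEpsilon:
    def _observed(self, n, eps_true, variant=2, depth_scale=None):
        """Raw 'counts' equal to the expected map (noise-free oracle)."""
        p = power_law_decay(n)
        chip = np.zeros(n)
        chip[n // 3 : n // 3 + 30] = np.exp(-np.arange(30) / 10.0)
        occ = normalize_chip(chip, eps_true)
        e = expected_map(p, occ.values, variant)
        return ContactMap(e * 1e4, 1000, n * 1000, balanced=False), chip, p

    def test_noiseless_likelihood_recovery(self):
        obs, chip, p = self._observed(150, 0.20)
        grid = np.round(np.arange(0.05, 0.51, 0.01), 2)
        fit = fit_epsilon(obs, chip, p, variant=2, grid=grid)
        assert fit.best_epsilon == pytest.approx(0.20)

    def test_noiseless_spearman_recovery(self):
        obs, chip, p = self._observed(150, 0.20)
        bal = ContactMap(doubly_stochastic(obs.matrix), 1000, 150_000,
                         balanced=True)
        grid = np.round(np.arange(0.10, 0.31, 0.05), 2)
        fit = fit_epsilon(bal, chip, p, variant=2, grid=grid,
                          objective="spearman")
        assert fit.best_epsilon == pytest.approx(0.20)
        assert fit.best_spearman == pytest.approx(1.0, abs=1e-9)
        assert fit.best_spearman == np.nanmax(fit.spearman_per_epsilon)

    def test_singleton_grid(self):
        obs, chip, p = self._observed(100, 0.20)
        fit = fit_epsilon(obs, chip, p, variant=1, grid=[0.4])
        assert fit.best_epsilon == 0.4

    def test_invalid_grid_rejected(self):
        obs, chip, p = self._observed(100, 0.20)
        with pytest.raises(ValueError):
            fit_epsilon(obs, chip, p, variant=2, grid=[0.0, 0.5])

    def test_zero_chip_ties_variants(self):
        p = power_law_decay(80)
        rng = np.random.default_rng(0)
        e = expected_map(p, np.zeros(80), 1)
        counts = rng.poisson(e * 2000).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        obs = ContactMap(counts, 1000, 80_000)
        fits = compare_variants(obs, np.zeros(80), p, grid=[0.1, 0.3])
        assert fits[1].log_likelihood == pytest.approx(fits[2].log_likelihood)

    def test_variant_recovery_under_own_model(self):
        # data simulated under each variant prefers that variant
        n = 300
        p = power_law_decay(n)
        chip = np.zeros(n)
        chip[100:200] = np.exp(-np.arange(100) / 40.0)
        rng = np.random.default_rng(11)
        grid = np.round(np.arange(0.05, 0.61, 0.01), 2)
        for truth in (1, 2):
            occ = normalize_chip(chip, 0.35)
            e = expected_map(p, occ.values, truth)
            e *= 2_000_000 / np.triu(e).sum()
            counts = rng.poisson(np.triu(e)).astype(float)
            counts = counts + np.triu(counts, 1).T
            obs = ContactMap(counts, 1000, n * 1000)
            fits = compare_variants(obs, chip, p, grid=grid)
            winner = max(fits, key=lambda v: fits[v].log_likelihood)
            assert winner == truth
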