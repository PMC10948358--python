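"""Gene selection, window extraction, pileups and their controls."""

import numpy as np
import pytest

from tidmap.contact_map import ContactMap
from tidmap.pileup import (
    Gene,
    diagonal_profile,
    extract_window,
    pileup_at_anchors,
    pileup_ratio,
    pileup_track,
    pileup_transcription_correlation,
    pileup_windows,
    select_active_genes,
    select_tu_starts,
)
from tests.conftest import toeplitz_map


def make_genes(rpkms, length=2000, gap=1000):
    genes = []
    pos = 0
    for k, r in enumerate(rpkms):
        genes.append(Gene(id=f"g{k}", start=pos, end=pos + length,
                          strand="+", expression=float(r)))
        pos += length + gap
    return genes


class TestGeneSelection:
    def test_top_fraction(self):
        genes = make_genes([1, 9, 2, 8, 3, 7, 4, 6, 5, 0])
        top = select_active_genes(genes, 0.2)
        assert sorted(g.expression for g in top) == [8, 9]

    def test_fraction_one_keeps_all(self):
        genes = make_genes([1, 2, 3])
        assert len(select_active_genes(genes, 1.0)) == 3

    def test_ties_broken_by_genomic_order(self):
        genes = make_genes([5, 5, 5, 5, 5])
        top = select_active_genes(genes, 0.4)  # ceil(2.0) = 2
        assert [g.id for g in top] == ["g0", "g1"]

    def test_output_sorted_by_position(self):
        genes = make_genes([1, 9, 2, 8])
        top = select_active_genes(genes, 0.5)
        starts = [g.start for g in top]
        assert starts == sorted(starts)


class TestTuStarts:
    def test_upstream_active_gene_disqualifies(self):
        g1 = Gene("g1", 5000, 8000, "+", 10.0)
        g2 = Gene("g2", 8500, 9500, "+", 10.0)
        kept = select_tu_starts([g1, g2], genome_length=50_000)
        assert [g.id for g in kept] == ["g1"]

    def test_single_gene_kept(self):
        g = Gene("g", 1000, 4000, "+", 5.0)
        assert select_tu_starts([g], genome_length=50_000) == [g]

    def test_reverse_strand_upstream_is_after_end(self):
        # g2 is reverse: its upstream is [9500, 12500), which contains g3
        g2 = Gene("g2", 8500, 9500, "-", 10.0)
        g3 = Gene("g3", 10_000, 11_000, "+", 10.0)
        kept = select_tu_starts([g2, g3], genome_length=50_000)
        assert "g2" not in [g.id for g in kept]

    def test_subset_of_active(self):
        genes = make_genes(np.arange(20), length=1500, gap=500)
        active = select_active_genes(genes, 0.5)
        kept = select_tu_starts(active, genome_length=60_000)
        assert set(g.id for g in kept) <= set(g.id for g in active)


class TestExtractWindow:
    def test_forward_strand_unmodified(self, decay_map):
        win, _ = extract_window(decay_map, 50_000, "+", 10_000)
        center = 50
        idx = np.arange(center - 5, center + 5)
        np.testing.assert_array_equal(win,
                                      decay_map.matrix[np.ix_(idx, idx)])

    def test_double_flip_identity(self, decay_map):
        fwd, _ = extract_window(decay_map, 50_000, "+", 10_000)
        rev, _ = extract_window(decay_map, 50_000, "-", 10_000)
        np.testing.assert_array_equal(rev[::-1, ::-1], fwd)

    def test_flip_moves_downstream_marker_upstream(self):
        n = 40
        m = np.zeros((n, n))
        m[25, 26] = m[26, 25] = 9.0  # marker downstream of bin 20
        cmap = ContactMap(m, 1000, n * 1000, balanced=True)
        rev, _ = extract_window(cmap, 20_000, "-", 20_000)
        w = rev.shape[0]
        fwd, _ = extract_window(cmap, 20_000, "+", 20_000)
        i, j = np.unravel_index(np.argmax(fwd), fwd.shape)
        ri, rj = np.unravel_index(np.argmax(rev), rev.shape)
        assert {ri, rj} == {w - 1 - i, w - 1 - j}
        assert max(i, j) > w // 2 > min(ri, rj)

    def test_linear_edge_window_excluded(self):
        cmap = ContactMap(np.ones((20, 20)), 1000, 20_000, circular=False)
        assert extract_window(cmap, 1000, "+", 10_000) is None

    def test_width_must_be_bin_multiple(self, decay_map):
        with pytest.raises(ValueError):
            extract_window(decay_map, 50_000, "+", 1500)


class TestPileup:
    def test_single_window_identity(self):
        w = np.arange(9.0).reshape(3, 3)
        pile = pileup_windows([(w, np.zeros_like(w, dtype=bool))])
        np.testing.assert_array_equal(pile.matrix, w)

    def test_two_scalar_windows_average(self):
        a = (np.array([[2.0]]), np.array([[False]]))
        b = (np.array([[4.0]]), np.array([[False]]))
        assert pileup_windows([a, b]).matrix[0, 0] == 3.0

    def test_masked_cell_uses_other_window(self):
        a = (np.array([[2.0]]), np.array([[True]]))
        b = (np.array([[4.0]]), np.array([[False]]))
        pile = pileup_windows([a, b])
        assert pile.matrix[0, 0] == 4.0
        assert pile.counts[0, 0] == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pileup_windows([])

    def test_k_copies_equal_window(self, decay_map):
        win = extract_window(decay_map, 30_000, "+", 10_000)
        pile = pileup_windows([win] * 5)
        np.testing.assert_allclose(pile.matrix, win[0])

    def test_converges_to_toeplitz_on_pure_decay_map(self):
        # law of large numbers: pileup of many random anchors ~ p(s) window
        cmap = toeplitz_map(n=400, alpha=0.8)
        rng = np.random.default_rng(0)
        anchors = rng.integers(0, 400_000, size=600)
        pile = pileup_at_anchors(cmap, list(anchors), ["+"] * 600, 20_000)
        w = pile.matrix.shape[0]
        d = np.abs(np.arange(w)[:, None] - np.arange(w)[None, :])
        expected = (d + 1.0) ** -0.8
        for offset in range(w):
            got = np.diagonal(pile.matrix, offset)
            want = np.diagonal(expected, offset)
            assert np.all(np.abs(got - want) / want < 0.05)


class TestPileupRatio:
    def test_zero_jitter_gives_ones(self, decay_map):
        anchors = [20_000, 50_000, 80_000]
        strands = ["+", "+", "+"]
        pile = pileup_at_anchors(decay_map, anchors, strands, 10_000)
        ratio = pileup_ratio(pile, decay_map, anchors, strands, 10_000,
                             jitter_bp=0, seed=3)
        np.testing.assert_allclose(ratio, 1.0)

    def test_deterministic_given_seed(self, decay_map):
        anchors = [20_000, 50_000]
        pile = pileup_at_anchors(decay_map, anchors, ["+", "+"], 10_000)
        r1 = pileup_ratio(pile, decay_map, anchors, ["+", "+"], 10_000, seed=9)
        r2 = pileup_ratio(pile, decay_map, anchors, ["+", "+"], 10_000, seed=9)
        np.testing.assert_array_equal(r1, r2)


class TestPileupTrack:
    def test_single_track(self):
        np.testing.assert_array_equal(pileup_track([np.array([1.0, 2, 3])],
                                                   ["+"]), [1, 2, 3])

    def test_reverse_strand_reversed(self):
        out = pileup_track([np.array([0.0, 1, 2]), np.array([2.0, 1, 0])],
                           ["+", "-"])
        np.testing.assert_array_equal(out, [0, 1, 2])

    def test_constant_tracks(self):
        out = pileup_track([np.full(4, 2.0), np.full(4, 4.0)], ["+", "-"])
        np.testing.assert_array_equal(out, np.full(4, 3.0))


class TestTranscriptionCorrelation:
    def _pile(self, profile):
        w = len(profile) + 1
        m = np.zeros((w, w))
        for k, v in enumerate(profile):
            m[k, k + 1] = m[k + 1, k] = v
        from tidmap.pileup import Pileup
        return Pileup(matrix=m, n_windows=1, counts=np.ones((w, w), dtype=int))

    def test_identical_profile_r_one(self):
        prof = np.array([1.0, 3, 2, 5, 4])
        pile = self._pile(prof)
        assert pileup_transcription_correlation(pile, prof) == pytest.approx(1.0)

    def test_antiproportional_r_minus_one(self):
        prof = np.array([1.0, 3, 2, 5, 4])
        pile = self._pile(prof)
        r = pileup_transcription_correlation(pile, -2.0 * prof + 7)
        assert r == pytest.approx(-1.0)

    def test_constant_profile_undefined(self):
        pile = self._pile(np.full(5, 2.0))
        assert np.isnan(pileup_transcription_correlation(pile,
                                                         np.arange(5.0)))

    def test_diagonal_profile_extraction(self):
        pile = self._pile(np.array([4.0, 5, 6]))
        np.testing.assert_array_equal(diagonal_profile(pile), [4, 5, 6])
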