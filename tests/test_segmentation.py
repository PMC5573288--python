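"""Segmentation, source matching, Dice scoring and the signed-rank test."""

import itertools

import numpy as np
import pytest

import spanmf as sp
from tests.conftest import dice_against_truth


class TestSegmentAbundances:
    def test_one_hot_columns_label_by_argmax(self, rng):
        labels_true = rng.integers(0, 3, size=30)
        H = np.zeros((3, 30))
        H[labels_true, np.arange(30)] = 1.0
        seg = sp.segment_abundances(H)
        np.testing.assert_array_equal(seg.labels, labels_true + 1)

    def test_two_voxel_example(self):
        H = np.array([[0.9, 0.1], [0.1, 0.9]])
        seg = sp.segment_abundances(H)
        np.testing.assert_array_equal(seg.labels, [1, 2])

    def test_sharp_phantom_abundances_track_truth(self):
        ph = sp.make_phantom(sp.PhantomConfig(grid_shape=(24, 24), seed=9,
                                              mixing_sharpness=40.0))
        seg = sp.segment_abundances(ph.H_true)
        # interior voxels: boundary voxels are genuine two-tissue mixtures
        # whose dominant tissue can differ from the region label
        grid = (ph.label_map_true.labels - 1).reshape(24, 24)
        interior = np.ones_like(grid, bool)
        interior[:-1] &= grid[:-1] == grid[1:]
        interior[1:] &= grid[1:] == grid[:-1]
        interior[:, :-1] &= grid[:, :-1] == grid[:, 1:]
        interior[:, 1:] &= grid[:, 1:] == grid[:, :-1]
        mask = interior.ravel()
        acc = np.mean(seg.labels[mask] == ph.label_map_true.labels[mask])
        assert acc >= 0.99

    def test_zero_columns_left_unassigned(self):
        H = np.array([[1.0, 0.0, 0.2], [0.0, 0.0, 0.8]])
        seg = sp.segment_abundances(H)
        assert seg.labels[1] == 0
        assert set(seg.labels[[0, 2]]) <= {1, 2}

    def test_single_source_rejected(self):
        with pytest.raises(ValueError):
            sp.segment_abundances(np.ones((1, 5)))


class TestMatchSources:
    def test_identity(self, rng):
        W = rng.uniform(size=(6, 4))
        np.testing.assert_array_equal(sp.match_sources(W, W), np.arange(4))

    def test_recovers_swap(self, rng):
        W = rng.uniform(size=(6, 3))
        perm = sp.match_sources(W[:, [1, 0, 2]], W)
        np.testing.assert_array_equal(perm, [1, 0, 2])

    def test_scale_invariant_permutation_vs_brute_force(self, rng):
        W = rng.uniform(size=(7, 4))
        true_perm = np.array([2, 0, 3, 1])
        W_est = W[:, true_perm] * rng.uniform(0.5, 3.0, size=4)
        got = sp.match_sources(W_est, W)
        np.testing.assert_array_equal(got, true_perm)
        # brute force over all 4! assignments maximizing summed cosine
        Wn = W / np.linalg.norm(W, axis=0)
        En = W_est / np.linalg.norm(W_est, axis=0)
        C = En.T @ Wn
        best = max(itertools.permutations(range(4)),
                   key=lambda p: sum(C[k, p[k]] for k in range(4)))
        np.testing.assert_array_equal(got, best)


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros(10, bool); m[2:5] = True
        assert sp.dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros(10, bool); a[:3] = True
        b = np.zeros(10, bool); b[5:] = True
        assert sp.dice(a, b) == 0.0

    def test_hand_arithmetic(self):
        a = np.zeros(20, bool); a[:6] = True        # |A| = 6
        b = np.zeros(20, bool); b[3:7] = True       # |B| = 4, overlap 3
        assert sp.dice(a, b) == pytest.approx(0.6)

    def test_symmetry_and_empty_conventions(self, rng):
        a = rng.uniform(size=50) > 0.5
        b = rng.uniform(size=50) > 0.5
        assert sp.dice(a, b) == sp.dice(b, a)
        empty = np.zeros(50, bool)
        assert sp.dice(empty, empty) == 1.0
        assert sp.dice(a, empty) == 0.0


class TestTissueClassMasks:
    def _label_map(self, labels):
        return sp.LabelMap(labels=np.asarray(labels),
                           class_of_source={1: "normal", 2: "edema",
                                            3: "active", 4: "necrosis"})

    def test_all_normal_gives_empty_masks(self):
        masks = sp.tissue_class_masks(self._label_map([1, 1, 1]))
        assert all(m.sum() == 0 for m in masks.values())

    def test_counts_and_nesting(self):
        labels = [3] * 10 + [4] * 5 + [2] * 20 + [1] * 7
        masks = sp.tissue_class_masks(self._label_map(labels))
        assert masks["active"].sum() == 10
        assert masks["core"].sum() == 15
        assert masks["whole"].sum() == 35
        assert np.all(masks["core"] | masks["active"] == masks["core"])
        assert np.all(masks["whole"] | masks["core"] == masks["whole"])

    def test_unmapped_label_raises(self):
        lm = sp.LabelMap(labels=np.array([1, 5]),
                         class_of_source={1: "normal"})
        with pytest.raises(ValueError):
            sp.tissue_class_masks(lm)


def wilcoxon_brute_force(a, b) -> tuple[float, float]:
    """Oracle: enumerate all 2^n sign patterns of the nonzero differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(rk for rk, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return w_obs, count / 2**n


class TestWilcoxon:
    def test_all_positive_five_pairs(self):
        w, p = sp.wilcoxon_one_tailed([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert w == 15.0
        assert p == pytest.approx(1 / 32)

    def test_equal_inputs_give_p_one(self):
        w, p = sp.wilcoxon_one_tailed([0.5] * 6, [0.5] * 6)
        assert p == 1.0

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for trial in range(5):
            a = rng.normal(size=n) + 0.3
            b = rng.normal(size=n)
            if trial % 2:  # inject ties among |differences|
                a = np.round(a, 1)
                b = np.round(b, 1)
            w, p = sp.wilcoxon_one_tailed(a, b)
            w_ref, p_ref = wilcoxon_brute_force(a, b)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_complementary_tail_by_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        _, p_ab = sp.wilcoxon_one_tailed(a, b)
        _, p_ref = wilcoxon_brute_force(a, b)
        assert p_ab == pytest.approx(p_ref)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sp.wilcoxon_one_tailed([1, 2], [0, 1])


class TestEndToEnd:
    def test_spa_ahals_pipeline_recovers_segmentation(self):
        ph = sp.make_phantom(sp.PhantomConfig(seed=42, snr_db=30))
        fac = sp.solve(ph.X, 4, "ahals", "spa")
        d = dice_against_truth(fac.H, fac.W, ph)
        assert d["whole"] >= 0.90
        assert d["core"] >= 0.85
        assert d["active"] >= 0.85

    def test_segmentation_reproducible_with_deterministic_inputs(self):
        ph = sp.make_phantom(sp.PhantomConfig(grid_shape=(24, 24), seed=2, snr_db=30))
        fac = sp.solve(ph.X, 4, "ahals", "spa")
        a = sp.segment_abundances(fac.H)
        b = sp.segment_abundances(fac.H)
        np.testing.assert_array_equal(a.labels, b.labels)
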