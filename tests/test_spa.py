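"""SPA column selection and the initializations derived from it."""

import itertools

import numpy as np
import pytest

import spanmf as sp
from spanmf.spa import RankDeficiencyError


def brute_force_spa(X: np.ndarray, r: int) -> list[int]:
    """Independent oracle: literal projection arithmetic with explicit
    orthogonal projector matrices instead of the rank-one update."""
    S = X.astype(float).copy()
    picked = []
    for _ in range(r):
        norms = np.sum(S * S, axis=0)
        i = int(np.argmax(norms))
        picked.append(i)
        s = S[:, i]
        P = np.eye(X.shape[0]) - np.outer(s, s) / (s @ s)
        S = P @ S
    return picked


class TestSpaSelectColumns:
    def test_worked_two_source_example_with_tie(self):
        # norms {1, 1, 0.5}: tie between columns 0 and 1 -> smallest index 0;
        # after projecting out (1,0) the residual norms are {1, 0.25} -> 1
        X = np.array([[1, 0, 0.5], [0, 1, 0.5]], float)
        sel = sp.spa_select_columns(X, 2)
        assert sel.indices == [0, 1]
        assert sel.projected_norms == [1.0, 1.0]
        np.testing.assert_array_equal(sel.vectors, X[:, [0, 1]])

    def test_dominant_column_first(self):
        X = np.array([[2, 0, 1], [0, 1, 0.5]], float)
        sel = sp.spa_select_columns(X, 2)
        assert sel.indices == [0, 1]
        assert sel.projected_norms[0] == pytest.approx(4.0)
        assert sel.projected_norms[1] == pytest.approx(1.0)

    def test_r_equal_one_is_argmax_norm(self, rng):
        X = rng.uniform(size=(5, 12))
        sel = sp.spa_select_columns(X, 1)
        assert sel.indices == [int(np.argmax(np.sum(X * X, axis=0)))]

    @pytest.mark.parametrize("shape,r", [((4, 9), 3), ((6, 15), 4), ((3, 7), 2)])
    def test_matches_projector_matrix_oracle(self, rng, shape, r):
        X = rng.uniform(size=shape)
        assert sp.spa_select_columns(X, r).indices == brute_force_spa(X, r)

    def test_projected_norms_non_increasing_and_vectors_unprojected(self, rng):
        X = rng.uniform(size=(8, 30))
        sel = sp.spa_select_columns(X, 5)
        assert all(a >= b - 1e-12 for a, b in
                   zip(sel.projected_norms, sel.projected_norms[1:]))
        for j, idx in enumerate(sel.indices):
            np.testing.assert_array_equal(sel.vectors[:, j], X[:, idx])

    def test_deterministic(self, rng):
        X = rng.uniform(size=(6, 40))
        a = sp.spa_select_columns(X, 4)
        b = sp.spa_select_columns(X, 4)
        assert a.indices == b.indices
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_rank_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            sp.spa_select_columns(np.ones((2, 5)), 3)

    def test_rank_deficient_data_raises_naming_step(self):
        # rank-1 data cannot supply a second direction
        X = np.outer(np.arange(1.0, 4.0), np.arange(1.0, 6.0))
        with pytest.raises(RankDeficiencyError, match="step 1"):
            sp.spa_select_columns(X, 2)

    def test_recovers_pure_pixels_on_separable_phantom(self, small_phantom):
        ph = small_phantom
        sel = sp.spa_select_columns(ph.X, 4)
        all_pure = set(itertools.chain.from_iterable(ph.pure_indices.values()))
        assert set(sel.indices) <= all_pure
        # one pick per source
        src_of = {i: k for k, idxs in ph.pure_indices.items() for i in idxs}
        assert sorted(src_of[i] for i in sel.indices) == [0, 1, 2, 3]

    def test_projection_orthogonality_invariant(self, rng):
        # re-run the recursion, checking S stays orthogonal to selected dirs
        X = rng.uniform(size=(7, 25))
        S = X.copy()
        kept = []
        for _ in range(4):
            norms = np.sum(S * S, axis=0)
            i = int(np.argmax(norms))
            s = S[:, i].copy()
            kept.append(s / np.linalg.norm(s))
            S -= np.outer(s / norms[i], s @ S)
            for u in kept:
                assert np.max(np.abs(u @ S)) < 1e-8 * np.linalg.norm(X)


class TestNnlsAbundances:
    def test_identity_basis_returns_data(self, rng):
        X = rng.uniform(size=(4, 6))
        np.testing.assert_allclose(sp.nnls_abundances(X, np.eye(4)), X, atol=1e-12)

    def test_exact_column_gives_unit_vector(self, rng):
        W = rng.uniform(size=(5, 3))
        X = W[:, [1]]
        H = sp.nnls_abundances(X, W)
        np.testing.assert_allclose(H[:, 0], [0, 1, 0], atol=1e-10)

    def test_at_least_as_good_as_generating_abundances(self, rng):
        W = rng.uniform(size=(5, 3))
        Hstar = rng.uniform(size=(3, 8))
        X = W @ Hstar
        H = sp.nnls_abundances(X, W)
        assert (np.linalg.norm(X - W @ H)
                <= np.linalg.norm(X - W @ Hstar) + 1e-8)

    def test_zero_basis_column_raises(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            sp.nnls_abundances(np.ones((2, 3)), W)


class TestInitFromSpa:
    def test_worked_example(self):
        X = np.array([[1, 0, 0.5], [0, 1, 0.5]], float)
        init = sp.init_from_spa(X, 2)
        np.testing.assert_array_equal(init.W0, np.eye(2))
        np.testing.assert_allclose(init.H0, X, atol=1e-10)
        assert init.method == "spa"

    def test_exact_on_noiseless_separable_phantom(self, small_phantom):
        ph = small_phantom
        init = sp.init_from_spa(ph.X, 4)
        rel = (np.linalg.norm(ph.X.data - init.W0 @ init.H0)
               / np.linalg.norm(ph.X.data))
        assert rel < 1e-8

    def test_full_rank_square_basis_reconstructs(self, rng):
        # m pure coordinate-direction columns + mixtures, r = m
        m = 3
        coords = 2.0 * np.eye(m)
        mix = rng.uniform(0.1, 0.5, size=(m, 4))
        X = np.hstack([coords, mix])
        init = sp.init_from_spa(X, m)
        assert np.linalg.norm(X - init.W0 @ init.H0) < 1e-10 * np.linalg.norm(X)


class TestConvexWeightsInit:
    def test_identity_example(self):
        A0 = sp.convex_weights_init(np.eye(2))
        np.testing.assert_allclose(A0, [[1.2, 0.2], [0.2, 1.2]])

    def test_nonnegative_solution_gets_mean_offset(self):
        # orthogonal rows make the unconstrained solve already non-negative,
        # so the positive part is the identity map and only the offset acts
        H0 = np.array([[2.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 3.0]])
        A = np.linalg.solve(H0 @ H0.T, H0).T
        assert np.all(A >= 0)  # precondition of this example
        mean_nz = A[A > 0].mean()
        A0 = sp.convex_weights_init(H0)
        np.testing.assert_allclose(A0, A + 0.2 * mean_nz)

    def test_negative_entries_zeroed_and_floor_holds(self):
        H0 = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        # independent oracle for the unconstrained solve
        A_ref = (np.linalg.inv(H0 @ H0.T) @ H0).T
        A_pos = np.maximum(A_ref, 0.0)
        mean_nz = np.abs(A_pos).sum() / np.count_nonzero(A_pos)
        A0 = sp.convex_weights_init(H0)
        np.testing.assert_allclose(A0, A_pos + 0.2 * mean_nz)
        assert np.all(A0 >= 0.2 * mean_nz - 1e-12)

    def test_singular_gram_raises(self):
        H0 = np.array([[1.0, 2.0], [2.0, 4.0]])  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            sp.convex_weights_init(H0)
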