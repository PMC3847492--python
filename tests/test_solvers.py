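import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import poolfreq as pf
from poolfreq.solvers import (
    SolverConfig,
    make_projector,
    project_ball,
    shrink,
    solve,
    solve_missing,
    solve_noisy,
)

from conftest import make_row_sparse_instance
from reference import best_sparse_fit, oracle_exact


class TestShrink:
    def test_hand_example(self):
        np.testing.assert_allclose(shrink(np.array([[3.0, 4.0]]), 1.0),
                                   [[2.4, 3.2]])

    def test_zero_row_stays_zero(self):
        np.testing.assert_array_equal(shrink(np.zeros((2, 3)), 0.5),
                                      np.zeros((2, 3)))

    def test_rows_below_threshold_vanish(self):
        R = np.array([[0.1, 0.1], [3.0, 4.0]])
        out = shrink(R, 1.0)
        np.testing.assert_array_equal(out[0], [0.0, 0.0])
        assert np.linalg.norm(out[1]) == pytest.approx(4.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(np.ones((1, 2)), 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        R=arrays(float, (4, 3), elements=st.floats(-5, 5)),
        a=st.floats(0.01, 3.0),
    )
    def test_shrink_shortens_rows_preserving_direction(self, R, a):
        out = shrink(R, a)
        in_norms = np.linalg.norm(R, axis=1)
        out_norms = np.linalg.norm(out, axis=1)
        np.testing.assert_allclose(out_norms, np.maximum(in_norms - a, 0.0),
                                   atol=1e-12)
        for r_in, r_out in zip(R, out):
            if np.linalg.norm(r_out) > 0:
                cos = r_in @ r_out / (np.linalg.norm(r_in) * np.linalg.norm(r_out))
                assert cos == pytest.approx(1.0)


class TestProjector:
    def test_zero_matrix_gives_identity(self):
        proj = make_projector(np.zeros((3, 1)))
        v = np.array([2.5])
        np.testing.assert_allclose(proj(v), v)

    def test_matches_dense_inverse(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(4, 8)).astype(float)
        proj = make_projector(H)
        dense = np.linalg.inv(np.eye(8) + H.T @ H)
        np.testing.assert_allclose(proj(np.eye(8)), dense, atol=1e-12)

    def test_symmetric_positive_definite(self):
        rng = np.random.default_rng(1)
        H = rng.integers(0, 2, size=(3, 6)).astype(float)
        U4 = make_projector(H)(np.eye(6))
        np.testing.assert_allclose(U4, U4.T, atol=1e-12)
        assert np.linalg.eigvalsh(U4).min() > 0


class TestProjectBall:
    def test_center_and_interior_unchanged(self):
        A = np.array([[0.2, 0.8]])
        np.testing.assert_array_equal(project_ball(A, A, 0.5), A)
        V = A + 0.1
        np.testing.assert_array_equal(project_ball(V, A, 1.0), V)

    def test_exterior_point_lands_on_sphere(self):
        A = np.zeros((2, 2))
        V = np.full((2, 2), 1.0)  # ||V - A||_F = 2
        out = project_ball(V, A, 1.0)
        np.testing.assert_allclose(out, V / 2)
        assert ((out - A) ** 2).sum() == pytest.approx(1.0)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            project_ball(np.zeros((1, 1)), np.zeros((1, 1)), -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        V=arrays(float, (3, 2), elements=st.floats(-2, 2)),
        delta=st.floats(0.0, 4.0),
    )
    def test_idempotent_and_contractive(self, V, delta):
        A = np.zeros((3, 2))
        once = project_ball(V, A, delta)
        twice = project_ball(once, A, delta)
        np.testing.assert_allclose(twice, once, atol=1e-12)
        assert ((once - A) ** 2).sum() <= ((V - A) ** 2).sum() + 1e-12
        assert ((once - A) ** 2).sum() <= delta + 1e-9


class TestSolverConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(rho=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(max_iter=0)
        with pytest.raises(ValueError):
            SolverConfig(delta=-0.1)

    def test_default_rho_is_inverse_mean_frequency(self):
        ps = pf.PoolSet(A=np.array([[0.2], [0.6]]), sizes=[2])
        assert SolverConfig().resolve_rho(ps) == pytest.approx(1 / 0.4)
        assert SolverConfig(rho=3.0).resolve_rho(ps) == 3.0


class TestSolveCore:
    def test_single_haplotype_column_recovers_unit_vector(self, dict4):
        j = 9
        A = dict4.H[:, [j]]
        ps = pf.PoolSet(A=A, sizes=[2])
        X, diag = solve(ps, dict4, SolverConfig(max_iter=3000, tol=0.0))
        expected = np.zeros(16)
        expected[j] = 1.0
        np.testing.assert_allclose(X[:, 0], expected, atol=1e-4)
        # the unit vector is also the exhaustive best sparse fit
        resid, w = best_sparse_fit(dict4.H, A[:, 0])
        assert resid == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(w, expected)

    def test_shared_one_hot_column_recovered_across_pools(self, dict4):
        j = 5
        X_true = np.zeros((16, 3))
        X_true[j, :] = 1.0
        ps = pf.PoolSet(A=dict4.H @ X_true, sizes=[2, 2, 2])
        X, diag = solve(ps, dict4, SolverConfig(max_iter=3000, tol=0.0))
        np.testing.assert_allclose(X, X_true, atol=1e-4)
        assert diag.data_residual < 1e-6

    def test_columns_exactly_on_simplex(self, dict4):
        rng = np.random.default_rng(2)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=4, rng=rng)
        X, _ = solve(ps, dict4, SolverConfig(max_iter=500, tol=0.0))
        assert (X >= 0).all()
        np.testing.assert_array_equal(X.sum(axis=0), np.ones(3))

    def test_objective_matches_convex_oracle(self, dict4):
        rng = np.random.default_rng(3)
        for _ in range(3):
            ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng)
            X, diag = solve(ps, dict4, SolverConfig(max_iter=8000))
            _, obj_oracle = oracle_exact(dict4.H, ps.A)
            obj = float(np.linalg.norm(X, axis=1).sum())
            assert obj == pytest.approx(obj_oracle, rel=1e-3)
            assert np.linalg.norm(dict4.H @ X - ps.A) < 1e-3

    def test_support_not_larger_than_oracle_support(self, dict4):
        rng = np.random.default_rng(4)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng)
        X, _ = solve(ps, dict4, SolverConfig(max_iter=8000))
        X_oracle, _ = oracle_exact(dict4.H, ps.A)
        loose = np.linalg.norm(X_oracle, axis=1) < 1e-6
        ours = np.linalg.norm(X, axis=1) > 1e-4
        # rows we use beyond the oracle's support must be oracle-negligible rows
        assert not (ours & ~loose & (np.linalg.norm(X_oracle, axis=1) < 1e-4)).any()

    def test_dimension_mismatch_and_missing_rejected(self, dict4):
        ps = pf.PoolSet(A=np.zeros((3, 1)) + 0.5, sizes=[2])
        with pytest.raises(ValueError):
            solve(ps, dict4, SolverConfig())
        mask = np.zeros((4, 1), dtype=bool)
        mask[0, 0] = True
        ps2 = pf.PoolSet(A=np.full((4, 1), 0.5), sizes=[2], missing_mask=mask)
        with pytest.raises(ValueError, match="solve_missing"):
            solve(ps2, dict4, SolverConfig())


class TestSolveNoisy:
    def test_degenerates_to_core_when_delta_tiny(self, dict4):
        rng = np.random.default_rng(5)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng)
        X_core, _ = solve(ps, dict4, SolverConfig(max_iter=6000, tol=0.0))
        X_noisy, _ = solve_noisy(ps, dict4,
                                 SolverConfig(max_iter=6000, tol=0.0, delta=1e-12))
        assert np.abs(X_core - X_noisy).sum(axis=0).max() < 1e-3

    def test_huge_delta_deactivates_data_constraint(self):
        # with the ball containing H*X for any simplex X, only row-sparsity
        # drives the solution: the minimizers are exactly the matrices with
        # identical simplex columns, all attaining objective sqrt(O)
        d = pf.build_full_dictionary(3)
        rng = np.random.default_rng(6)
        ps, _ = make_row_sparse_instance(d, O=2, k=2, rng=rng)
        delta = float((ps.A ** 2).sum()) + 10.0
        X, diag = solve_noisy(ps, d, SolverConfig(max_iter=4000, tol=0.0, delta=delta))
        assert diag.objective == pytest.approx(np.sqrt(2), rel=1e-3)
        np.testing.assert_allclose(X[:, 0], X[:, 1], atol=1e-3)

    def test_ball_feasibility_at_convergence(self, dict4):
        rng = np.random.default_rng(7)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng, noise_sd=0.05)
        X, _ = solve_noisy(ps, dict4, SolverConfig(max_iter=8000, delta=0.1))
        assert ((dict4.H @ X - ps.A) ** 2).sum() <= 0.1 + 1e-3


class TestSolveMissing:
    def test_zero_mask_reproduces_core_iterates_exactly(self, dict4):
        rng = np.random.default_rng(8)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng)
        X_core, d_core = solve(ps, dict4, SolverConfig(max_iter=400, tol=0.0))
        X_miss, d_miss = solve_missing(ps, dict4, SolverConfig(max_iter=400, tol=0.0))
        np.testing.assert_array_equal(X_core, X_miss)
        assert d_core.n_iter == d_miss.n_iter

    def test_masked_entries_never_read(self, dict4):
        rng = np.random.default_rng(9)
        ps, _ = make_row_sparse_instance(dict4, O=3, k=3, rng=rng)
        mask = np.zeros((4, 3), dtype=bool)
        mask[1, 0] = mask[3, 2] = True
        A_perturbed = ps.A.copy()
        A_perturbed[1, 0] = 0.987
        A_perturbed[3, 2] = 0.123
        cfg = SolverConfig(max_iter=400, tol=0.0)
        X1, _ = solve_missing(
            pf.PoolSet(A=ps.A, sizes=ps.sizes, missing_mask=mask), dict4, cfg)
        X2, _ = solve_missing(
            pf.PoolSet(A=A_perturbed, sizes=ps.sizes, missing_mask=mask), dict4, cfg)
        np.testing.assert_array_equal(X1, X2)

    def test_one_masked_locus_still_recovers_unit_vector(self):
        # with the full dictionary a masked locus always leaves a twin
        # haplotype, so uniqueness needs a restricted dictionary: here
        # "1111" stays unique on the three observed loci
        d = pf.dictionary_from_haplotypes(["0000", "1111", "0011"])
        j = d.index_of("1111")
        A = d.H[:, [j]].copy()
        mask = np.zeros((4, 1), dtype=bool)
        mask[1, 0] = True
        ps = pf.PoolSet(A=A, sizes=[2], missing_mask=mask)
        X, _ = solve_missing(ps, d, SolverConfig(max_iter=6000, tol=0.0))
        resid, w = best_sparse_fit(d.H[[0, 2, 3], :], A[[0, 2, 3], 0])
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert np.argmax(w) == j
        assert X[j, 0] == pytest.approx(1.0, abs=1e-3)

    def test_joint_support_coupling_across_masks(self, dict4):
        # two pools drawn from one haplotype; one pool loses a locus, yet the
        # shared row support survives
        j = dict4.index_of("0110")
        X_true = np.zeros((16, 2))
        X_true[j, :] = 1.0
        A = dict4.H @ X_true
        mask = np.zeros((4, 2), dtype=bool)
        mask[0, 1] = True
        ps = pf.PoolSet(A=A, sizes=[2, 2], missing_mask=mask)
        X, _ = solve_missing(ps, dict4, SolverConfig(max_iter=4000, tol=0.0))
        assert (X[j, :] > 0.99).all()

    def test_all_missing_pool_rejected(self, dict4):
        mask = np.zeros((4, 2), dtype=bool)
        mask[:, 1] = True
        ps = pf.PoolSet(A=np.full((4, 2), 0.5), sizes=[2, 2], missing_mask=mask)
        with pytest.raises(ValueError, match="no information"):
            solve_missing(ps, dict4, SolverConfig(max_iter=10))
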