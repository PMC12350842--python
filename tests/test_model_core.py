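"""Model core: composition, inference, dictionary updates, fitting."""

import numpy as np
import pytest

import dlds
from dlds._solvers import _objective
from dlds.model import (
    compose_dynamics,
    project_dictionary,
    project_observation,
    project_operator,
    update_observation,
    update_operators,
)


class TestComposeDynamics:
    def test_zero_weights_give_zero_matrix(self, rng):
        ops = rng.standard_normal((4, 3, 3))
        assert np.array_equal(compose_dynamics(ops, np.zeros(4)), np.zeros((3, 3)))

    def test_scalar_algebra_on_identity_dictionary(self):
        ops = np.stack([np.eye(2), 2 * np.eye(2)])
        out = compose_dynamics(ops, [1.0, 0.5])
        np.testing.assert_allclose(out, 2 * np.eye(2))

    def test_matches_explicit_loop_summation(self, rng):
        ops = rng.standard_normal((5, 3, 3))
        w = rng.standard_normal(5)
        expected = np.zeros((3, 3))
        for m in range(5):
            for i in range(3):
                for j in range(3):
                    expected[i, j] += w[m] * ops[m, i, j]
        np.testing.assert_allclose(compose_dynamics(ops, w), expected, atol=1e-12)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="weights"):
            compose_dynamics(rng.standard_normal((2, 3, 3)), np.ones(3))


class TestProjections:
    def test_observation_projection_unit_columns(self, rng):
        D = project_observation(rng.standard_normal((6, 3)) * 5)
        np.testing.assert_allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-12)

    def test_projection_idempotence(self, rng):
        D = rng.standard_normal((6, 3)) * 3
        once = project_observation(D)
        np.testing.assert_array_equal(project_observation(once), once)
        f = rng.standard_normal((4, 4)) * 3
        np.testing.assert_array_equal(project_operator(project_operator(f)),
                                      project_operator(f))

    def test_operator_inside_ball_untouched(self):
        f = 0.1 * np.eye(3)
        np.testing.assert_array_equal(project_operator(f), f)


class TestInfer:
    def test_identity_dynamics_fixed_point(self):
        # D = I, dictionary = {I}, constant y: latents track y, coefficient ~ 1
        p = 3
        y = np.tile(np.array([[0.6], [0.3], [0.9]]), (1, 20))
        hyper = dlds.Hyperparameters(p=p, M=1, lam_dyn=0.9, lam_x_sparse=1e-6,
                                     lam_c_sparse=1e-6, lam_c_smooth=1e-6)
        model = dlds.DLDSModel(D=np.eye(p), operators=np.eye(p)[None, :, :],
                               hyper=hyper)
        lat, coef = dlds.infer(model, y)
        np.testing.assert_allclose(lat.x, y, atol=1e-2)
        np.testing.assert_allclose(coef.c[0, 2:], 1.0, atol=1e-2)

    def test_nonfinite_input_rejected(self, small_fit):
        _, _, model, _, _ = small_fit
        bad = np.full((model.n_traces, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            dlds.infer(model, bad)

    def test_objective_never_exceeds_warm_start(self, small_fit):
        # The solve is initialized at (x_{t-1}, c_{t-1}); monotone CD cannot
        # return anything worse than that starting point.
        rec, _, model, lat, coef = small_fit
        h = model.hyper
        for t in range(1, rec.n_timepoints):
            Ftil = np.stack([f @ lat.x[:, t - 1] for f in model.operators], axis=1)
            start = _objective(
                np.ascontiguousarray(rec.traces[:, t]), model.D,
                lat.x[:, t - 1].copy(), coef.c[:, t - 1].copy(), Ftil,
                coef.c[:, t - 1].copy(), h.lam_dyn, h.lam_x_sparse,
                h.lam_c_sparse, h.lam_c_smooth, True)
            assert lat.objective[t] <= start + 1e-12

    def test_matches_convex_oracle_on_tiny_instances(self):
        gap = dlds.inference_oracle_gap(n_instances=6, seed=3)
        assert gap <= 1e-6

    def test_sparsity_increases_with_penalty(self, small_fit):
        # stronger l1 on c never increases the median active-coefficient count
        rec, _, model, _, _ = small_fit
        medians = []
        for lam_c in (1e-4, 1e-2, 1.0):
            hyper = model.hyper.replace(lam_c_sparse=lam_c)
            m = dlds.DLDSModel(D=model.D, operators=model.operators, hyper=hyper)
            _, coef = dlds.infer(m, rec)
            medians.append(coef.median_active_count())
        assert medians[0] >= medians[1] >= medians[2]


class TestUpdateObservation:
    def test_zero_residual_leaves_feasible_D(self, rng):
        D = project_observation(rng.standard_normal((5, 2)))
        X = rng.standard_normal((2, 7))
        Y = D @ X
        np.testing.assert_allclose(update_observation(D, X, Y, 0.1), D, atol=1e-12)

    def test_null_step_with_zero_eta(self, rng):
        D = project_observation(rng.standard_normal((5, 2)))
        X = rng.standard_normal((2, 7))
        Y = rng.standard_normal((5, 7))
        np.testing.assert_array_equal(update_observation(D, X, Y, 0.0), D)

    def test_negative_eta_rejected(self, rng):
        with pytest.raises(ValueError):
            update_observation(np.eye(2), np.ones((2, 1)), np.ones((2, 1)), -1.0)

    def test_hand_computed_single_timepoint_step(self):
        # one gradient step written out by hand, then column normalization
        D = np.array([[1.0, 0.0], [0.0, 1.0]])
        x = np.array([[2.0], [1.0]])
        y = np.array([[3.0], [1.0]])
        eta = 0.5
        resid = y - D @ x                       # [[1], [0]]
        stepped = D + eta * resid @ x.T         # [[2, 0.5], [0, 1]]
        expected = stepped / np.linalg.norm(stepped, axis=0)
        np.testing.assert_allclose(update_observation(D, x, y, eta), expected,
                                   atol=1e-12)


class TestUpdateOperators:
    def test_zero_coefficients_leave_dictionary(self, rng):
        ops = project_dictionary(rng.standard_normal((2, 3, 3)))
        X = rng.standard_normal((3, 6))
        C = np.zeros((2, 6))
        np.testing.assert_allclose(update_operators(ops, X, C, 0.1), ops,
                                   atol=1e-12)

    def test_exactly_generated_data_zero_gradient(self, rng):
        ops = project_dictionary(rng.standard_normal((2, 3, 3)))
        T = 6
        X = np.zeros((3, T))
        X[:, 0] = rng.standard_normal(3)
        C = np.abs(rng.standard_normal((2, T)))
        for t in range(1, T):
            X[:, t] = compose_dynamics(ops, C[:, t]) @ X[:, t - 1]
        np.testing.assert_allclose(update_operators(ops, X, C, 0.1), ops,
                                   atol=1e-10)

    def test_hand_computed_two_timepoint_step(self):
        # p = 2, M = 1, T = 2: grad = c_1 (x_1 - c_1 f x_0) x_0'
        f = np.array([[0.5, 0.0], [0.0, 0.5]])
        X = np.array([[1.0, 1.0], [0.0, 2.0]])
        C = np.array([[0.0, 2.0]])
        eta = 0.1
        resid = X[:, 1] - 2.0 * (f @ X[:, 0])          # [0, 2]
        stepped = f + eta * 2.0 * np.outer(resid, X[:, 0])
        norm = np.linalg.norm(stepped)
        expected = stepped / norm if norm > 1 else stepped
        out = update_operators(f[None], X, C, eta)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_single_timepoint_returns_unchanged(self, rng):
        ops = project_dictionary(rng.standard_normal((2, 3, 3)))
        out = update_operators(ops, rng.standard_normal((3, 1)),
                               rng.standard_normal((2, 1)), 0.1)
        np.testing.assert_array_equal(out, ops)


class TestFit:
    def test_reconstruction_quality_on_generated_data(self, small_fit):
        rec, _, model, lat, _ = small_fit
        _, r2 = dlds.reconstruct(model.D, lat, y=rec)
        assert r2 >= 0.9

    def test_seed_determinism_bitwise(self):
        rec, _ = dlds.generate_dlds_data(p=2, M=2, T=40, n_traces=8, seed=5)
        hyper = dlds.Hyperparameters(p=2, M=2, max_iter=15, seed=3)
        m1, l1, c1 = dlds.fit(rec, hyper)
        m2, l2, c2 = dlds.fit(rec, hyper)
        assert m1.fit_log["delta_D"].tolist() == m2.fit_log["delta_D"].tolist()
        assert m1.fit_log["delta_F"].tolist() == m2.fit_log["delta_F"].tolist()
        np.testing.assert_array_equal(m1.D, m2.D)
        np.testing.assert_array_equal(m1.operators, m2.operators)
        np.testing.assert_array_equal(c1.c, c2.c)

    def test_single_timepoint_keeps_initial_dictionary(self):
        rec = dlds.NeuralRecording(traces=np.abs(np.random.default_rng(0)
                                                 .standard_normal((6, 1))))
        hyper = dlds.Hyperparameters(p=2, M=3, max_iter=10, seed=7)
        model, lat, coef = dlds.fit(rec, hyper)
        rng = np.random.default_rng(7)
        rng.standard_normal((6, 2))          # D draw consumed first
        init_ops = project_dictionary(rng.standard_normal((3, 2, 2)))
        np.testing.assert_array_equal(model.operators, init_ops)

    def test_fit_log_records_change_norms(self, small_fit):
        _, _, model, _, _ = small_fit
        assert {"iteration", "delta_D", "delta_F", "objective"} <= set(
            model.fit_log.columns)
        assert len(model.fit_log) >= 1


class TestFitAligned:
    def test_single_recording_matches_fit_exactly(self):
        rec, _ = dlds.generate_dlds_data(p=2, M=2, T=50, n_traces=8, seed=2)
        hyper = dlds.Hyperparameters(p=2, M=2, max_iter=20, seed=6)
        model, lat, coef = dlds.fit(rec, hyper)
        aligned = dlds.fit_aligned([rec], hyper)
        sub = aligned.per_subject[rec.subject_id]
        np.testing.assert_array_equal(sub.D, model.D)
        np.testing.assert_array_equal(aligned.operators, model.operators)
        np.testing.assert_array_equal(sub.coefficients.c, coef.c)

    def test_two_subjects_share_one_dictionary_object(self):
        pairs = dlds.generate_multi_subject(2, p=2, M=2, T=40, n_traces=[6, 9],
                                            seed=8)
        hyper = dlds.Hyperparameters(p=2, M=2, max_iter=15, seed=1)
        aligned = dlds.fit_aligned([r for r, _ in pairs], hyper)
        models = [aligned.subject_model(r.subject_id) for r, _ in pairs]
        assert models[0].operators is models[1].operators

    def test_many_subjects_shape_contract(self):
        # aligned run permitting ~10 unique operators per subject
        recs = [dlds.NeuralRecording(
                    traces=np.abs(np.random.default_rng(s).standard_normal((5, 8))),
                    subject_id=f"w{s}")
                for s in range(7)]
        hyper = dlds.Hyperparameters(p=3, M=70, max_iter=1, seed=0)
        aligned = dlds.fit_aligned(recs, hyper)
        assert aligned.operators.shape == (70, 3, 3)
        for rec in recs:
            sub = aligned.per_subject[rec.subject_id]
            assert sub.coefficients.c.shape == (70, rec.n_timepoints)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dlds.fit_aligned([], dlds.Hyperparameters())


class TestReconstruct:
    def test_identity_observation(self, rng):
        X = rng.standard_normal((3, 10))
        y_hat, r2 = dlds.reconstruct(np.eye(3), X, y=X)
        np.testing.assert_array_equal(y_hat, X)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_r2(self, rng):
        D = rng.standard_normal((4, 2))
        X = rng.standard_normal((2, 6))
        Y = rng.standard_normal((4, 6))
        y_hat, r2 = dlds.reconstruct(D, X, y=Y)
        ss_res = np.sum((Y - D @ X) ** 2)
        ss_tot = np.sum((Y - Y.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_zero_variance_reports_nan(self):
        with pytest.warns(RuntimeWarning, match="variance"):
            _, r2 = dlds.reconstruct(np.eye(2), np.ones((2, 3)),
                                     y=np.ones((2, 3)))
        assert np.isnan(r2)

    def test_scale_applied(self, rng):
        X = rng.standard_normal((2, 4))
        y_hat, _ = dlds.reconstruct(np.eye(2), X, scale=3.0)
        np.testing.assert_allclose(y_hat, 3.0 * X)


class TestSelectNumOperators:
    def test_exact_low_rank_data(self, rng):
        basis = rng.standard_normal((10, 3))
        weights = rng.standard_normal((3, 50))
        traces = basis @ weights
        assert dlds.select_num_operators(traces) == 6

    def test_spectrum_needing_five_components(self, rng):
        # construct data whose centered spectrum needs exactly 5 PCs for 95%
        U = np.linalg.qr(rng.standard_normal((20, 20)))[0]
        V = np.linalg.qr(rng.standard_normal((60, 60)))[0]
        svals = np.array([10.0, 8.0, 6.0, 5.0, 4.0] + [0.5] * 15)
        cum = np.cumsum(svals ** 2) / np.sum(svals ** 2)
        assert np.searchsorted(cum, 0.95) + 1 == 5
        traces = (U * svals) @ V[:20, :]
        traces = traces - traces.mean(axis=1, keepdims=True) + 1.0
        assert dlds.select_num_operators(traces) == 10

    def test_candidate_counts_pick_smallest_at_plateau(self, rng):
        traces = rng.standard_normal((5, 30))
        counts = {4: 2.0, 6: 3.0, 8: 3.0, 10: 3.0}
        out = dlds.select_num_operators(traces, candidate_counts=[4, 6, 8, 10],
                                        median_active_counts=counts)
        assert out == 6

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            dlds.select_num_operators(np.empty((0, 0)))


class TestSpanDiagnostics:
    def test_conjugated_copy_has_zero_angles(self, rng):
        ops = np.stack([f / np.linalg.norm(f) for f in rng.standard_normal((3, 4, 4))])
        D = rng.standard_normal((10, 4))
        R = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        D2 = D @ np.linalg.inv(R)
        ops2 = np.stack([R @ f @ np.linalg.inv(R) for f in ops])
        basis = dlds.align_latent_bases(D2, D)
        ang = dlds.operator_span_angles(ops2, ops, basis_change=basis)
        assert np.degrees(ang).max() < 1e-6
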