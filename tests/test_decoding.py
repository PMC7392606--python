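"""Linear decoders: OLS, cross-validation, multi-day fits, ranking, GP."""

import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from driftstab import dataio, decoding as dec, synthetic as sy
from driftstab.data import InvalidParameterError, SessionData

from conftest import make_ramp_session


class TestFitOLS:

    def test_identity_regression(self):
        x = np.linspace(-1, 1, 50)
        w = dec.fit_ols(x[:, None], x)
        assert abs(w.weights[0] - 1.0) < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((50, 5))
        x = rng.standard_normal(50)
        w = dec.fit_ols(Z, x)
        oracle = np.linalg.pinv(Z) @ x
        assert np.allclose(w.weights, oracle, atol=1e-10)
        resid = Z.T @ (x - Z @ w.weights)
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(Z.T @ x)

    def test_orthonormal_design_gives_inner_products(self):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((60, 4)))
        x = rng.standard_normal(60)
        w = dec.fit_ols(Q, x)
        assert np.allclose(w.weights, Q.T @ x, atol=1e-12)

    def test_singular_design_advises_ridge(self):
        Z = np.ones((20, 3))  # rank 1
        with pytest.raises(dec.IllConditionedError, match="ridge"):
            dec.fit_ols(Z, np.arange(20.0))
        w = dec.fit_ols(Z, np.arange(20.0), ridge_strength=1e-3)
        assert np.all(np.isfinite(w.weights))


class TestEvaluateCV:

    def test_noiseless_linear_data_is_perfectly_decoded(self):
        sess = make_ramp_session(informative=True, seed=0)
        prep = dataio.prepare_decoding_series(sess)
        res = dec.evaluate_cv(prep, "position", folds=6)
        assert res["mae"] < 1e-8

    def test_matches_hand_looped_folds(self):
        sess = make_ramp_session(n_trials=5, samples_per_trial=20,
                                 n_units=3, seed=1, informative=True)
        prep = dataio.prepare_decoding_series(sess)
        res = dec.evaluate_cv(prep, "position", folds=5)
        Z, x = prep.activity, prep.target("position")
        tid = prep.kinematics.trial_id
        errs = []
        for t in range(5):  # one trial per fold, in order
            test = tid == t
            w = np.linalg.lstsq(Z[~test], x[~test], rcond=None)[0]
            errs.append(np.abs(x[test] - Z[test] @ w))
        assert abs(res["mae"] - np.concatenate(errs).mean()) < 1e-12

    def test_folds_never_split_trials(self):
        sess = make_ramp_session(n_trials=7, seed=2)
        masks = dec.trial_folds(sess.kinematics.trial_id, 3)
        tid = sess.kinematics.trial_id
        for m in masks:
            present = set(tid[m].tolist())
            for t in present:
                assert np.all(m[tid == t])

    def test_fewer_trials_than_folds_rejected(self):
        sess = make_ramp_session(n_trials=4, seed=3)
        with pytest.raises(InvalidParameterError):
            dec.evaluate_cv(sess, "position", folds=10)


class TestChanceLevel:

    def test_constant_target_has_zero_chance_error(self):
        sess = make_ramp_session(seed=4)
        kin = dec.with_target_channel(sess.kinematics, "position",
                                      np.zeros(sess.n_samples))
        s2 = SessionData(0, sess.unit_ids, sess.activity, kin)
        assert dec.chance_level(s2, "position", n_shuffles=5) < 1e-10

    def test_uninformative_activity_approaches_quarter_range(self):
        # closed form: prediction ~0 = median of the centered uniform
        # position, so E|x - xhat| -> L/4
        L = 4.0
        sess = make_ramp_session(n_trials=40, samples_per_trial=50,
                                 maze_len=L, n_units=4, seed=5,
                                 informative=False)
        prep = dataio.prepare_decoding_series(sess)
        mae = dec.chance_level(prep, "position", n_shuffles=20, seed=0,
                               folds=4)
        assert abs(mae - L / 4) < 0.1 * (L / 4)


class TestConcatenated:

    def test_single_session_equals_fit_ols(self, prepared_dataset):
        sub = prepared_dataset[:1]
        cat = dec.fit_concatenated(sub, "position")
        ols = dec.fit_ols(sub[0].activity, sub[0].target("position"))
        assert np.allclose(cat.weights, ols.weights, atol=1e-10)

    def test_duplicated_session_invariance(self, prepared_dataset):
        from driftstab.data import MultiDayDataset
        s = prepared_dataset[0]
        dup = MultiDayDataset([s, s, s])
        cat = dec.fit_concatenated(dup, "position")
        ols = dec.fit_ols(s.activity, s.target("position"))
        assert np.allclose(cat.weights, ols.weights, atol=1e-8)

    def test_matches_stacked_normal_equations(self, prepared_dataset):
        sub = prepared_dataset[:3]
        cat = dec.fit_concatenated(sub, "position")
        Z = np.vstack([s.activity for s in sub.sessions])
        x = np.concatenate([s.target("position") for s in sub.sessions])
        oracle = np.linalg.solve(Z.T @ Z, Z.T @ x)
        assert np.allclose(cat.weights, oracle, atol=1e-8)

    def test_training_error_at_least_per_day_optimum(self, prepared_dataset):
        cat = dec.fit_concatenated(prepared_dataset, "position")
        total_cat, total_day = 0.0, 0.0
        for s in prepared_dataset.sessions:
            x = s.target("position")
            total_cat += np.sum((x - s.activity @ cat.weights) ** 2)
            w = dec.fit_ols(s.activity, x)
            total_day += np.sum((x - s.activity @ w.weights) ** 2)
        assert total_cat >= total_day - 1e-9


class TestConstrainedPath:

    def test_lambda_zero_recovers_per_day_ols(self, prepared_dataset):
        res = dec.fit_constrained_path(prepared_dataset, "position", [0.0])
        for d, s in enumerate(prepared_dataset.sessions):
            ols = dec.fit_ols(s.activity, s.target("position"))
            rel = np.linalg.norm(res.per_day_weights[0][d] - ols.weights) \
                / np.linalg.norm(ols.weights)
            assert rel < 1e-6

    def test_lambda_to_one_recovers_concatenated(self, prepared_dataset):
        res = dec.fit_constrained_path(prepared_dataset, "position",
                                       [1 - 1e-9])
        cat = dec.fit_concatenated(prepared_dataset, "position")
        M = res.per_day_weights[0]
        for d in range(prepared_dataset.n_sessions):
            rel = np.linalg.norm(M[d] - cat.weights) \
                / np.linalg.norm(cat.weights)
            assert rel < 1e-4

    def test_mid_lambda_matches_generic_quadratic_solver(self):
        # generic QP oracle on a tiny 2-day problem
        rng = np.random.default_rng(6)
        Z1, Z2 = rng.standard_normal((30, 3)), rng.standard_normal((30, 3))
        x1, x2 = rng.standard_normal(30), rng.standard_normal(30)
        from driftstab.data import KinematicsSeries, MultiDayDataset
        sessions = []
        for d, (Z, x) in enumerate([(Z1, x1), (Z2, x2)]):
            kin = KinematicsSeries(
                np.arange(30) / 5.3, x, np.zeros(30), np.zeros(30),
                np.repeat(np.arange(3), 10), np.ones(30, bool),
                np.zeros(30, int), np.zeros(30, bool), maze_len_m=10.0)
            sessions.append(SessionData(d, np.arange(3), Z, kin))
        md = MultiDayDataset(sessions)
        lam = 0.4
        res = dec.fit_constrained_path(md, "position", [lam])

        def objective(m):
            m1, m2 = m[:3], m[3:]
            return ((1 - lam) * (np.sum((x1 - Z1 @ m1) ** 2)
                                 + np.sum((x2 - Z2 @ m2) ** 2))
                    + lam * np.sum((m2 - m1) ** 2))

        opt = scipy.optimize.minimize(objective, np.zeros(6),
                                      method="BFGS",
                                      options={"gtol": 1e-12})
        ours = objective(res.per_day_weights[0].ravel())
        assert abs(ours - opt.fun) < 1e-6 * max(1.0, abs(opt.fun))

    def test_weight_change_decreases_along_path(self, prepared_dataset):
        grid = [0.0, 0.2, 0.5, 0.8, 0.999]
        res = dec.fit_constrained_path(prepared_dataset, "position", grid)
        pct = res.pct_weight_change
        assert np.all(np.diff(pct) <= 1e-6)
        assert pct[-1] < 0.05 * pct[0]

    def test_lambda_outside_unit_interval_rejected(self, prepared_dataset):
        for bad in ([-0.1], [1.0], [1.5]):
            with pytest.raises(InvalidParameterError):
                dec.fit_constrained_path(prepared_dataset, "position", bad)


class TestPermutationBaseline:

    def test_identity_permutation_is_noop(self, prepared_dataset):
        n = prepared_dataset.n_units
        perms = [np.arange(n)] * prepared_dataset.n_sessions
        res = dec.permutation_identity_baseline(prepared_dataset,
                                                "position",
                                                permutations=perms)
        assert abs(res["errors"][0] - res["unpermuted"]) < 1e-12

    def test_systematic_drift_beats_permuted_codes(self, prepared_dataset):
        res = dec.permutation_identity_baseline(prepared_dataset,
                                                "position", n_perms=30,
                                                seed=0)
        assert res["unpermuted"] < np.percentile(res["errors"], 5)


class TestCrossDayMatrix:

    def test_zero_drift_off_diagonal_close_to_diagonal(
            self, prepared_stationary):
        m = dec.cross_day_matrix(prepared_stationary, "position", folds=5)
        diag = np.diag(m).mean()
        off = m[~np.eye(len(m), dtype=bool)].mean()
        assert off < 1.25 * diag

    def test_diagonal_equals_cv_error(self, prepared_dataset):
        m = dec.cross_day_matrix(prepared_dataset[:2], "position", folds=5)
        cv = dec.evaluate_cv(prepared_dataset[0], "position", folds=5)
        assert abs(m[0, 0] - cv["mae"]) < 1e-12

    def test_diffusive_drift_grows_with_day_gap(self):
        # Monte-Carlo oracle: mean error should correlate positively
        # with |i - j| under random-walk drift
        rhos = []
        for seed in range(8):
            cfg = sy.SimulateConfig(
                n_units=20, n_sessions=5, n_trials=15, seed=seed,
                drift=sy.DriftSpec("random_walk", step_size=0.08,
                                   seed=seed + 50),
                noise_params=sy.NoiseParams(0.5, 0.5, 0.5))
            md = sy.generate_dataset(cfg).map_sessions(
                dataio.prepare_decoding_series)
            m = dec.cross_day_matrix(md, "position", folds=5)
            i, j = np.indices(m.shape)
            rhos.append(scipy.stats.spearmanr(
                np.abs(i - j).ravel(), m.ravel()).statistic)
        assert np.mean(rhos) > 0.5

    def test_invariant_to_unit_reordering(self, prepared_dataset):
        sub = prepared_dataset[:2]
        perm = np.random.default_rng(0).permutation(sub.n_units)
        from driftstab.data import MultiDayDataset
        permuted = MultiDayDataset(
            [SessionData(s.day_index, s.unit_ids[perm],
                         s.activity[:, perm], s.kinematics)
             for s in sub.sessions],
            common_units=sub.common_units[perm])
        a = dec.cross_day_matrix(sub, "position", folds=5)
        b = dec.cross_day_matrix(permuted, "position", folds=5)
        assert np.allclose(a, b, atol=1e-8)


class TestGreedyRank:

    def test_informative_unit_ranked_first(self):
        sess = make_ramp_session(n_trials=10, n_units=6, seed=7,
                                 informative=True)
        prep = dataio.prepare_decoding_series(sess)
        res = dec.greedy_rank(prep, "position", ridge_strength=1e-4,
                              folds=5)
        assert res.order[0] == 0

    def test_full_set_error_equals_evaluate_cv(self, prepared_dataset):
        s = prepared_dataset[0]
        res = dec.greedy_rank(s, "position", ridge_strength=0.0, folds=5)
        cv = dec.evaluate_cv(s, "position", folds=5)
        assert abs(res.cv_error_by_k[-1] - cv["mse"]) < 1e-8

    def test_greedy_matches_exhaustive_best_addition(self):
        # 8-unit toy: at every step the greedy choice must equal the
        # brute-force best single addition
        sess = make_ramp_session(n_trials=8, n_units=8, seed=8,
                                 informative=True)
        rng = np.random.default_rng(9)
        act = sess.activity
        act[:, 3] += 0.7 * sess.target("position")  # second informative
        act[:, 5] += 0.2 * rng.standard_normal(sess.n_samples)
        prep = dataio.prepare_decoding_series(sess)
        res = dec.greedy_rank(prep, "position", ridge_strength=1e-4,
                              folds=4)
        Z, x = prep.activity, prep.target("position")
        masks = dec.trial_folds(prep.kinematics.trial_id, 4)

        def cv_mse(S):
            S = list(S)
            errs = []
            for test in masks:
                A = Z[~test][:, S]
                w = np.linalg.solve(
                    A.T @ A / len(A) + 1e-4 * np.eye(len(S)),
                    A.T @ x[~test] / len(A))
                errs.append((x[test] - Z[test][:, S] @ w) ** 2)
            return np.concatenate(errs).mean()

        chosen = []
        for step in range(8):
            rest = [j for j in range(8) if j not in chosen]
            best = min(rest, key=lambda j: (cv_mse(chosen + [j]), j))
            assert res.order[step] == best
            chosen.append(best)


class TestExtrapolation:

    def test_interpolates_noiseless_curve(self):
        sizes = np.array([5, 10, 20, 40, 80])
        errors = 2.0 / np.sqrt(sizes) + 0.3
        gp = dec.fit_performance_gp(sizes, errors, sizes, seed=0)
        assert np.all(np.abs(gp["mean"] - errors) / errors < 0.01)

    def test_band_is_1p96_sigma(self):
        sizes = np.array([5, 10, 20, 40])
        errors = np.array([1.0, 0.7, 0.55, 0.5])
        gp = dec.fit_performance_gp(sizes, errors,
                                    np.array([5, 15, 60]), seed=0)
        assert np.allclose(gp["upper"] - gp["mean"], 1.96 * gp["sigma"])
        assert np.allclose(gp["mean"] - gp["lower"], 1.96 * gp["sigma"])

    def test_error_decreases_with_subset_size(self, prepared_dataset):
        s = prepared_dataset[0]
        res = dec.extrapolate_performance(s, "position", [5, 15, 40],
                                          n_draws=5, seed=0, folds=5)
        assert res["mean_error"][0] > res["mean_error"][-1]

    def test_too_few_sizes_rejected(self, prepared_dataset):
        with pytest.raises(InvalidParameterError):
            dec.extrapolate_performance(prepared_dataset[0], "position",
                                        [5, 10], n_draws=2)


class TestDegradationCurve:

    def test_stationary_code_stays_near_one(self, prepared_stationary):
        curve = dec.degradation_curve(prepared_stationary, "position")
        assert curve[0] == pytest.approx(1.0, abs=1e-9)
        assert curve.min() > 0.9
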