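import numpy as np
import pytest

from uvquant.plsr import (
    cross_validate,
    fit_pls1,
    metrics,
    predict,
    regression_vector_report,
    venetian_blinds,
)
from uvquant.preprocess import PreprocessChain, fit_chain, run_chain_rowwise
from uvquant.report import fit_analyte
from uvquant.spectra_io import subset
from uvquant.synth import BSA, ComponentSpectrum, NoiseModel, build_cospike_design, simulate_dataset


def _centered_instance(rng, n=8, p=5):
    X = rng.normal(0, 1, (n, p))
    y = rng.normal(0, 1, n)
    return X - X.mean(axis=0), y


class TestFitPLS1:
    def test_rank_one_problem_solved_with_one_lv(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        X = np.zeros((20, 6))
        X[:, 2] = x
        y = 3.0 * x + 5.0
        model = fit_pls1(X - X.mean(axis=0), y, 1)
        rmse = np.sqrt(np.mean((predict(model, X - X.mean(axis=0)) - y) ** 2))
        assert rmse < 1e-8

    def test_full_lv_matches_least_squares_oracle(self):
        # independent oracle: minimum-norm pseudo-inverse solution
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Xc, y = _centered_instance(rng)
            model = fit_pls1(Xc, y, 5)
            oracle = Xc @ np.linalg.pinv(Xc) @ (y - y.mean()) + y.mean()
            np.testing.assert_allclose(predict(model, Xc), oracle, atol=1e-6)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Xc, y = _centered_instance(rng, n=20, p=12)
            for n_lv in (1, 3, 5):
                model = fit_pls1(Xc, y, n_lv)
                ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(Xc, y)
                np.testing.assert_allclose(
                    predict(model, Xc), ref.predict(Xc).ravel(), atol=1e-8
                )

    def test_duplicating_all_rows_leaves_model_unchanged(self):
        rng = np.random.default_rng(1)
        Xc, y = _centered_instance(rng, n=10, p=6)
        m1 = fit_pls1(Xc, y, 3)
        m2 = fit_pls1(np.vstack([Xc, Xc]), np.concatenate([y, y]), 3)
        np.testing.assert_allclose(m1.b, m2.b, atol=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        Xc, y = _centered_instance(rng, n=15, p=10)
        model = fit_pls1(Xc, y, 5)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(gram))

    def test_b_predictions_equal_sequential_lv_reconstruction(self):
        rng = np.random.default_rng(3)
        Xc, y = _centered_instance(rng, n=12, p=8)
        model = fit_pls1(Xc, y, 4)
        # sequential route: scores from deflated weights, then T q
        seq = model.T @ model.q + model.y_mean
        np.testing.assert_allclose(predict(model, Xc), seq, rtol=1e-8, atol=1e-8)

    def test_rmsec_nonincreasing_in_lv(self):
        rng = np.random.default_rng(4)
        Xc, y = _centered_instance(rng, n=20, p=10)
        errors = []
        for lv in range(1, 10):
            model = fit_pls1(Xc, y, lv)
            errors.append(np.sqrt(np.mean((predict(model, Xc) - y) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(5)
        Xc, y = _centered_instance(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_pls1(Xc, np.ones(8), 2)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls1(Xc, y, 6)  # > min(n-1, p) = 5
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls1(Xc, y, 0)


ZERO_NOISE = NoiseModel(additive_sd=0.0, pathlength_sd=0.0, baseline_drift=(0.0, 0.0), seed=0)


class TestPredict:
    def test_calibration_mean_spectrum_predicts_y_mean(self):
        rng = np.random.default_rng(6)
        Xc, y = _centered_instance(rng, n=10, p=6)
        model = fit_pls1(Xc, y, 3)
        assert predict(model, np.zeros((1, 6)))[0] == pytest.approx(y.mean())

    def test_ground_truth_recovery_zero_noise(self, noiseless_cospike):
        # without path-length variation SNV is unnecessary and the response
        # is exactly linear, so a few LVs recover the truth to numerical noise
        cal = subset(noiseless_cospike, lambda m: m.role == "calibration")
        chain = PreprocessChain(snv_enabled=False)
        fit_chain(cal, chain)
        model = fit_analyte(cal, chain, BSA, 3)
        preds = predict(model, cal)
        assert np.max(np.abs(preds - cal.concentrations(BSA))) < 0.1

    def test_selectivity_against_orthogonal_band_analyte(self):
        # analyte A at 220 nm, interferent B at 300 nm, disjoint bands
        comps = {
            "A": ComponentSpectrum("A", bands=((220.0, 4.0, 1e-3),)),
            "B": ComponentSpectrum("B", bands=((300.0, 4.0, 1e-3),)),
        }
        bg = ComponentSpectrum("bg", bands=((230.0, 10.0, 0.0),))
        from uvquant.synth import DesignTable

        rows_a = tuple((i + 1, {"A": c, "B": 100.0}) for i, c in enumerate([400, 300, 200, 100, 50]))
        train = DesignTable(rows=rows_a)
        ds = simulate_dataset(train, components=comps, urine_background=bg, noise=ZERO_NOISE,
                              n_collections=1, n_replicates=1, n_calibration_collections=1)
        chain = PreprocessChain(trim_range=None, baseline=None, smooth_params=None,
                                snv_enabled=False, mean_center=True)
        fit_chain(ds, chain)
        model = fit_analyte(ds, chain, "A", 1)
        rows_b = tuple((i + 1, {"A": 210.0, "B": c}) for i, c in enumerate([500, 250, 10]))
        varied_b = simulate_dataset(DesignTable(rows=rows_b), components=comps, urine_background=bg,
                                    noise=ZERO_NOISE, n_collections=1, n_replicates=1,
                                    n_calibration_collections=1)
        preds = predict(model, varied_b)
        assert np.max(np.abs(preds - 210.0)) < 0.5

    def test_grid_mismatch_rejected(self, noiseless_cospike):
        cal = subset(noiseless_cospike, lambda m: m.role == "calibration")
        chain = PreprocessChain()
        fit_chain(cal, chain)
        model = fit_analyte(cal, chain, BSA, 4)
        with pytest.raises(ValueError, match="wavelengths"):
            predict(model, np.zeros((1, 7)))


class TestVenetianBlinds:
    def test_round_robin_assignment(self):
        plan = venetian_blinds(list(range(8)), k=4)
        assert plan.folds == ((0, 4), (1, 5), (2, 6), (3, 7))

    def test_cospike_fold_sizes(self):
        groups = [("day1", f) for f in range(1, 16)] + [("day2", f) for f in range(1, 16)]
        plan = venetian_blinds(groups, k=4)
        assert sorted(len(f) for f in plan.folds) == [7, 7, 8, 8]

    def test_partition_property(self):
        groups = [(c, f) for c in "ab" for f in range(9)]
        plan = venetian_blinds(groups, k=5)
        flat = [g for fold in plan.folds for g in fold]
        assert sorted(flat) == sorted(set(groups))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            venetian_blinds(list(range(3)), k=4)
        with pytest.raises(ValueError):
            venetian_blinds(list(range(3)), k=1)


class TestCrossValidate:
    def test_zero_noise_linear_data_has_tiny_rmsecv(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(0, 1, 6)
        X = rng.normal(0, 1, (24, 6))
        y = X @ beta
        groups = [("g", i // 3) for i in range(24)]  # triplicate groups
        m, y_hat = cross_validate(X, y, groups, n_lv=6, k=4)
        assert m.rmsecv < 1e-6
        assert not np.any(np.isnan(y_hat))

    def test_two_group_univariate_hand_oracle(self):
        # leave-group-out by hand: train B -> slope 0.5 predicts A as (2, 2.5);
        # train A -> slope 1 predicts B as (2, 3); RMSECV = sqrt(7.5/4)
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 1.0, 3.0, 3.5])
        groups = [("a", 0), ("a", 0), ("b", 1), ("b", 1)]
        m, y_hat = cross_validate(X, y, groups, n_lv=1, k=2)
        np.testing.assert_allclose(y_hat, [2.0, 2.5, 2.0, 3.0], atol=1e-12)
        assert m.rmsecv == pytest.approx(np.sqrt(7.5 / 4))

    def test_deterministic(self, default_cospike):
        cal = subset(default_cospike, lambda m: m.role == "calibration")
        chain = PreprocessChain()
        rowwise = run_chain_rowwise(cal, chain)
        y = cal.concentrations(BSA)
        groups = [(m.urine_collection_id, m.fraction_index) for m in cal.meta]
        m1, p1 = cross_validate(rowwise.absorbance, y, groups, 6)
        m2, p2 = cross_validate(rowwise.absorbance, y, groups, 6)
        assert m1.rmsecv == m2.rmsecv and np.array_equal(p1, p2)

    def test_corrupting_held_out_labels_leaves_fold_models_unchanged(self):
        # leakage check: fold-0 held-out predictions cannot depend on fold-0 labels
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (24, 6))
        y = X @ rng.normal(0, 1, 6) + rng.normal(0, 0.1, 24)
        groups = [("g", i // 3) for i in range(24)]
        plan = venetian_blinds(groups, k=4)
        held0 = np.array([g in plan.folds[0] for g in groups])
        _, clean = cross_validate(X, y, groups, n_lv=3, k=4)
        y_bad = y.copy()
        y_bad[held0] += 1e6
        _, dirty = cross_validate(X, y_bad, groups, n_lv=3, k=4)
        np.testing.assert_array_equal(clean[held0], dirty[held0])

    def test_constant_training_fold_rejected_by_name(self):
        X = np.random.default_rng(10).normal(0, 1, (4, 2))
        y = np.array([1.0, 1.0, 5.0, 1.0])
        groups = [("g", 0), ("g", 1), ("g", 2), ("g", 3)]
        with pytest.raises(ValueError, match="fold 2"):
            cross_validate(X, y, groups, n_lv=1, k=4)


class TestMetrics:
    def test_perfect_fit(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], context="cal")
        assert m.rmsec == 0.0 and m.r2_cal == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        m = metrics([0.0, 0.0], [3.0, 4.0], context="pred")
        assert m.rmsep == pytest.approx(np.sqrt(12.5))

    def test_r2_is_affine_invariant_squared_pearson(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(y, 2 * y + 7, context="cv")
        assert m.r2_cv == pytest.approx(1.0)
        assert m.rmsecv > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0, 2.0], [1.0], context="cal")


class TestRegressionVectorReport:
    def test_single_band_analyte_peaks_near_band_center(self):
        comps = {"A": ComponentSpectrum("A", bands=((250.0, 5.0, 1e-3),))}
        bg = ComponentSpectrum("bg", bands=((230.0, 10.0, 0.0),))
        from uvquant.synth import DesignTable

        rows = tuple((i + 1, {"A": c}) for i, c in enumerate([400, 300, 200, 100, 50, 0]))
        ds = simulate_dataset(DesignTable(rows=rows), components=comps, urine_background=bg,
                              noise=ZERO_NOISE, n_collections=1, n_replicates=1,
                              n_calibration_collections=1)
        chain = PreprocessChain(trim_range=(190.0, 320.0), baseline=None, smooth_params=None,
                                snv_enabled=False, mean_center=True)
        fit_chain(ds, chain)
        model = fit_analyte(ds, chain, "A", 1)
        df = regression_vector_report(model)
        assert abs(df.attrs["max_abs_nm"] - 250.0) <= 3.0
        np.testing.assert_array_equal(df["coefficient"].to_numpy(), model.b)
        assert np.any(model.b != 0)
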