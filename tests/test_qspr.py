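"""MLR fitting, diagnostics, outlier exclusion and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from eempka.errors import (
    CollinearityError,
    DegenerateFoldError,
    DescriptorError,
    JoinError,
)
from eempka.io import load_model, save_model
from eempka.qspr import (
    KIND_SYMBOLS,
    QsprModel,
    assign_stratified_folds,
    cooks_distances,
    cross_validate,
    evaluate,
    fit_mlr,
    predict,
    remove_outliers_and_refit,
)
from eempka.synthetic import (
    gen_parameter_set,
    gen_qspr_dataset,
    phenol_study_spec,
)


@pytest.fixture(scope="module")
def ref_params():
    return gen_parameter_set(3)


@pytest.fixture(scope="module")
def noiseless(ref_params):
    spec = phenol_study_spec(noise_sigma=0.0, seed=5)
    return gen_qspr_dataset(spec, ref_params), spec


@pytest.fixture(scope="module")
def noisy(ref_params):
    spec = phenol_study_spec(noise_sigma=0.5, seed=5)
    return gen_qspr_dataset(spec, ref_params), spec


class TestFit:
    def test_noiseless_data_recovered_exactly(self, noiseless):
        (desc, pka), spec = noiseless
        model, report = fit_mlr(desc, pka, "5d")
        assert report.r2 == pytest.approx(1.0, abs=1e-9)
        assert report.rmse == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            model.coefficients, spec.true_coefficients, atol=1e-6
        )
        assert model.intercept == pytest.approx(spec.intercept, abs=1e-6)

    def test_coefficients_match_normal_equations_oracle(self, noisy):
        (desc, pka), _ = noisy
        model, _ = fit_mlr(desc, pka, "3d")
        merged = desc.merge(pka, on="molecule_id").sort_values("molecule_id")
        X = np.column_stack(
            [np.ones(len(merged))] + [merged[s] for s in KIND_SYMBOLS["3d"]]
        )
        y = merged["pka_exp"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert model.intercept == pytest.approx(beta[0], rel=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], rtol=1e-7)

    def test_training_r2_equals_coefficient_of_determination(self, noisy):
        # squared-Pearson and 1 - SSE/SST coincide for OLS with intercept
        (desc, pka), _ = noisy
        model, report = fit_mlr(desc, pka, "5d")
        merged = desc.merge(pka, on="molecule_id").sort_values("molecule_id")
        y = merged["pka_exp"].to_numpy()
        pred = predict(model, merged)
        sse = ((y - pred) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert report.r2 == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_mae_never_exceeds_rmse(self, noisy, noiseless):
        for (desc, pka), _ in (noisy, noiseless):
            for kind in ("3d", "5d"):
                _, report = fit_mlr(desc, pka, kind)
                assert report.mae <= report.rmse + 1e-12

    @pytest.mark.parametrize("data_seed", [5, 6, 7])
    def test_nested_model_monotonicity(self, ref_params, data_seed):
        # adding the two anion descriptors never lowers training R^2
        spec = phenol_study_spec(noise_sigma=0.5, seed=data_seed)
        desc, pka = gen_qspr_dataset(spec, ref_params)
        _, r3 = fit_mlr(desc, pka, "3d")
        _, r5 = fit_mlr(desc, pka, "5d")
        assert r5.r2 >= r3.r2 - 1e-12

    def test_duplicate_descriptor_column_is_collinear(self, noisy):
        (desc, pka), _ = noisy
        broken = desc.copy()
        broken["q_OD"] = broken["q_O"]
        with pytest.raises(CollinearityError):
            fit_mlr(broken, pka, "5d")

    def test_mismatched_ids_raise_join_error(self, noisy):
        (desc, pka), _ = noisy
        with pytest.raises(JoinError):
            fit_mlr(desc, pka.iloc[:-3], "5d")

    def test_parameter_recovery_within_4se(self, ref_params):
        """At sigma = 0.5, n = 74, true coefficients fall within 4 standard
        errors in >= 95% of 200 seeded noise replicates."""
        import statsmodels.api as sm

        spec = phenol_study_spec(noise_sigma=0.0, seed=5)
        desc, pka = gen_qspr_dataset(spec, ref_params)
        merged = desc.merge(pka, on="molecule_id").sort_values("molecule_id")
        X = sm.add_constant(
            merged[list(KIND_SYMBOLS["5d"])].to_numpy(dtype=float)
        )
        y0 = merged["pka_exp"].to_numpy()
        truth = np.array((spec.intercept,) + spec.true_coefficients)
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(200):
            res = sm.OLS(y0 + rng.normal(0, 0.5, len(y0)), X).fit()
            if np.all(np.abs(res.params - truth) <= 4 * res.bse):
                hits += 1
        assert hits / 200 >= 0.95


class TestPredict:
    def test_constant_model(self):
        model = QsprModel("3d", KIND_SYMBOLS["3d"], (0.0, 0.0, 0.0), 7.0)
        assert predict(model, {"q_H": 1.0, "q_O": -1.0, "q_C1": 0.5}) == 7.0

    def test_single_descriptor_projection(self):
        model = QsprModel("3d", KIND_SYMBOLS["3d"], (1.0, 0.0, 0.0), 0.0)
        assert predict(model, {"q_H": 0.3, "q_O": 9.0, "q_C1": -9.0}) == pytest.approx(0.3)

    def test_missing_descriptor_raises(self):
        model = QsprModel("3d", KIND_SYMBOLS["3d"], (1.0, 1.0, 1.0), 0.0)
        with pytest.raises(DescriptorError):
            predict(model, {"q_H": 0.3, "q_O": 0.1})

    def test_model_document_round_trip_reproduces_predictions(self, noisy, tmp_path):
        (desc, pka), _ = noisy
        model, _ = fit_mlr(desc, pka, "5d")
        path = tmp_path / "model.json"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(
            predict(model, desc), predict(reloaded, desc)
        )


class TestCooksDistance:
    def test_matches_leave_one_out_oracle(self, ref_params):
        """D_i must equal sum_j (yhat_j - yhat_j^(i))^2 / (m s^2) from an
        explicit n-times refit."""
        spec = phenol_study_spec(noise_sigma=0.5, seed=8, n_molecules=30)
        desc, pka = gen_qspr_dataset(spec, ref_params)
        d = cooks_distances(desc, pka, "3d")
        merged = desc.merge(pka, on="molecule_id").sort_values("molecule_id").reset_index(drop=True)
        X = np.column_stack(
            [np.ones(len(merged))] + [merged[s] for s in KIND_SYMBOLS["3d"]]
        )
        y = merged["pka_exp"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        yhat = X @ beta
        m = X.shape[1]
        s2 = ((y - yhat) ** 2).sum() / (len(y) - m)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            beta_i = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            d_oracle = ((yhat - X @ beta_i) ** 2).sum() / (m * s2)
            assert d.iloc[i] == pytest.approx(d_oracle, abs=1e-8)

    def test_invariant_to_descriptor_column_order(self, noisy):
        (desc, pka), _ = noisy
        d1 = cooks_distances(desc, pka, "5d")
        shuffled = desc[list(reversed(desc.columns))]
        d2 = cooks_distances(shuffled, pka, "5d")
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestOutlierExclusion:
    def test_ten_percent_of_74_is_7(self, noisy):
        (desc, pka), _ = noisy
        report = remove_outliers_and_refit(desc, pka, "3d")
        assert len(report.outlier_ids) == 7
        assert report.refit.n == 67

    def test_injected_gross_outlier_ranks_first(self, noisy):
        (desc, pka), _ = noisy
        pka2 = pka.copy()
        target = pka2["molecule_id"].iloc[30]
        pka2.loc[pka2["molecule_id"] == target, "pka_exp"] += 15.0
        report = remove_outliers_and_refit(desc, pka2, "3d")
        assert report.outlier_ids[0] == target

    def test_removing_outliers_improves_fit(self, noisy):
        (desc, pka), _ = noisy
        report = remove_outliers_and_refit(desc, pka, "3d")
        assert report.refit.rmse <= report.full_report.rmse

    def test_fraction_zero_is_identity(self, noisy):
        (desc, pka), _ = noisy
        report = remove_outliers_and_refit(desc, pka, "3d", fraction=0.0)
        assert report.outlier_ids == ()
        assert report.refit == report.full_report


class TestCrossValidation:
    def test_fold_sizes_for_74_molecules(self, noisy):
        (desc, pka), _ = noisy
        cv = cross_validate(desc, pka, "5d", k_folds=5, seed=17)
        sizes = sorted(len(f.test_ids) for f in cv.folds)
        assert sizes == [14, 15, 15, 15, 15]

    def test_folds_partition_the_dataset(self, noisy):
        (desc, pka), _ = noisy
        cv = cross_validate(desc, pka, "5d", k_folds=5, seed=17)
        all_ids = [i for f in cv.folds for i in f.test_ids]
        assert len(all_ids) == len(set(all_ids)) == len(pka)
        assert set(all_ids) == set(pka["molecule_id"])

    def test_same_seed_reproduces_report(self, noisy):
        (desc, pka), _ = noisy
        cv1 = cross_validate(desc, pka, "5d", k_folds=5, seed=4)
        cv2 = cross_validate(desc, pka, "5d", k_folds=5, seed=4)
        assert cv1.assignment == cv2.assignment
        assert cv1.folds == cv2.folds

    def test_different_seed_changes_assignment(self, noisy):
        (desc, pka), _ = noisy
        cv1 = cross_validate(desc, pka, "5d", k_folds=5, seed=4)
        cv2 = cross_validate(desc, pka, "5d", k_folds=5, seed=5)
        assert cv1.assignment != cv2.assignment

    def test_noiseless_data_gives_perfect_test_folds(self, noiseless):
        (desc, pka), _ = noiseless
        cv = cross_validate(desc, pka, "5d", k_folds=5, seed=1)
        for fold in cv.folds:
            assert fold.test_report.r2 == pytest.approx(1.0, abs=1e-9)

    def test_stratification_balances_fold_means(self, noisy):
        # every fold's mean pKa within 1 unit of the global mean
        (desc, pka), _ = noisy
        assignment = assign_stratified_folds(pka, 5, seed=11)
        global_mean = pka["pka_exp"].mean()
        by_fold = pka.assign(fold=pka["molecule_id"].map(assignment))
        for _, grp in by_fold.groupby("fold"):
            assert abs(grp["pka_exp"].mean() - global_mean) < 1.0

    def test_too_few_molecules_for_folds(self, ref_params):
        spec = phenol_study_spec(noise_sigma=0.1, seed=2, n_molecules=8)
        desc, pka = gen_qspr_dataset(spec, ref_params)
        with pytest.raises(DegenerateFoldError):
            cross_validate(desc, pka, "5d", k_folds=5, seed=0)

    def test_evaluate_on_held_out_set_uses_pearson_r2(self, noisy):
        (desc, pka), _ = noisy
        model, _ = fit_mlr(desc.iloc[:50], pka.iloc[:50], "5d")
        report = evaluate(model, desc.iloc[50:], pka.iloc[50:])
        pred = predict(model, desc.iloc[50:].sort_values("molecule_id"))
        obs = pka.iloc[50:].sort_values("molecule_id")["pka_exp"].to_numpy()
        assert report.r2 == pytest.approx(np.corrcoef(pred, obs)[0, 1] ** 2)
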