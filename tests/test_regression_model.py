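"""OLS fitting, prediction, correlation, cross-validation and importance."""

import numpy as np
import pytest

from gdvb.features import BValueVector, FeatureMatrix, zscore_columns
from gdvb.regression_model import (
    CoefficientSet,
    contact_preset,
    crossvalidate,
    evaluate_correlation,
    fit_linear,
    predict,
    read_coefficients,
    rescale_to_raw,
    variable_importance,
    write_coefficients,
)

N_ORBITS = 15


def zscored_design(n, seed, n_cols=N_ORBITS):
    rng = np.random.default_rng(seed)
    return zscore_columns(FeatureMatrix(rng.normal(size=(n, n_cols)))).values


class TestFitLinear:
    def test_noiseless_recovery(self):
        X = zscored_design(400, seed=0)
        beta = np.linspace(-0.5, 0.4, N_ORBITS)
        y = 0.3 + X @ beta
        rep = fit_linear(FeatureMatrix(X), BValueVector(y, scale="normalized"))
        np.testing.assert_allclose(rep.coefficients.beta_vector(), beta, atol=1e-8)
        assert abs(rep.coefficients.intercept - 0.3) < 1e-8
        assert rep.r_squared > 1 - 1e-12

    def test_noisy_recovery_within_confidence_intervals(self):
        # known truth, sigma = 0.3, N = 5000: the 99% CI should cover the
        # true beta in at least 14 of 15 columns
        X = zscored_design(5000, seed=1)
        beta = np.linspace(-0.4, 0.4, N_ORBITS)
        rng = np.random.default_rng(2)
        y = X @ beta + rng.normal(0, 0.3, size=5000)
        rep = fit_linear(FeatureMatrix(X), BValueVector(y, scale="normalized"))
        est = rep.coefficients.beta_vector()
        se = np.abs(est / rep.t_statistics)
        covered = np.abs(est - beta) <= 2.576 * se
        assert covered.sum() >= 14

    def test_contact_model_slope_recovery(self):
        # single-column design mirroring the published contact fit:
        # slope -0.64, intercept 0
        X = zscored_design(5000, seed=3, n_cols=1)
        rng = np.random.default_rng(4)
        y = -0.64 * X[:, 0] + rng.normal(0, 0.3, size=5000)
        rep = fit_linear(
            FeatureMatrix(X), BValueVector(y, scale="normalized"), model_kind="contact"
        )
        est = rep.coefficients.betas[0]
        se = abs(est / rep.t_statistics[0])
        assert abs(est + 0.64) <= 2.576 * se
        assert abs(rep.coefficients.intercept) < 0.02

    def test_rank_deficient_design_names_columns(self):
        X = zscored_design(100, seed=5)
        X[:, 7] = X[:, 4]  # exact duplicate
        with pytest.raises(ValueError, match="O4.*O7|O7.*O4|collinear"):
            fit_linear(FeatureMatrix(X), BValueVector(X[:, 0], scale="normalized"))

    def test_too_few_observations(self):
        X = zscored_design(10, seed=6)
        with pytest.raises(ValueError, match="observations"):
            fit_linear(FeatureMatrix(X), BValueVector(X[:, 0]))


class TestPredict:
    def test_zero_features_give_intercept(self):
        coeffs = CoefficientSet(
            intercept=0.7, betas={k: 1.0 for k in range(N_ORBITS)}, model_kind="gdv"
        )
        out = predict(FeatureMatrix(np.zeros((3, N_ORBITS))), coeffs)
        np.testing.assert_allclose(out, 0.7)

    def test_contact_preset_published_slope(self):
        # standardized contact count of 1.0 -> predicted normalized B -0.64
        preset = contact_preset()
        assert preset.intercept == 0.0 and preset.cutoff == 7.0
        out = predict(FeatureMatrix(np.array([[1.0]])), preset)
        np.testing.assert_allclose(out, [-0.64])

    def test_residuals_orthogonal_to_design(self):
        X = zscored_design(300, seed=7)
        rng = np.random.default_rng(8)
        y = X @ np.linspace(-1, 1, N_ORBITS) + rng.normal(0, 0.5, 300)
        rep = fit_linear(FeatureMatrix(X), BValueVector(y, scale="normalized"))
        resid = y - predict(FeatureMatrix(X), rep.coefficients)
        assert abs(resid.mean()) < 1e-10
        assert np.all(np.abs(resid @ X) < 1e-6)

    def test_column_mismatch(self):
        with pytest.raises(ValueError, match="columns"):
            predict(FeatureMatrix(np.zeros((3, 4))), contact_preset())


class TestEvaluateCorrelation:
    def test_self_and_negation(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert evaluate_correlation(v, v) == pytest.approx(1.0)
        assert evaluate_correlation(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = [2, 5, 1, 9, 4, 7, 3, 8, 6, 10]
        y = [1.5, 4.0, 2.5, 8.0, 3.0, 6.5, 2.0, 9.0, 5.5, 9.5]
        # frozen from the raw sum formula computed independently
        assert evaluate_correlation(x, y) == pytest.approx(
            0.9568868404744106, abs=1e-12
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 50))
        r = evaluate_correlation(a, b)
        assert evaluate_correlation(3.0 * a + 1.0, b) == pytest.approx(r, abs=1e-12)
        assert evaluate_correlation(a, 0.5 * b - 4.0) == pytest.approx(r, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 points"):
            evaluate_correlation([1.0, 2.0], [1.0, 2.0])


def make_entries(n_entries, n_atoms, sigma, base_seed=100):
    beta = np.linspace(-0.5, 0.3, N_ORBITS)
    entries = []
    for i in range(n_entries):
        X = zscored_design(n_atoms, seed=base_seed + i)
        rng = np.random.default_rng(base_seed + 1000 + i)
        y = X @ beta + rng.normal(0, sigma, size=n_atoms)
        entries.append(
            (FeatureMatrix(X), BValueVector(y, scale="normalized"))
        )
    return entries, beta


class TestCrossvalidate:
    def test_identical_entries_give_identical_r(self):
        entry = make_entries(1, 200, sigma=0.4)[0][0]
        report = crossvalidate([entry] * 10, k=10, seed=0)
        rs = report.per_entry["pearson_r"].to_numpy()
        np.testing.assert_allclose(rs, rs[0], atol=1e-12)

    def test_noiseless_entries_give_r_one(self):
        entries, _ = make_entries(12, 150, sigma=0.0)
        report = crossvalidate(entries, k=10, seed=0)
        np.testing.assert_allclose(report.per_entry["pearson_r"], 1.0, atol=1e-9)

    def test_mean_r_matches_monte_carlo_oracle(self):
        # CV estimate vs a direct simulation of corr(signal+noise, signal)
        sigma = 0.5
        entries, beta = make_entries(20, 800, sigma=sigma)
        report = crossvalidate(entries, k=10, seed=1)
        rng = np.random.default_rng(123)
        oracle = []
        for _ in range(40):
            X = zscore_columns(
                FeatureMatrix(rng.normal(size=(800, N_ORBITS)))
            ).values
            signal = X @ beta
            noisy = signal + rng.normal(0, sigma, 800)
            oracle.append(np.corrcoef(noisy, signal)[0, 1])
        assert report.per_entry["pearson_r"].mean() == pytest.approx(
            np.mean(oracle), abs=0.05
        )

    def test_fold_assignment_reproducible(self):
        entries, _ = make_entries(10, 120, sigma=0.3)
        r1 = crossvalidate(entries, k=5, seed=7).per_entry
        r2 = crossvalidate(entries, k=5, seed=7).per_entry
        assert r1.equals(r2)
        r3 = crossvalidate(entries, k=5, seed=8).per_entry
        assert not r1["pearson_r"].equals(r3["pearson_r"])

    def test_fewer_entries_than_folds(self):
        entries, _ = make_entries(3, 100, sigma=0.1)
        with pytest.raises(ValueError, match="entries"):
            crossvalidate(entries, k=10)


class TestVariableImportance:
    def test_dominant_predictor_scores_100(self):
        rng = np.random.default_rng(11)
        X = zscored_design(600, seed=11)
        y = 2.0 * X[:, 8] + rng.normal(0, 0.2, 600)
        rep = fit_linear(FeatureMatrix(X), BValueVector(y, scale="normalized"))
        table = variable_importance(rep)
        assert table.iloc[0]["orbit"] == "O8"
        assert table.iloc[0]["importance"] == 100.0

    def test_top3_structure(self):
        # strong O4, medium O1 and O5, rest zero: the top-3 set must match
        rng = np.random.default_rng(12)
        X = zscored_design(4000, seed=12)
        beta = np.zeros(N_ORBITS)
        beta[4], beta[1], beta[5] = -0.6, -0.3, -0.3
        y = X @ beta + rng.normal(0, 0.3, 4000)
        rep = fit_linear(FeatureMatrix(X), BValueVector(y, scale="normalized"))
        top3 = set(variable_importance(rep).head(3)["orbit"])
        assert top3 == {"O4", "O1", "O5"}


class TestCoefficientIO:
    def test_round_trip(self, tmp_path):
        coeffs = CoefficientSet(
            intercept=0.123456789,
            betas={k: -0.01 * k - 0.005 for k in range(N_ORBITS)},
            model_kind="gdv",
            cutoff=5.0,
            provenance="fitted",
        )
        path = tmp_path / "model.coeffs"
        write_coefficients(coeffs, path)
        rt = read_coefficients(path)
        assert rt.model_kind == "gdv" and rt.cutoff == 5.0
        assert rt.intercept == coeffs.intercept
        np.testing.assert_array_equal(rt.beta_vector(), coeffs.beta_vector())

    def test_beta_cardinality_enforced(self):
        with pytest.raises(ValueError, match="contact"):
            CoefficientSet(0.0, {0: -0.5, 1: 0.1}, model_kind="contact")
        with pytest.raises(ValueError, match="gdv"):
            CoefficientSet(0.0, {0: -0.5}, model_kind="gdv")


def test_rescale_to_raw():
    out = rescale_to_raw([-1.0, 0.0, 2.0], mean_b=30.0, sd_b=10.0)
    np.testing.assert_allclose(out, [20.0, 30.0, 50.0])
    with pytest.raises(ValueError):
        rescale_to_raw([0.0], 30.0, 0.0)
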