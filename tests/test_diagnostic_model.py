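import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import methylmark as mm
from methylmark.core_io import BetaMatrix, SampleSheet
from methylmark.diagnostic_model import (
    DiagnosticModel,
    compute_auc,
    evaluate_cohort,
    fit_logistic,
    predict_proba,
)


def _study(values, states, cohort="C"):
    """One-cohort study from a sites x samples array and tumor/normal states."""
    values = np.asarray(values, dtype=float)
    sites = [f"cg{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    matrix = BetaMatrix(pd.DataFrame(values, index=sites, columns=samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "cohort_id": cohort,
                "cancer_type": "COAD",
                "tissue_state": states,
                "stage": "NA",
                "cimp": "NA",
            }
        )
    )
    return matrix, sheet, sites


def pairwise_auc(scores, labels):
    """Oracle: enumerate every tumor-normal pair."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    tot = hits = 0.0
    for st in s[y]:
        for sn in s[~y]:
            tot += 1
            hits += 1.0 if st > sn else (0.5 if st == sn else 0.0)
    return hits / tot


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_mixed_with_tie(self):
        # pairs: (.9>.4)=1, (.9>.1)=1, (.4==.4)=.5, (.4>.1)=1 -> 3.5/4
        assert compute_auc([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_equals_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 12)
            scores = np.round(rng.random(n), 1)  # coarse grid injects ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert compute_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a1 = compute_auc(scores, labels)
        a2 = compute_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.random(20)
        labels = np.array([1] * 8 + [0] * 12)
        assert compute_auc(scores, labels) == pytest.approx(
            1.0 - compute_auc(scores, 1 - labels), abs=1e-12
        )


class TestFitLogistic:
    def test_symmetric_data_predicts_half_at_midpoint(self):
        # marker values mirror-symmetric about 0.5 across the two classes
        matrix, sheet, sites = _study(
            [[0.2, 0.3, 0.7, 0.8]], ["normal", "normal", "tumor", "tumor"]
        )
        model = fit_logistic(matrix, sheet, sites, "C", ridge_lambda=0.01)
        probe = BetaMatrix(pd.DataFrame([[0.5]], index=sites, columns=["q"]))
        assert predict_proba(model, probe, ["q"]).iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.random((2, 12))
        states = ["tumor"] * 6 + ["normal"] * 6
        m1, s1, sites = _study(vals, states)
        perm = rng.permutation(12)
        m2, s2, _ = _study(vals[:, perm], [states[i] for i in perm])
        a = fit_logistic(m1, s1, sites, "C", 0.05)
        b = fit_logistic(m2, s2, sites, "C", 0.05)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-7)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-7)

    def test_matches_direct_objective_minimizer(self):
        # independent oracle: numeric minimization of the penalized NLL
        matrix, sheet, sites = _study(
            [[0.2, 0.3, 0.7, 0.8]], ["normal", "normal", "tumor", "tumor"]
        )
        lam = 0.1
        x = matrix.values.to_numpy()[0]
        y = np.array([0.0, 0.0, 1.0, 1.0])

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * lam * theta[1] ** 2

        # coarse grid scan, then local refinement from the best grid point
        b0s, b1s = np.meshgrid(np.arange(-8, 8, 0.1), np.arange(-15, 15, 0.1))
        grid = np.stack([b0s.ravel(), b1s.ravel()], axis=1)
        vals_grid = np.array([nll(t) for t in grid])
        best = minimize(
            nll, grid[vals_grid.argmin()], method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13},
        )
        model = fit_logistic(matrix, sheet, sites, "C", lam)
        assert model.intercept == pytest.approx(best.x[0], abs=1e-4)
        assert model.coefficients[0] == pytest.approx(best.x[1], abs=1e-4)

    def test_agrees_with_sklearn_ridge_logistic(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        vals = np.clip(rng.random((3, 40)) + np.tile([0.0] * 20 + [0.25] * 20, (3, 1)), 0, 1)
        states = ["normal"] * 20 + ["tumor"] * 20
        matrix, sheet, sites = _study(vals, states)
        lam = 0.5
        model = fit_logistic(matrix, sheet, sites, "C", lam)
        sk = LogisticRegression(C=1.0 / lam, solver="lbfgs", tol=1e-10, max_iter=10000)
        sk.fit(vals.T, np.array(states) == "tumor")
        assert model.intercept == pytest.approx(sk.intercept_[0], abs=1e-4)
        assert np.allclose(model.coefficients, sk.coef_[0], atol=1e-4)

    def test_separable_unpenalized_fit_raises_advice(self):
        matrix, sheet, sites = _study(
            [[0.1, 0.1, 0.9, 0.9]], ["normal", "normal", "tumor", "tumor"]
        )
        with pytest.raises(RuntimeError, match="ridge_lambda > 0"):
            fit_logistic(matrix, sheet, sites, "C", ridge_lambda=0.0)

    def test_single_class_cohort_rejected(self):
        matrix, sheet, sites = _study([[0.1, 0.2]], ["tumor", "tumor"])
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(matrix, sheet, sites, "C")

    def test_missing_values_imputed_with_training_means(self):
        vals = np.array([[0.2, np.nan, 0.8, 0.7]])
        matrix, sheet, sites = _study(vals, ["normal", "normal", "tumor", "tumor"])
        model = fit_logistic(matrix, sheet, sites, "C", 0.1)
        assert model.training_means[0] == pytest.approx(np.nanmean(vals))
        p = predict_proba(model, matrix, ["s1"])  # imputes stored mean
        probe = BetaMatrix(
            pd.DataFrame([[np.nanmean(vals)]], index=sites, columns=["q"])
        )
        assert p.iloc[0] == pytest.approx(predict_proba(model, probe, ["q"]).iloc[0])

    def test_json_round_trip(self, tmp_path, model1):
        p = tmp_path / "model.json"
        model1.to_json(p)
        back = DiagnosticModel.from_json(p)
        assert back == model1


class TestPredictProba:
    def test_zero_model_gives_half(self):
        model = DiagnosticModel(("cg0",), 0.0, (0.0,), 0.0, "C", training_means=(0.5,))
        matrix = BetaMatrix(pd.DataFrame([[0.3, 0.9]], index=["cg0"], columns=["a", "b"]))
        assert (predict_proba(model, matrix, ["a", "b"]) == 0.5).all()

    def test_logistic_link_value(self):
        # linear score 0.5 -> 1/(1+e^-0.5)
        model = DiagnosticModel(("cg0",), 0.0, (1.0,), 0.0, "C", training_means=(0.5,))
        matrix = BetaMatrix(pd.DataFrame([[0.5]], index=["cg0"], columns=["a"]))
        assert predict_proba(model, matrix, ["a"]).iloc[0] == pytest.approx(0.6224593312)

    def test_probability_monotone_in_score(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.random(20))
        model = DiagnosticModel(("cg0",), -1.0, (3.0,), 0.0, "C", training_means=(0.5,))
        matrix = BetaMatrix(
            pd.DataFrame([x], index=["cg0"], columns=[f"s{i}" for i in range(20)])
        )
        p = predict_proba(model, matrix, matrix.sample_ids).to_numpy()
        assert (np.diff(p) >= 0).all() and ((p > 0) & (p < 1)).all()

    def test_unknown_sample_rejected(self, model1, bundle1):
        with pytest.raises(KeyError):
            predict_proba(model1, bundle1.matrix, ["no_such_sample"])


class TestEvaluateCohort:
    def test_validation_cohorts_reach_high_auc(self, bundle1, model1):
        aucs = [
            evaluate_cohort(model1, bundle1.matrix, bundle1.sheet, f"VAL{i}").auc
            for i in range(1, 6)
        ]
        assert sorted(aucs)[2] >= 0.93  # majority of the five cohorts

    def test_rectal_transfer_cohort(self, bundle1, model1):
        m = evaluate_cohort(model1, bundle1.matrix, bundle1.sheet, "RECTAL")
        assert m.auc >= 0.93
        assert (m.n_tumor, m.n_normal) == (40, 20)

    def test_positive_coefficients_on_planted_markers(self, model1):
        assert all(c > 0 for c in model1.coefficients)

    def test_perfectly_scored_cohort(self):
        matrix, sheet, sites = _study(
            [[0.95, 0.9, 0.05, 0.1]], ["tumor", "tumor", "normal", "normal"]
        )
        model = fit_logistic(matrix, sheet, sites, "C", 1e-3)
        m = evaluate_cohort(model, matrix, sheet, "C")
        assert (m.auc, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
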