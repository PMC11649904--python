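import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from modfuse.core_io import Config, ValidationError
from modfuse.integrate import (
    FFSTrace,
    auroc,
    choose_complexity,
    class_weight_vector,
    concat_integrate,
    ffs_integrate,
    fit_weighted_elastic_net,
    platt_apply,
    platt_fit,
    threshold_select,
    tune_elastic_net,
    weighted_log_loss,
)
from modfuse.select import make_resample_plan


def _xy(rng, n=200, p=8, effect=0.8, case_frac=0.25):
    y = pd.Series((rng.random(n) < case_frac).astype(int),
                  index=[f"S{i:03d}" for i in range(n)])
    X = pd.DataFrame(rng.standard_normal((n, p)), index=y.index,
                     columns=[f"f{j}" for j in range(p)])
    X.iloc[:, 0] += effect * y.to_numpy()
    return X, y


class TestWeightedLogLoss:
    def test_coin_flip_is_ln2(self):
        assert weighted_log_loss([1, 0], [0.5, 0.5]) == pytest.approx(
            np.log(2))

    def test_perfect_predictions_near_zero(self):
        assert weighted_log_loss([1, 0], [1.0, 0.0]) < 1e-10

    def test_balanced_weights_invariant_to_duplicating_controls(self, rng):
        y = np.array([1, 1, 0, 0, 0])
        p = rng.uniform(0.1, 0.9, 5)
        w = class_weight_vector(y)
        base = weighted_log_loss(y, p, w)
        y2 = np.concatenate([y, y[y == 0]])
        p2 = np.concatenate([p, p[y == 0]])
        w2 = class_weight_vector(y2)
        assert weighted_log_loss(y2, p2, w2) == pytest.approx(base)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1]) == pytest.approx(0.75)

    def test_ties_count_half(self):
        assert auroc([1, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_trapezoidal_integration(self, rng):
        from sklearn.metrics import roc_curve

        for _ in range(100):
            n = int(rng.integers(10, 80))
            y = np.zeros(n, dtype=int)
            y[: max(1, int(rng.integers(1, n)))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            s = rng.standard_normal(n)
            fpr, tpr, _ = roc_curve(y, s)
            expected = np.trapezoid(tpr, fpr)
            assert abs(auroc(y, s) - expected) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([1, 1], [0.1, 0.2])


class TestElasticNet:
    def test_unpenalised_matches_generic_convex_optimiser(self, rng):
        X, y = _xy(rng, n=150, p=3)
        w = class_weight_vector(y.to_numpy())
        model = fit_weighted_elastic_net(X, y, alpha=0.5, lam=0.0)

        def objective(beta):
            z = X.to_numpy() @ beta[1:] + beta[0]
            ll = y.to_numpy() * np.logaddexp(0, -z) + (
                1 - y.to_numpy()) * np.logaddexp(0, z)
            return float((w * ll).sum() / w.sum())

        res = optimize.minimize(objective, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert model.intercept == pytest.approx(res.x[0], abs=1e-3)
        assert np.allclose(model.coefficients, res.x[1:], atol=1e-3)

    def test_full_shrinkage_intercept_is_weighted_log_odds(self, rng):
        X, y = _xy(rng, n=200, p=4, effect=0.0)
        model = fit_weighted_elastic_net(X, y, alpha=0.5, lam=50.0)
        assert np.allclose(model.coefficients, 0.0)
        # balanced weights equalise the classes: weighted log-odds is 0
        assert model.intercept == pytest.approx(0.0, abs=0.05)

    def test_lasso_zeroes_noise_features(self, rng):
        X, y = _xy(rng, n=300, p=10, effect=1.5)
        model = fit_weighted_elastic_net(X, y, alpha=1.0, lam=0.05)
        assert model.coefficients["f0"] != 0.0
        assert (model.coefficients.iloc[1:] == 0.0).sum() >= 5

    def test_invalid_hyperparameters_rejected(self, rng):
        X, y = _xy(rng, n=50)
        with pytest.raises(ValidationError):
            fit_weighted_elastic_net(X, y, alpha=1.5, lam=0.1)


class TestTuneElasticNet:
    def test_default_grid_enumerates_400_combinations(self, rng):
        X, y = _xy(rng, n=100, p=3)
        plan = make_resample_plan(y, 1, seed=0)
        res = tune_elastic_net(X.loc[plan.splits[0][0]],
                               y.loc[plan.splits[0][0]],
                               plan.folds[0], grid_size=20)
        assert res.n_combinations == 400
        assert len(res.cv_table) == 400

    def test_strong_signal_avoids_maximum_lambda(self, rng):
        X, y = _xy(rng, n=250, p=4, effect=2.0)
        plan = make_resample_plan(y, 1, seed=1)
        tr = plan.splits[0][0]
        res = tune_elastic_net(X.loc[tr], y.loc[tr], plan.folds[0],
                               grid_size=6)
        assert res.lam < 1.0

    def test_degenerate_grid_returns_origin(self, rng):
        X, y = _xy(rng, n=100, p=3)
        plan = make_resample_plan(y, 1, seed=2)
        tr = plan.splits[0][0]
        res = tune_elastic_net(X.loc[tr], y.loc[tr], plan.folds[0],
                               grid_size=1)
        assert (res.alpha, res.lam) == (0.0, 0.0)

    def test_fold_missing_a_class_rejected(self, rng):
        X, y = _xy(rng, n=40, p=2)
        bad_folds = [(np.arange(20), np.arange(20, 40))]
        y.iloc[20:] = 0  # validation fold single-class
        with pytest.raises(ValidationError):
            tune_elastic_net(X, y, bad_folds, grid_size=2)


class TestPlatt:
    def test_calibration_preserves_auroc_exactly(self, rng):
        y = (rng.random(300) < 0.3).astype(int)
        s = rng.standard_normal(300) + y
        cal = platt_fit(s, y)
        assert auroc(y, platt_apply(cal, s)) == auroc(y, s)

    def test_well_calibrated_inputs_near_identity(self, rng):
        n = 2000
        z = rng.standard_normal(n) * 2
        p = 1 / (1 + np.exp(-z))
        y = (rng.random(n) < p).astype(int)
        cal = platt_fit(z, y)
        assert cal.slope == pytest.approx(1.0, abs=0.1)
        assert cal.intercept == pytest.approx(0.0, abs=0.1)

    def test_improves_brier_on_miscalibrated_scores(self, rng):
        wins = 0
        for rep in range(25):
            n = 1000
            z = rng.standard_normal(n) * 2
            p_true = 1 / (1 + np.exp(-z))
            y = (rng.random(n) < p_true).astype(int)
            shifted = 1 / (1 + np.exp(-(0.3 * z + 1.5)))  # miscalibrated
            cal = platt_fit(shifted, y)
            fixed = platt_apply(cal, shifted)
            brier_raw = np.mean((shifted - y) ** 2)
            brier_cal = np.mean((fixed - y) ** 2)
            wins += int(brier_cal <= brier_raw + 1e-9)
        assert wins == 25

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            platt_fit(np.ones(10), np.repeat([0, 1], 5))


class TestThresholdSelect:
    def test_planted_features_mostly_selected(self, rng):
        from modfuse.core_io import FeatureMatrix, PhenotypeTable

        n = 300
        y = np.zeros(n, dtype=int)
        y[:75] = 1
        X = rng.standard_normal((n, 100))
        X[:, :20] += y[:, None]  # 1 SD shift on 20 features
        ids = [f"S{i}" for i in range(n)]
        fm = FeatureMatrix("transcriptomic", pd.DataFrame(
            X, index=ids, columns=[f"g{j:03d}" for j in range(100)]))
        pheno = PhenotypeTable(pd.DataFrame(
            {"label": y}, index=pd.Index(ids, name="sample_id")))
        chosen = threshold_select(fm, pheno, p_cut=0.05)
        planted = {f"g{j:03d}" for j in range(20)}
        assert len(planted & set(chosen)) >= 16  # >= 80% power

    def test_null_selection_near_alpha(self, rng):
        from modfuse.core_io import FeatureMatrix, PhenotypeTable

        n, p = 400, 1000
        y = np.zeros(n, dtype=int)
        y[:100] = 1
        X = rng.standard_normal((n, p))
        ids = [f"S{i}" for i in range(n)]
        fm = FeatureMatrix("transcriptomic", pd.DataFrame(
            X, index=ids, columns=[f"g{j:04d}" for j in range(p)]))
        pheno = PhenotypeTable(pd.DataFrame(
            {"label": y}, index=pd.Index(ids, name="sample_id")))
        n_chosen = len(threshold_select(fm, pheno, p_cut=0.05))
        se = np.sqrt(p * 0.05 * 0.95)
        assert abs(n_chosen - 0.05 * p) <= 3 * se + 5


class TestChooseComplexity:
    def _trace(self, dists):
        rows = []
        for k, values in enumerate(dists, start=1):
            rows += [(i, k, "m", 0.5, v) for i, v in enumerate(values)]
        return FFSTrace(records=pd.DataFrame(
            rows, columns=["resample", "k", "modality_added", "cv_auroc",
                           "test_auroc"]))

    def test_step_then_plateau(self, rng):
        base = rng.normal(0.6, 0.02, 30)
        trace = self._trace([base, base + 0.1,
                             base + 0.1 + rng.normal(0, 0.005, 30)])
        assert choose_complexity(trace) == 2

    def test_flat_distributions_give_one(self, rng):
        base = rng.normal(0.5, 0.03, 30)
        trace = self._trace([base, rng.normal(0.5, 0.03, 30),
                             rng.normal(0.5, 0.03, 30)])
        assert choose_complexity(trace) == 1

    def test_monotone_improvement_gives_max(self, rng):
        dists = [rng.normal(0.5 + 0.08 * k, 0.02, 30) for k in range(4)]
        trace = self._trace(dists)
        assert choose_complexity(trace) == 4

    def test_single_complexity_returns_one(self, rng):
        trace = self._trace([rng.normal(0.6, 0.02, 12)])
        assert choose_complexity(trace) == 1


class TestIntegrationStrategies:
    def test_concat_single_panel_equals_ffs_k1(self, rng):
        X, y = _xy(rng, n=200, p=6)
        panels = {"metabolomic": X}
        cfg = Config(grid_size=4, master_seed=3)
        plan = make_resample_plan(y, 3, seed=4)
        trace = ffs_integrate(panels, y, plan, None, cfg)
        con = concat_integrate(panels, y, plan, cfg)
        ffs_auc = trace.records.sort_values("resample")["test_auroc"]
        con_auc = con.sort_values("resample")["test_auroc"]
        assert np.allclose(ffs_auc.to_numpy(), con_auc.to_numpy())

    def test_forced_baseline_is_first(self, rng):
        X, y = _xy(rng, n=160, p=4, effect=1.0)
        noise = pd.DataFrame(rng.standard_normal((160, 4)), index=y.index,
                             columns=[f"n{j}" for j in range(4)])
        panels = {"clinical": noise, "metabolomic": X}
        cfg = Config(grid_size=3, master_seed=1)
        plan = make_resample_plan(y, 2, seed=5)
        trace = ffs_integrate(panels, y, plan, "clinical", cfg)
        firsts = trace.records.loc[trace.records["k"] == 1, "modality_added"]
        assert (firsts == "clinical").all()

    def test_cv_score_of_choice_dominates_rejected(self, rng):
        """The chosen modality's inner-CV score is the step maximum."""
        X, y = _xy(rng, n=160, p=4, effect=1.0)
        noise = pd.DataFrame(rng.standard_normal((160, 4)), index=y.index,
                             columns=[f"n{j}" for j in range(4)])
        panels = {"metabolomic": X, "transcriptomic": noise}
        cfg = Config(grid_size=3, master_seed=2)
        plan = make_resample_plan(y, 3, seed=6)
        trace = ffs_integrate(panels, y, plan, None, cfg)
        firsts = trace.records.loc[trace.records["k"] == 1, "modality_added"]
        assert (firsts == "metabolomic").sum() >= 2
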