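import numpy as np
import pandas as pd
import pytest

from ipqtl.human_genetics import (
    HumanCohort,
    associate_snv,
    bootstrap_select_snvs,
    choose_best_model,
    encode_genetic_model,
    evaluate_on_test,
    filter_by_imputation,
    fit_lasso_risk_model,
    label_cda_cases,
    logistic_lrt_pvalues,
    optimize_cutoff_youden,
)
from ipqtl.simulate import HumanConfig, simulate_human_cohort


def _cohort(dosages, outcome=None, r2=None):
    df = pd.DataFrame(np.atleast_2d(dosages).astype(float))
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return HumanCohort(
        dosages=df,
        imputation_r2=None if r2 is None else pd.Series(r2, index=df.columns),
        outcome=None if outcome is None else np.asarray(outcome),
    )


class TestFilter:
    def test_boundary_strict_less_than(self):
        c = _cohort(np.zeros((3, 4)), r2=[0.9, 0.69, 0.70, 0.71])
        with pytest.warns(UserWarning):
            out = filter_by_imputation(c)
        assert list(out.dosages.columns) == ["s0", "s2", "s3"]  # 0.70 kept

    def test_all_perfect_unchanged(self):
        c = _cohort(np.zeros((3, 4)), r2=[1.0] * 4)
        out = filter_by_imputation(c)
        assert out.dosages.shape[1] == 4

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        r2 = rng.uniform(0, 1, 50)
        c = _cohort(np.zeros((2, 50)), r2=r2)
        k_below = int((r2 < 0.7).sum())  # independent hand count
        if k_below:
            with pytest.warns(UserWarning):
                out = filter_by_imputation(c)
        else:
            out = filter_by_imputation(c)
        assert out.dosages.shape[1] == 50 - k_below


class TestLabelCases:
    def test_boundary_inclusive(self):
        labels, valid = label_cda_cases([60.0], [55.0])
        assert labels[0] == 1 and valid[0]

    def test_below_threshold_control(self):
        labels, _ = label_cda_cases([60.0], [55.5])
        assert labels[0] == 0

    def test_counting_oracle_ten_patients(self):
        baseline = np.array([60, 65, 55, 70, 62, 58, 61, 66, 59, 63], dtype=float)
        drops = np.array([5.0, 4.9, 10.0, 0.0, -2.0, 5.1, 3.0, 20.0, 4.99, 6.0])
        followup = baseline - drops
        labels, valid = label_cda_cases(baseline, followup)
        assert valid.all()
        assert labels.sum() == int((drops >= 5).sum()) == 5

    def test_any_timepoint_qualifies(self):
        baseline = np.array([60.0, 60.0])
        followup = np.array([[58.0, 54.0], [58.0, 59.0]])  # (n, t)
        labels, _ = label_cda_cases(baseline, followup)
        assert list(labels) == [1, 0]

    def test_missing_followup_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            labels, valid = label_cda_cases([60.0, 61.0], [np.nan, 55.0])
        assert not valid[0] and valid[1]


class TestEncoding:
    def test_dominant(self):
        np.testing.assert_array_equal(
            encode_genetic_model([0, 1, 2], "dominant").ravel(), [0, 1, 1]
        )

    def test_recessive_overdominant(self):
        np.testing.assert_array_equal(
            encode_genetic_model([0, 1, 2], "recessive").ravel(), [0, 0, 1]
        )
        np.testing.assert_array_equal(
            encode_genetic_model([0, 1, 2], "overdominant").ravel(), [0, 1, 0]
        )

    def test_codominant_two_columns(self):
        Z = encode_genetic_model([0, 1, 2], "codominant")
        np.testing.assert_array_equal(Z, [[0, 0], [1, 0], [0, 1]])

    def test_log_additive_identity(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0, 1, 2], size=100)
        la = encode_genetic_model(g, "log-additive")
        dom = encode_genetic_model(g, "dominant")
        rec = encode_genetic_model(g, "recessive")
        np.testing.assert_array_equal(la, dom + rec)

    def test_invalid_code(self):
        with pytest.raises(ValueError):
            encode_genetic_model([0, 3], "dominant")


class TestAssociateSnv:
    def test_null_or_near_one(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 1, 2], size=2000, p=[0.49, 0.42, 0.09])
        y = rng.integers(0, 2, 2000)
        res = associate_snv(_cohort(g[:, None], y), "s0", "log-additive")
        assert 0.8 < res.odds_ratio < 1.25
        assert res.p_value > 0.01

    def test_two_by_two_cross_product_oracle(self):
        # cases: 10 exposed / 10 unexposed; controls: 5 / 20 -> OR = 4
        g = np.array([1] * 10 + [0] * 10 + [1] * 5 + [0] * 20)
        y = np.array([1] * 20 + [0] * 25)
        res = associate_snv(_cohort(g[:, None], y), "s0", "dominant")
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-4)

    def test_codominant_matches_saturated_table(self):
        # logistic MLE on a 2x3 table equals the observed cell odds
        counts = {(0, 0): 30, (0, 1): 20, (0, 2): 10, (1, 0): 10, (1, 1): 15, (1, 2): 12}
        g = np.concatenate([np.full(c, k[1]) for k, c in counts.items()])
        y = np.concatenate([np.full(c, k[0]) for k, c in counts.items()])
        res = associate_snv(_cohort(g[:, None], y), "s0", "codominant")
        or_het = (counts[(1, 1)] / counts[(0, 1)]) / (counts[(1, 0)] / counts[(0, 0)])
        or_hom = (counts[(1, 2)] / counts[(0, 2)]) / (counts[(1, 0)] / counts[(0, 0)])
        assert res.odds_ratio[0] == pytest.approx(or_het, rel=1e-4)
        assert res.odds_ratio[1] == pytest.approx(or_hom, rel=1e-4)
        # and the LRT p matches statsmodels
        import statsmodels.api as sm

        Z = encode_genetic_model(g, "codominant")
        fit = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        assert res.p_value == pytest.approx(fit.llr_pvalue, rel=1e-6)

    def test_separation_flagged(self):
        g = np.array([0] * 10 + [2] * 10)
        y = np.array([0] * 10 + [1] * 10)
        res = associate_snv(_cohort(g[:, None], y), "s0", "recessive")
        assert res.separation_flagged

    def test_best_model_lowest_aic(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0, 1, 2], size=600, p=[0.49, 0.42, 0.09])
        # purely heterozygote-driven risk: overdominant should win
        p = np.where(g == 1, 0.7, 0.25)
        y = (rng.random(600) < p).astype(int)
        results = choose_best_model(_cohort(g[:, None], y), "s0")
        chosen = [r for r in results if r.chosen]
        assert len(chosen) == 1
        assert chosen[0].model == "overdominant"


class TestVectorizedLogistic:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n, m = 150, 8
        G = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        eta = -0.5 + 0.8 * G[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pv = logistic_lrt_pvalues(G, y)
        for j in range(m):
            fit = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            assert pv[j] == pytest.approx(fit.llr_pvalue, rel=1e-4, abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(40):
            G = rng.choice([0.0, 1.0, 2.0], size=(120, 25))
            y = rng.integers(0, 2, 120).astype(float)
            pvals.append(logistic_lrt_pvalues(G, y))
        pvals = np.concatenate(pvals)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestBootstrapSelect:
    def test_strong_snv_selected(self):
        cfg = HumanConfig(n=336, n_snvs=20, causal={0: 8.0}, prevalence=0.4, tag="t")
        cohort, _ = simulate_human_cohort(cfg, seed=11)
        hits = bootstrap_select_snvs(cohort, n_iter=100, seed=1)
        assert "snv1" in hits.index
        assert hits["snv1"] >= 50

    def test_null_snvs_rarely_selected(self):
        cfg = HumanConfig(n=300, n_snvs=50, causal={}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=12)
        hits = bootstrap_select_snvs(cohort, n_iter=100, seed=2)
        assert len(hits) == 0

    def test_seed_determinism(self):
        cfg = HumanConfig(n=200, n_snvs=30, causal={3: 2.5}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=13)
        a = bootstrap_select_snvs(cohort, n_iter=30, seed=7)
        b = bootstrap_select_snvs(cohort, n_iter=30, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_n_iter_validation(self):
        cfg = HumanConfig(n=100, n_snvs=5)
        cohort, _ = simulate_human_cohort(cfg, seed=14)
        with pytest.raises(ValueError):
            bootstrap_select_snvs(cohort, n_iter=0)


class TestLasso:
    def test_huge_lambda_intercept_only(self):
        cfg = HumanConfig(n=150, n_snvs=10, causal={0: 2.0}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=15)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fit_lasso_risk_model(cohort, cohort.snv_ids, fixed_C=1e-6)
        assert model.intercept_only
        assert model.coefficients == {}

    def test_lambda_zero_matches_unpenalized(self):
        import statsmodels.api as sm

        cfg = HumanConfig(n=400, n_snvs=4, causal={0: 2.0, 1: 1.5}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=16)
        model = fit_lasso_risk_model(cohort, cohort.snv_ids, fixed_C=1e8)
        X = sm.add_constant(cohort.dosages.to_numpy(float))
        fit = sm.Logit(np.asarray(cohort.outcome, float), X).fit(disp=0)
        assert model.intercept == pytest.approx(fit.params[0], abs=1e-4)
        for j, s in enumerate(cohort.snv_ids):
            assert model.coefficients.get(s, 0.0) == pytest.approx(fit.params[j + 1], abs=1e-4)

    def test_no_candidates_error(self):
        cfg = HumanConfig(n=100, n_snvs=5)
        cohort, _ = simulate_human_cohort(cfg, seed=17)
        with pytest.raises(ValueError):
            fit_lasso_risk_model(cohort, [])

    def test_json_roundtrip(self, tmp_path):
        from ipqtl.human_genetics import RiskScoreModel

        cfg = HumanConfig(n=200, n_snvs=6, causal={0: 2.5}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=18)
        model = fit_lasso_risk_model(cohort, cohort.snv_ids, seed=0, n_folds=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RiskScoreModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.cutoff == model.cutoff


class TestYouden:
    def test_perfect_separation_tie_rule(self):
        cutoff, J, roc = optimize_cutoff_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert J == 1.0
        assert cutoff == 0.8  # smallest threshold achieving max J

    def test_null_scores_low_j(self):
        rng = np.random.default_rng(19)
        js = []
        for _ in range(100):
            scores = rng.random(200)
            labels = rng.integers(0, 2, 200)
            _, J, _ = optimize_cutoff_youden(scores, labels)
            js.append(J)
        assert np.mean(js) < 0.25  # small-sample optimism only

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_brute_force_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60).round(2)  # force ties
        labels = rng.integers(0, 2, 60)
        cutoff, J, _ = optimize_cutoff_youden(scores, labels)
        best_j, best_t = -2.0, None
        for t in sorted(np.unique(scores)):
            pred = scores >= t
            sens = pred[labels == 1].mean()
            spec = (~pred)[labels == 0].mean()
            j = sens + spec - 1
            if j > best_j:
                best_j, best_t = j, t
        assert J == pytest.approx(best_j, abs=1e-12)
        assert cutoff == best_t

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            optimize_cutoff_youden([0.1, 0.9], [1, 1])


class TestEvaluate:
    def test_train_equals_test_consistency(self):
        cfg = HumanConfig(n=300, n_snvs=10, causal={0: 2.5, 1: 2.0}, prevalence=0.4)
        cohort, _ = simulate_human_cohort(cfg, seed=20)
        model = fit_lasso_risk_model(cohort, cohort.snv_ids, seed=0, n_folds=5)
        metrics = evaluate_on_test(model, cohort)
        for k in ("auc", "sensitivity", "specificity"):
            assert metrics[k] == pytest.approx(model.training_metrics[k], abs=1e-12)

    def test_uninformative_model_chance_auc(self):
        from ipqtl.human_genetics import RiskScoreModel

        rng = np.random.default_rng(21)
        model = RiskScoreModel(
            snv_ids=["s0"], hit_counts={}, coefficients={"s0": 0.5}, intercept=0.0,
            penalty_lambda=0.1, lambda_record="fixed", cutoff=0.5,
        )
        c = _cohort(rng.choice([0, 1, 2], size=(2000, 1)), rng.integers(0, 2, 2000))
        c.dosages.columns = ["s0"]
        metrics = evaluate_on_test(model, c)
        assert abs(metrics["auc"] - 0.5) < 0.05

    def test_missing_snv_error(self):
        from ipqtl.human_genetics import RiskScoreModel

        model = RiskScoreModel(
            snv_ids=["absent"], hit_counts={}, coefficients={"absent": 1.0}, intercept=0.0,
            penalty_lambda=0.1, lambda_record="fixed",
        )
        c = _cohort(np.zeros((5, 1)), np.array([0, 1, 0, 1, 0]))
        with pytest.raises(ValueError, match="absent"):
            evaluate_on_test(model, c)
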