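import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipqtl.imp_association import (
    IMPPanel,
    assign_age_groups,
    compare_groups,
    correlate_with_phenotype,
    ddct_fold_change,
    pca_classify,
    select_imps,
)


class TestDdct:
    def test_zero_ddct_unity(self):
        assert ddct_fold_change(20, 18, 22, 20) == 1.0

    def test_ddct_one_halves(self):
        assert ddct_fold_change(21, 18, 22, 20) == 0.5

    def test_hand_arithmetic(self):
        # (25-20) - (24-21) = 2 -> 2^-2 = 0.25
        assert ddct_fold_change(25, 20, 24, 21) == 0.25

    def test_multiplicative_in_ddct(self):
        # fold(a + b) = fold(a) * fold(b)
        fa = ddct_fold_change(21.3, 20, 20, 20)   # ddct = 1.3
        fb = ddct_fold_change(20.9, 20, 20, 20)   # ddct = 0.9
        fab = ddct_fold_change(22.2, 20, 20, 20)  # ddct = 2.2
        assert fab == pytest.approx(fa * fb, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan, 20, 24, 21)

    def test_positive(self):
        assert ddct_fold_change(30, 18, 20, 25) > 0


class TestAgeGroups:
    def test_four_ages(self):
        labels, med = assign_age_groups([60, 70, 80, 90])
        assert med == 75
        assert list(labels) == ["young", "young", "old", "old"]

    def test_all_equal_all_old(self):
        with pytest.warns(UserWarning, match="old"):
            labels, _ = assign_age_groups([70, 70, 70])
        assert list(labels) == ["old", "old", "old"]

    def test_boundary_at_median_is_old(self):
        labels, med = assign_age_groups([60, 71, 90])
        assert med == 71
        assert list(labels) == ["young", "old", "old"]

    def test_needs_two(self):
        with pytest.raises(ValueError):
            assign_age_groups([71])


class TestCorrelate:
    def test_linear_normal_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        method, r, p = correlate_with_phenotype(x, 2 * x)
        assert method == "pearson"
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_heavy_tail_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(size=200)
        method, rho, p = correlate_with_phenotype(x, x**3)
        assert method == "spearman"
        assert rho == pytest.approx(1.0)

    def test_six_point_textbook_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 7, 5])
        _, r, _ = correlate_with_phenotype(x, y)
        # direct covariance formula
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_phenotype(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="5"):
            correlate_with_phenotype([1, 2, 3], [1, 2, 3])

    def test_pairwise_complete(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 3 * x + rng.normal(scale=0.1, size=50)
        x[:5] = np.nan
        method, r, p = correlate_with_phenotype(x, y)
        assert r > 0.9


class TestCompareGroups:
    def test_identical_groups_high_p(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        lab = ["a"] * 10 + ["b"] * 10
        _, _, p = compare_groups(v, lab)
        assert p > 0.9

    def test_shift_power(self):
        rng = np.random.default_rng(3)
        reject = 0
        for _ in range(200):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)  # 2 sigma shift
            _, _, p = compare_groups(np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30)
            reject += p < 0.05
        assert reject >= 190  # >= 95% power

    def test_heavy_tail_routes_mannwhitney(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.standard_cauchy(40), rng.standard_cauchy(40) + 1])
        test, _, _ = compare_groups(v, ["a"] * 40 + ["b"] * 40)
        assert test == "mann-whitney"

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2, 3, 4], ["a", "a", "a", "b"])


class TestSelectImps:
    def _panel(self, rng, n=120):
        imp1 = rng.normal(size=n)
        imp2 = rng.normal(size=n)
        pheno = imp1 + 0.5 * rng.normal(size=n)
        levels = pd.DataFrame({"IMP1": imp1, "IMP2": imp2})
        return IMPPanel(levels=levels), pheno

    def test_true_imp_selected_false_rejected(self):
        rng = np.random.default_rng(5)
        hit1 = hit2 = 0
        for _ in range(100):
            panel, pheno = self._panel(rng)
            sel = select_imps(panel, pheno)
            got = set(sel["molecule"])
            hit1 += "IMP1" in got
            hit2 += "IMP2" in got
        assert hit1 >= 90
        assert hit2 <= 20  # ~5% false entry

    def test_null_panel_false_entry_rate(self):
        rng = np.random.default_rng(6)
        entries = 0
        n_imps = 5
        for _ in range(100):
            levels = pd.DataFrame(rng.normal(size=(60, n_imps)),
                                  columns=[f"I{j}" for j in range(n_imps)])
            sel = select_imps(IMPPanel(levels=levels), rng.normal(size=60))
            entries += len(sel)
        rate = entries / (100 * n_imps)
        assert 0.01 < rate < 0.10  # nominal 5%

    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        panel = IMPPanel(levels=pd.DataFrame({"IMP": x}))
        sel = select_imps(panel, x.copy())
        assert list(sel["molecule"]) == ["IMP"]
        assert sel["coefficient"][0] == pytest.approx(1.0, abs=1e-8)
        assert sel["p_value"][0] < 1e-20

    def test_empty_screen_not_error(self):
        rng = np.random.default_rng(8)
        panel = IMPPanel(levels=pd.DataFrame({"I": rng.normal(size=40)}))
        y = rng.normal(size=40)
        # force no candidate by using an absurdly strict entry threshold
        sel = select_imps(panel, y, alpha_entry=1e-12)
        assert len(sel) == 0


class TestPcaClassify:
    def test_separated_groups(self):
        rng = np.random.default_rng(9)
        n = 60
        grp = np.repeat([0, 1], n // 2)
        levels = pd.DataFrame(
            {f"v{j}": grp * 4.0 + rng.normal(size=n) for j in range(4)}
        )
        pheno = grp * 10.0 + rng.normal(size=n)
        res = pca_classify(levels, pheno)
        pc1 = res["scores"]["PC1"].to_numpy()
        # PC1 separates the generating groups
        auc_split = (pc1[grp == 1].mean() - pc1[grp == 0].mean())
        assert abs(auc_split) > 2.0
        agree = np.mean((res["labels"] == "high") == (grp == 1))
        assert max(agree, 1 - agree) >= 0.9

    def test_duplicate_variable_keeps_geometry(self):
        rng = np.random.default_rng(10)
        levels = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        pheno = rng.normal(size=30)
        base = pca_classify(levels, pheno)
        dup = pca_classify(levels.assign(a2=levels["a"]), pheno)
        # pairwise score distances preserved up to overall scale
        def dists(scores):
            s = scores.to_numpy()
            d = np.linalg.norm(s[:, None, :] - s[None, :, :], axis=2)
            return d[np.triu_indices(len(s), 1)]

        d1, d2 = dists(base["scores"]), dists(dup["scores"].iloc[:, :2])
        r = stats.pearsonr(d1, d2)[0]
        assert r > 0.9

    def test_median_split_balanced(self):
        rng = np.random.default_rng(11)
        for n in (20, 21):
            levels = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            pheno = rng.normal(size=n)
            res = pca_classify(levels, pheno)
            n_high = int((res["labels"] == "high").sum())
            assert abs(n_high - (n - n_high)) <= 1

    def test_zero_variance_dropped(self):
        rng = np.random.default_rng(12)
        levels = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20),
                               "c": np.ones(20)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_classify(levels, rng.normal(size=20))
        assert "c" not in res["loadings"].index

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pca_classify(pd.DataFrame({"a": [1.0, 2, 3, 4]}), [1, 2, 3, 4])
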