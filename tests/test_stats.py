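"""Group comparisons, ICC and ROC against enumeration and library oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lentimorph as lm
from lentimorph.stats import icc_two_rater


def two_group_table(pos, neg, names=("MSA-P", "PD"), col="x"):
    return pd.DataFrame(
        {
            "group": [names[0]] * len(pos) + [names[1]] * len(neg),
            col: np.concatenate([pos, neg]),
        }
    )


class TestNormalityGate:
    def test_normal_groups_route_parametric(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(0, 1, 19) for g in "abc"}
        # guard: this fixed draw is Shapiro-compatible in each group
        assert all(sps.shapiro(v).pvalue >= 0.05 for v in groups.values())
        route, pvals = lm.normality_gate(groups)
        assert route == "parametric"
        assert all(p >= 0.05 for p in pvals.values())

    def test_exponential_group_routes_nonparametric_usually(self):
        hits = 0
        c_rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {
                "a": rng.normal(0, 1, 19),
                "b": rng.normal(0, 1, 19),
                "c": rng.exponential(1.0, 19),
            }
            route, _ = lm.normality_gate(groups)
            hits += route == "nonparametric"
            c_rejections += sps.shapiro(groups["c"]).pvalue < 0.05
        # the gate must fire at least whenever the skewed group fails the
        # Shapiro-Wilk oracle, and far above the ~14% all-normal null rate
        assert hits >= c_rejections
        assert hits >= 60

    def test_constant_group_warns_nonparametric(self):
        groups = {"a": np.zeros(10), "b": np.random.default_rng(0).normal(0, 1, 10)}
        with pytest.warns(UserWarning, match="constant"):
            route, pvals = lm.normality_gate(groups)
        assert route == "nonparametric"
        assert np.isnan(pvals["a"])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n=2"):
            lm.normality_gate({"a": np.array([1.0, 2.0])})


class TestCompareGroups:
    def test_identical_groups_null_p(self):
        x = np.arange(19, dtype=float)
        tab = two_group_table(x, x)
        comp = lm.compare_groups(tab, "x")
        assert comp.p("MSA-P", "PD") > 0.9

    def test_gross_separation_both_paths(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 19), rng.normal(5, 1, 19)
        tab = two_group_table(a, b)
        comp = lm.compare_groups(tab, "x")
        assert comp.p("MSA-P", "PD") < 1e-3
        # force the nonparametric path via a tiny alpha on the gate
        from lentimorph.stats import _mwu_pairwise

        assert _mwu_pairwise({"a": a, "b": b})[("a", "b")] < 1e-3

    def test_mannwhitney_exact_small_sample(self):
        # enumeration oracle: all C(6,3)=20 label assignments; the observed
        # complete separation is one extreme per tail -> two-sided p = 2/20
        pooled = np.array([1.0, 2, 3, 4, 5, 6])
        observed_u = 0.0  # {1,2,3} vs {4,5,6}
        count = 0
        for idx in combinations(range(6), 3):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            u = sum((g > r) + 0.5 * (g == r) for g in grp for r in rest)
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                count += 1
        p_exact = count / 20
        assert p_exact == 0.1

        from lentimorph.stats import _mwu_pairwise

        pairs = _mwu_pairwise({"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])})
        assert pairs[("a", "b")] == pytest.approx(p_exact)

    def test_lsd_reduces_to_pooled_t_for_two_groups(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        tab = two_group_table(a, b)
        comp = lm.compare_groups(tab, "x")
        assert comp.test_used == "ANOVA_LSD"
        t = sps.ttest_ind(a, b, equal_var=True)
        assert comp.p("MSA-P", "PD") == pytest.approx(t.pvalue)

    def test_lsd_uses_pooled_three_group_variance(self):
        rng = np.random.default_rng(13)
        tab = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 10),
                "x": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(0.5, 1, 10), rng.normal(1, 1, 10)]
                ),
            }
        )
        comp = lm.compare_groups(tab, "x")
        # independent oracle: explicit mean-square computation
        arrays = [tab.loc[tab.group == g, "x"].to_numpy() for g in "abc"]
        mse = sum(((v - v.mean()) ** 2).sum() for v in arrays) / (30 - 3)
        se = np.sqrt(mse * (1 / 10 + 1 / 10))
        tstat = (arrays[0].mean() - arrays[1].mean()) / se
        p = 2 * sps.t.sf(abs(tstat), 27)
        assert comp.p("a", "b") == pytest.approx(p)


class TestIcc:
    def test_identical_raters_icc_one(self):
        x = np.random.default_rng(0).normal(0, 1, 20)
        res = icc_two_rater(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)
        assert res.agreement_band == "good"

    def test_constant_rater_offset_degrades_absolute_agreement(self):
        # 5-subject worked table: rater 2 = rater 1 + 10
        x = np.array([1.0, 2, 3, 4, 5])
        res = icc_two_rater(np.column_stack([x, x + 10.0]))
        assert res.icc < 0.2  # perfectly correlated but poor absolute agreement
        # independent oracle: variance-component formula via pingouin
        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(5), 2),
                "rater": np.repeat([1, 2], 5),
                "y": np.concatenate([x, x + 10.0]),
            }
        )
        icc2 = pg.intraclass_corr(long, "subject", "rater", "y")
        expected = icc2.loc[icc2.Type == "ICC(A,1)", "ICC"].item()
        assert res.icc == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_on_random_tables(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, 2, 30)
        vals = subj[:, None] + rng.normal(0, 1, (30, 2))
        res = icc_two_rater(vals)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(30), 2),
                "rater": np.repeat([1, 2], 30),
                "y": vals.T.ravel(),
            }
        )
        icc2 = pg.intraclass_corr(long, "subject", "rater", "y")
        assert res.icc == pytest.approx(
            icc2.loc[icc2.Type == "ICC(A,1)", "ICC"].item(), abs=1e-9
        )

    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        sigma_s, sigma_e = np.sqrt(0.7), np.sqrt(0.3)  # true ICC = 0.7
        subj = rng.normal(0, sigma_s, 2000)
        vals = subj[:, None] + rng.normal(0, sigma_e, (2000, 2))
        assert icc_two_rater(vals).icc == pytest.approx(0.7, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 3, (25, 2))
        base = icc_two_rater(vals).icc
        assert icc_two_rater(vals + 100.0).icc == pytest.approx(base)
        assert icc_two_rater(vals * 7.5).icc == pytest.approx(base)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc_two_rater(np.full((10, 2), 3.0))
        with pytest.raises(ValueError, match="n x 2"):
            icc_two_rater(np.zeros((10, 3)))

    @pytest.mark.parametrize(
        "icc, band",
        [(0.729, "good"), (0.468, "moderate"), (0.3, "moderate"),
         (0.7, "moderate"), (0.299, "slight"), (0.701, "good")],
    )
    def test_agreement_bands(self, icc, band):
        assert lm.icc_agreement_level(icc) == band


class TestRoc:
    def test_perfect_separation(self):
        tab = two_group_table([1.0, 2, 3], [10.0, 11, 12])
        r = lm.roc_analysis(tab, "x", "MSA-P", "PD")
        assert r.auc == 1.0
        assert r.youden_j == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.orientation == "lower_is_positive"

    def test_identical_distributions_auc_half(self):
        rng = np.random.default_rng(2)
        tab = two_group_table(rng.normal(0, 1, 3000), rng.normal(0, 1, 3000))
        r = lm.roc_analysis(tab, "x", "MSA-P", "PD")
        assert r.auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_sklearn_and_mannwhitney(self, seed):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        pos = rng.normal(1, 1.2, 25)
        neg = rng.normal(0, 0.8, 30)
        tab = two_group_table(pos, neg)
        r = lm.roc_analysis(tab, "x", "MSA-P", "PD")
        sign = -1 if r.orientation == "lower_is_positive" else 1
        y = np.array([1] * 25 + [0] * 30)
        assert r.auc == pytest.approx(
            sk.roc_auc_score(y, sign * np.concatenate([pos, neg]))
        )
        u = sps.mannwhitneyu(sign * pos, sign * neg, alternative="two-sided").statistic
        assert r.auc == pytest.approx(u / (25 * 30))

    @pytest.mark.parametrize("seed", range(10))
    def test_youden_identity_and_cutoff_optimality(self, seed):
        rng = np.random.default_rng(50 + seed)
        pos = rng.normal(1, 1, 12)
        neg = rng.normal(0, 1, 15)
        tab = two_group_table(pos, neg)
        r = lm.roc_analysis(tab, "x", "MSA-P", "PD")
        assert r.youden_j == pytest.approx(r.sensitivity + r.specificity - 1)
        # exhaustive check over a fine threshold grid
        sign = -1 if r.orientation == "lower_is_positive" else 1
        spos, sneg = sign * pos, sign * neg
        grid = np.linspace(min(spos.min(), sneg.min()) - 1,
                           max(spos.max(), sneg.max()) + 1, 4001)
        best = max((spos >= t).mean() + (sneg < t).mean() - 1 for t in grid)
        assert r.youden_j == pytest.approx(best, abs=1e-12)

    def test_binormal_convergence(self):
        rng = np.random.default_rng(99)
        mu1, mu2, s1, s2 = 0.0, 1.5, 1.0, 1.3
        tab = two_group_table(
            rng.normal(mu2, s2, 10**5), rng.normal(mu1, s1, 10**5)
        )
        r = lm.roc_analysis(tab, "x", "MSA-P", "PD")
        expected = sps.norm.cdf(abs(mu1 - mu2) / np.hypot(s1, s2))
        assert r.auc == pytest.approx(expected, abs=0.01)

    def test_single_valued_index_rejected(self):
        tab = two_group_table([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="single-valued"):
            lm.roc_analysis(tab, "x", "MSA-P", "PD")


class TestRunFullAnalysis:
    def test_default_cohort_selects_csl(self, tabular_indices, tabular_cohort):
        report = lm.run_full_analysis(
            tabular_indices, lm.per_rater_table(tabular_cohort)
        )
        assert "cSL" in report.roc_indices("MSA-P", "PD")
        assert "cSL" in report.roc_indices("MSA-P", "CG")
        assert len(report.comparisons) == 12
        # ICC: 7 indices x 3 groups
        assert len(report.icc) == 21
        for c in report.comparisons:
            for p in c.pairwise_p.values():
                assert 0 <= p <= 1

    def test_null_cohort_rarely_selects_csl(self, default_config):
        groups, noise = default_config
        from dataclasses import replace

        null_groups = [
            replace(groups[0], label=lab) for lab in ("MSA-P", "PD", "CG")
        ]
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            recs = lm.generate_cohort(null_groups, noise, seed=1000 + 57 * seed)
            tab = lm.indices_table(recs)
            rep = lm.run_full_analysis(tab)
            hits += "cSL" in rep.roc_indices("MSA-P", "PD")
        assert hits < n_seeds / 2
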