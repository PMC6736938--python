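"""Statistical layer: correlations, rank tests, ANOVA, chi-square, ROC."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from gazecog import (
    Cohort,
    Group,
    SubjectRecord,
    anova_tukey,
    chi_square_independence,
    cohort_report,
    kruskal_wallis,
    roc_auc,
    spearman,
    steel_dwass,
)
from gazecog.errors import ValidationError


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0]).rho == pytest.approx(1.0)
        assert spearman(x, [10.0, 8.0, 6.0, 4.0, 2.0]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_midrank_formula(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        r = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        # Pearson correlation of midranks computed by hand
        sx, sy = rx - rx.mean(), ry - ry.mean()
        expected = float(sx @ sy) / math.sqrt(float(sx @ sx) * float(sy @ sy))
        assert r.rho == pytest.approx(expected, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        r = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        sx = rx - rx.mean()
        obs = abs(float(sx @ (ry - ry.mean())))
        count = sum(
            abs(float(sx @ (np.asarray(perm) - np.mean(perm)))) >= obs - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert r.p == pytest.approx(count / math.factorial(6))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.random(40)
        y = x + rng.random(40)
        r = spearman(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(float(ref_rho), abs=1e-12)
        assert r.p == pytest.approx(float(ref_p), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_incomplete_pairs_dropped(self):
        r = spearman([1, 2, 3, np.nan, 5], [2, 3, 4, 5, np.nan])
        assert r.n == 3


class TestKruskalWallis:
    def test_two_identical_groups_degenerate(self):
        r = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_all_observations_identical(self):
        r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_three_shifted_groups_match_brute_force_rank_sum(self):
        groups = [[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]]
        r = kruskal_wallis(groups)
        # brute force: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), no ties
        allv = np.concatenate([np.asarray(g, float) for g in groups])
        ranks = sps.rankdata(allv)
        rsums = [ranks[:5].sum(), ranks[5:10].sum(), ranks[10:].sum()]
        n = 15
        h = 12.0 / (n * (n + 1)) * sum(s**2 / 5 for s in rsums) - 3 * (n + 1)
        assert r.statistic == pytest.approx(h, abs=1e-12)
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_matches_scipy(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4], [4, 4, 5, 1]]
        r = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_exact_p_matches_exhaustive_enumeration(self):
        groups = [[1.2, 3.4, 0.5, 2.2], [4.1, 5.0, 2.9, 6.3]]
        r_exact = kruskal_wallis(groups, p_method="exact")
        # independent enumeration over all C(8,4) assignments
        allv = np.concatenate([np.asarray(g) for g in groups])
        obs = kruskal_wallis(groups).statistic
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in combo]
            h = kruskal_wallis([allv[list(combo)], allv[rest]]).statistic
            count += h >= obs - 1e-12
            total += 1
        assert r_exact.p == pytest.approx(count / total)

    def test_permutation_p_approaches_exact(self):
        groups = [[1.2, 3.4, 0.5, 2.2], [4.1, 5.0, 2.9, 6.3]]
        exact = kruskal_wallis(groups, p_method="exact").p
        perm = kruskal_wallis(groups, p_method="permutation", n_perm=20000, seed=1).p
        assert perm == pytest.approx(exact, abs=0.02)

    def test_epsilon_squared_definition(self):
        groups = [[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]]
        r = kruskal_wallis(groups)
        assert r.effect_size == pytest.approx(r.statistic / 14)
        assert r.effect_size_label == "epsilon_squared"


class TestSteelDwass:
    def test_identical_groups_all_adjusted_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        for res in steel_dwass([g, g, g]):
            assert res.p > 0.95

    def test_one_extreme_group_has_the_small_pairwise_ps(self):
        a = [1, 2, 3, 4, 5]
        b = [1.5, 2.5, 3.5, 4.5, 5.5]
        c = [101, 102, 103, 104, 105]
        res = {r.pair: r.p for r in steel_dwass([a, b, c], labels=["a", "b", "c"])}
        assert res[("a", "c")] < res[("a", "b")]
        assert res[("b", "c")] < res[("a", "b")]

    def test_matches_independently_coded_reference(self):
        # dual implementation: pairwise midranks standardized with the
        # tie-corrected variance, sqrt(2)|t| on the studentized range
        rng = np.random.default_rng(4)
        groups = [list(rng.normal(m, 1, 5)) for m in (0.0, 0.8, 2.0)]
        k = len(groups)

        def reference_pair(a, b):
            a, b = np.asarray(a), np.asarray(b)
            m, n = len(a), len(b)
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            w = ranks[:m].sum()
            e = m * (m + n + 1) / 2
            v = m * n / ((m + n) * (m + n - 1)) * (
                (ranks**2).sum() - (m + n) * (m + n + 1) ** 2 / 4
            )
            t = (w - e) / math.sqrt(v)
            return t, float(sps.studentized_range.sf(math.sqrt(2) * abs(t), k, np.inf))

        got = steel_dwass(groups)
        for res, (i, j) in zip(got, itertools.combinations(range(k), 2)):
            t_ref, p_ref = reference_pair(groups[i], groups[j])
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_needs_three_groups_of_two(self):
        with pytest.raises(ValidationError):
            steel_dwass([[1, 2], [3, 4]])
        with pytest.raises(ValidationError):
            steel_dwass([[1, 2], [3, 4], [5]])


class TestAnovaTukey:
    def test_identical_groups_f_and_eta_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        r = anova_tukey([g, g, g])
        assert r.F == pytest.approx(0.0, abs=1e-12)
        assert r.eta_squared == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_is_square_of_pooled_t(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.5]
        b = [2.5, 3.5, 4.0, 6.0]
        r = anova_tukey([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert r.F == pytest.approx(t**2, rel=1e-12)

    def test_three_group_fixture_matches_brute_force_sums_of_squares(self):
        groups = [[2.0, 3.1, 2.5, 4.0], [5.2, 4.8, 6.1, 5.0, 5.5], [7.9, 8.2, 7.5]]
        r = anova_tukey(groups)
        allv = np.concatenate([np.asarray(g) for g in groups])
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        k, n = 3, len(allv)
        f = (ssb / (k - 1)) / (ssw / (n - k))
        assert r.F == pytest.approx(f, abs=1e-10)
        assert r.eta_squared == pytest.approx(ssb / (ssb + ssw), abs=1e-10)
        assert (r.df_between, r.df_within) == (2, 9)

    def test_tukey_kramer_pairwise_matches_scipy(self):
        groups = [[2.0, 3.1, 2.5, 4.0], [5.2, 4.8, 6.1, 5.0, 5.5], [7.9, 8.2, 7.5]]
        r = anova_tukey(groups, labels=["a", "b", "c"])
        ref = sps.tukey_hsd(*groups)
        got = {p[:2]: p[2] for p in r.pairwise}
        assert got[("a", "b")] == pytest.approx(ref.pvalue[0, 1])
        assert got[("a", "c")] == pytest.approx(ref.pvalue[0, 2])
        assert got[("b", "c")] == pytest.approx(ref.pvalue[1, 2])

    def test_zero_variance_everywhere_is_degenerate(self):
        with pytest.raises(ValidationError):
            anova_tukey([[1.0, 1.0], [2.0, 2.0]])


class TestChiSquare:
    def test_identical_columns_statistic_zero(self):
        r = chi_square_independence([[5, 5, 5], [9, 9, 9]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_2x2_matches_hand_computed_expected_counts(self):
        table = np.array([[10, 20], [30, 40]])
        r = chi_square_independence(table)
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        stat = ((table - expected) ** 2 / expected).sum()
        assert r.statistic == pytest.approx(stat, abs=1e-12)
        assert r.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square_independence([[0, 0], [3, 4]])

    def test_cramers_v_reported(self):
        r = chi_square_independence([[10, 20], [30, 5]])
        n = 65
        assert r.effect_size == pytest.approx(math.sqrt(r.statistic / n))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [10, 20, 30, 80, 85, 90]
        labels = [1, 1, 1, 0, 0, 0]  # impaired score lower
        r = roc_auc(scores, labels, n_boot=200, seed=0)
        assert r.auc == 1.0
        assert r.ci_low <= r.auc <= r.ci_high

    def test_all_tied_scores_give_half(self):
        r = roc_auc([5.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0], n_boot=100, seed=0)
        assert r.auc == pytest.approx(0.5)

    def test_eight_subject_fixture_matches_pair_enumeration(self):
        scores = np.array([55.0, 60.0, 42.0, 60.0, 71.0, 80.0, 60.0, 90.0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        r = roc_auc(scores, labels, n_boot=0)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum(
            (p < q) + 0.5 * (p == q) for p in pos for q in neg
        )
        assert r.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_direction_flip_is_complementary(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        labels = rng.random(30) < 0.5
        lo = roc_auc(scores, labels, n_boot=0).auc
        hi = roc_auc(scores, labels, direction="higher_score_impaired", n_boot=0).auc
        assert lo + hi == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1], n_boot=0)

    def test_bootstrap_ci_ordered_and_seeded(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(40, 10, 20), rng.normal(60, 10, 20)])
        labels = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        r1 = roc_auc(scores, labels, n_boot=500, seed=7)
        r2 = roc_auc(scores, labels, n_boot=500, seed=7)
        assert (r1.ci_low, r1.auc, r1.ci_high) == (r2.ci_low, r2.auc, r2.ci_high)
        assert 0.0 <= r1.ci_low <= r1.auc <= r1.ci_high <= 1.0


def _toy_cohort():
    rng = np.random.default_rng(5)
    subs = []
    means = {Group.HC: (75, 29), Group.MCI: (55, 25), Group.DEMENTIA: (35, 16)}
    for g, n in [(Group.HC, 10), (Group.MCI, 10), (Group.DEMENTIA, 10)]:
        for i in range(n):
            et = float(np.clip(rng.normal(means[g][0], 8), 0, 100))
            mm = int(np.clip(round(rng.normal(means[g][1], 2)), 0, 30))
            subs.append(
                SubjectRecord(
                    f"{g.value}{i}", g, mmse=mm, et_score=et,
                    fab=float(np.clip(rng.normal(12, 3), 0, 18)) if i % 2 else None,
                )
            )
    return Cohort(subs)


class TestCohortReport:
    def test_reports_group_sizes(self):
        rep = cohort_report(_toy_cohort(), n_boot=100, seed=0)
        assert rep["group_sizes"] == {"HC": 10, "MCI": 10, "DEMENTIA": 10}

    def test_contains_all_analysis_blocks(self):
        rep = cohort_report(_toy_cohort(), n_boot=100, seed=0)
        assert "mmse" in rep["correlations"]
        assert "by_clinical_group" in rep["group_comparison"]
        assert "mci_vs_hc" in rep["roc"]["et_score"]
        assert "impaired_vs_hc" in rep["roc"]["mmse"]
        assert "mmse" in rep["demographics"]

    def test_missing_columns_skipped_with_reason(self):
        subs = [
            SubjectRecord(f"s{i}", g, et_score=50.0 + i)
            for i, g in enumerate([Group.HC] * 4 + [Group.MCI] * 4 + [Group.DEMENTIA] * 4)
        ]
        rep = cohort_report(Cohort(subs), n_boot=50, seed=0)
        assert any("adas_cog" in s for s in rep["skipped"])
        assert "adas_cog" not in rep["correlations"]
        assert "mmse" not in rep["roc"]

    def test_all_p_values_in_unit_interval(self):
        rep = cohort_report(_toy_cohort(), n_boot=100, seed=0)

        def walk(node):
            if isinstance(node, dict):
                for key, value in node.items():
                    if key == "p":
                        assert 0.0 <= value <= 1.0
                    else:
                        walk(value)
            elif isinstance(node, list):
                for value in node:
                    walk(value)

        walk(rep)

    def test_report_is_json_serializable(self):
        import json

        json.dumps(cohort_report(_toy_cohort(), n_boot=50, seed=0))
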