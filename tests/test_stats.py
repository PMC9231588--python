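"""Group-comparison dispatch, summaries and count tables.

Reference p-values frozen from R 4.3.3 (t.test, wilcox.test, kruskal.test,
oneway.test, shapiro.test, multcomp::glht Dunnett) on the fixture data
below; the Dunn fixture is a hand-derived rank calculation.
"""

import numpy as np
import pytest

from zebrabehave.stats import (
    GenotypeComparison,
    compare,
    count_summary,
    dunn_test,
    format_p,
    format_percent,
    normality_gate,
    significance_stars,
    summarize,
)

A = np.array([3.1, 2.4, 4.8, 3.9, 2.2, 3.3, 4.1, 2.9, 3.6, 4.4])
B = np.array([4.9, 5.3, 4.1, 6.2, 5.8, 4.6, 5.1, 6.0, 4.3, 5.5])
C = np.array([2.0, 2.8, 3.5, 2.3, 3.0, 2.6, 3.2, 2.1, 2.7, 3.4])

# frozen R 4.3.3 references
R_STUDENT_T_P = 0.000120813802335
R_MANNWHITNEY_P = 0.000876798029656
R_PAIRED_T_P = 0.00241887198067
R_KRUSKAL_P = 6.06209479454e-05
R_ANOVA_P = 1.04654202439e-07
R_SHAPIRO_A_P = 0.950890312345
R_DUNNETT_P = (2.03265536726e-05, 0.0605329488183)  # B, C vs control A


class TestNormalityGate:
    def test_gaussian_samples_pass_mostly(self):
        """Gaussian n=30 group gates parametric in >= 90% of 100 seeds
        (per-group false-rejection rate is the Shapiro alpha, 5%)."""
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            hits += normality_gate({"a": rng.normal(0, 1, 30)}) == "parametric"
        assert hits >= 90

    def test_lognormal_samples_fail_mostly(self):
        """Heavily skewed lognormal n=30 gates nonparametric >= 90%."""
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            hits += normality_gate({"a": rng.lognormal(0, 1.5, 30)}) == "nonparametric"
        assert hits >= 90

    def test_constant_group_routes_nonparametric(self):
        g = {"a": np.full(5, 2.0), "b": np.array([1.0, 2.0, 3.0, 4.0, 5.0])}
        assert normality_gate(g) == "nonparametric"

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="n=2 < 3"):
            normality_gate({"a": np.array([1.0, 2.0]), "b": A})

    def test_matches_frozen_shapiro(self):
        from scipy.stats import shapiro

        assert shapiro(A).pvalue == pytest.approx(R_SHAPIRO_A_P, abs=1e-6)


class TestTwoGroup:
    def test_identical_groups_give_p_one(self):
        res = compare({"WT": [1.0, 2.0, 3.0], "HOM": [1.0, 2.0, 3.0]})
        assert res.p_overall == pytest.approx(1.0)
        assert res.test_used == "student_t"

    def test_student_t_matches_reference(self):
        res = compare({"WT": A, "HOM": B})
        assert res.test_used == "student_t"
        assert res.p_overall == pytest.approx(R_STUDENT_T_P, abs=1e-6)
        assert res.group_summaries["WT"].style == "mean_sem"

    def test_mannwhitney_fallback_matches_reference(self):
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(A, B, alternative="two-sided").pvalue
        assert p == pytest.approx(R_MANNWHITNEY_P, abs=1e-6)
        # force the nonparametric branch with a skewed group
        rng = np.random.default_rng(1)
        skew = rng.lognormal(0, 1.8, 30)
        res = compare({"WT": skew, "HOM": skew + 1.0})
        assert res.test_used == "mann_whitney"
        assert res.group_summaries["WT"].style == "median_ci"
        assert any("fallback" in n for n in res.notes)

    def test_paired_matches_reference(self):
        res = compare({"before": A, "after": B}, design="paired")
        assert res.test_used == "paired_t"
        assert res.p_overall == pytest.approx(R_PAIRED_T_P, abs=1e-6)

    def test_paired_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="equal group lengths"):
            compare({"a": A, "b": B[:5]}, design="paired")


class TestMultiGroup:
    def test_anova_and_dunnett_match_references(self):
        res = compare({"WT": A, "HET": B, "HOM": C})
        assert res.test_used == "anova_dunnett"
        assert res.p_overall == pytest.approx(R_ANOVA_P, abs=1e-6)
        # both scipy and R use stochastic multivariate-t quadrature: 1e-3
        assert res.p_per_comparison["HET"] == pytest.approx(R_DUNNETT_P[0], abs=1e-3)
        assert res.p_per_comparison["HOM"] == pytest.approx(R_DUNNETT_P[1], abs=1e-3)

    def test_large_shift_is_detected(self):
        """A group shifted by 10 pooled SDs: Dunnett-adjusted p < 1e-4."""
        rng = np.random.default_rng(0)
        wt = rng.normal(0, 1, 20)
        het = rng.normal(0, 1, 20)
        hom = rng.normal(10, 1, 20)
        res = compare({"WT": wt, "HET": het, "HOM": hom})
        assert res.p_per_comparison["HOM"] < 1e-4

    def test_adjusted_at_least_unadjusted(self):
        res = compare({"WT": A, "HET": B, "HOM": C})
        for k, p_adj in res.p_per_comparison.items():
            assert p_adj >= res.p_unadjusted[k] - 1e-3
        # and on the rank branch
        rng = np.random.default_rng(2)
        g = {k: rng.lognormal(0, 1.8, 25) for k in ("WT", "HET", "HOM")}
        adj = dunn_test(g, "WT", adjust=True)
        raw = dunn_test(g, "WT", adjust=False)
        for k in adj:
            assert adj[k] >= raw[k]

    def test_kruskal_matches_reference(self):
        from scipy.stats import kruskal

        assert kruskal(A, B, C).pvalue == pytest.approx(R_KRUSKAL_P, abs=1e-6)

    def test_dunn_matches_hand_derived_ranks(self):
        g = {"ref": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
             "g1": np.array([6.0, 7.0, 8.0, 9.0, 10.0]),
             "g2": np.array([1.5, 2.5, 3.5, 4.5, 5.5])}
        raw = dunn_test(g, "ref", adjust=False)
        adj = dunn_test(g, "ref", adjust=True)
        assert raw["g1"] == pytest.approx(0.004677734981047266, rel=1e-12)
        assert raw["g2"] == pytest.approx(0.7236736098317631, rel=1e-12)
        assert adj["g1"] == pytest.approx(0.009355469962094532, rel=1e-12)
        assert adj["g2"] == 1.0

    def test_label_permutation_invariance(self):
        r1 = compare({"WT": A, "HET": B, "HOM": C})
        r2 = compare({"HOM": C, "WT": A, "HET": B})
        assert r1.p_overall == pytest.approx(r2.p_overall, rel=1e-12)
        for k in ("HET", "HOM"):
            # Dunnett p from quasi-MC quadrature: identical to its noise scale
            assert r1.p_per_comparison[k] == pytest.approx(
                r2.p_per_comparison[k], abs=1e-3)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            GenotypeComparison({"a": A, "b": B, "c": C},
                               design="multi_group_vs_reference", reference="WT")


class TestSummarize:
    def test_mean_sem_closed_form(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sem == pytest.approx(1.0 / np.sqrt(3.0), rel=1e-12)

    def test_constant_values_degenerate(self):
        s = summarize([5.0] * 6)
        assert s.sem == 0.0
        c = summarize([5.0] * 6, "median_ci", seed=1)
        assert c.ci_low == c.ci_high == 5.0

    def test_bootstrap_matches_loop_oracle(self):
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        s = summarize(v, "median_ci", n_boot=2000, seed=7)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, len(v), size=(2000, len(v)))
        meds = [float(np.sort(v[row])[3:5].mean()) for row in idx]
        lo, hi = np.percentile(meds, [2.5, 97.5])
        assert (s.ci_low, s.ci_high) == pytest.approx((lo, hi), rel=1e-12)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="n >= 2"):
            summarize([1.0])


class TestCountSummary:
    def test_worked_examples(self):
        assert format_percent(54, 82) == "54/82 (65.9%)"
        assert format_percent(0, 30) == "0/30 (0%)"
        assert format_percent(2, 40) == "2/40 (5%)"
        assert format_percent(1, 3) == "1/3 (33.3%)"

    def test_half_up_rounding(self):
        # 0.25% rounds up, not banker's-even
        assert format_percent(1, 400) == "1/400 (0.3%)"

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            format_percent(5, 3)
        with pytest.raises(ValueError):
            format_percent(1, 0)

    def test_table_construction(self):
        table = count_summary({
            "mortality": {"WT": (2, 92), "HOM": (54, 82)},
        })
        df = table.formatted()
        assert df.loc["mortality", "WT"] == "2/92 (2.2%)"
        assert table.percent("mortality", "HOM") == 65.9


class TestReporting:
    def test_stars_at_published_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"

    def test_p_formatting(self):
        assert format_p(0.042134) == "0.04213"
        assert format_p(1e-6) == "<0.0001"

    def test_summary_renders(self):
        res = compare({"WT": A, "HOM": B}, metric="activity")
        text = res.summary()
        assert "student_t" in text and "WT" in text and "p = " in text
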