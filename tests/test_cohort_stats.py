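import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidyscan import (
    Contingency2x2,
    contingency_test,
    defect_rate_report,
    fisher_exact_2xc,
    lethal_phase_analysis,
    paired_t_test,
    rank_test,
)
from ploidyscan import printed_counts as pc


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle_2x2(a, b, c, d, slack=1e-7):
    """Exhaustive hypergeometric enumeration over the 2x2 support."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + slack)
    )


def mann_whitney_oracle(x, y):
    """Exact two-sided p by enumerating every rank assignment."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_stat(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    observed = u_stat(range(n1))
    n1n2 = n1 * len(y)
    dev_obs = abs(observed - n1n2 / 2)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - n1n2 / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------


class TestContingency:
    def test_no_association(self):
        result = contingency_test(Contingency2x2(10, 10, 10, 10), "chisq")
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_fisher_small_table_closed_form(self):
        result = contingency_test(Contingency2x2(3, 1, 1, 3), "fisher")
        assert result.p_value == pytest.approx(34 / 70, rel=1e-12)

    def test_fisher_reconstructed_stage_table(self):
        # 2/63 pre-blastoderm vs 72/190 late cortical
        result = contingency_test(Contingency2x2(2, 61, 72, 118), "fisher")
        assert result.p_value == pytest.approx(6.6756e-09, rel=1e-3)

    def test_chisq_closed_form_against_scipy(self):
        from scipy.stats import chi2_contingency

        for table in [(12, 5, 7, 20), (45, 114, 48, 2349), (1, 9, 9, 1)]:
            ours = contingency_test(Contingency2x2(*table), "chisq")
            a, b, c, d = table
            stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
            assert ours.statistic == pytest.approx(stat, rel=1e-12)
            assert ours.p_value == pytest.approx(p, rel=1e-9)

    def test_yates_against_scipy(self):
        from scipy.stats import chi2_contingency

        ours = contingency_test(Contingency2x2(56, 91, 18, 92), "chisq_yates")
        stat, p, _, _ = chi2_contingency([[56, 91], [18, 92]], correction=True)
        assert ours.statistic == pytest.approx(stat, rel=1e-12)
        assert ours.p_value == pytest.approx(p, rel=1e-9)

    def test_low_expected_count_warning(self):
        result = contingency_test(Contingency2x2(1, 2, 2, 1), "chisq")
        assert "< 5" in result.notes

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty margin"):
            contingency_test(Contingency2x2(0, 0, 3, 4), "chisq")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    @settings(max_examples=150, deadline=None)
    def test_fisher_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            return
        ours = contingency_test(Contingency2x2(a, b, c, d), "fisher")
        assert ours.p_value == pytest.approx(
            fisher_oracle_2x2(a, b, c, d), rel=1e-7, abs=1e-12
        )

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
        method=st.sampled_from(["chisq", "chisq_yates", "fisher"]),
    )
    @settings(max_examples=80, deadline=None)
    def test_group_swap_symmetry(self, a, b, c, d, method):
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            return
        table = Contingency2x2(a, b, c, d)
        p1 = contingency_test(table, method).p_value
        p2 = contingency_test(table.swapped(), method).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestFisher2xc:
    def test_reduces_to_2x2(self):
        p_2xc = fisher_exact_2xc([(3, 4), (1, 4)]).p_value
        assert p_2xc == pytest.approx(34 / 70, rel=1e-9)

    @given(
        k1=st.integers(0, 8), t1=st.integers(1, 8),
        k2=st.integers(0, 8), t2=st.integers(1, 8),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_scipy_on_2x2(self, k1, t1, k2, t2):
        from scipy.stats import fisher_exact

        k1, k2 = min(k1, t1), min(k2, t2)
        if k1 + k2 == 0 or (t1 - k1) + (t2 - k2) == 0:
            return
        ours = fisher_exact_2xc([(k1, t1), (k2, t2)]).p_value
        _, p = fisher_exact([[k1, t1 - k1], [k2, t2 - k2]])
        assert ours == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_reproduces_printed_stagewise_p(self):
        groups = [pc.ABNORMALITY_COUNTS[g] for g in pc.CI_STAGE_GROUPS]
        result = fisher_exact_2xc(groups)
        assert result.p_value == pytest.approx(1.9e-8, rel=0.05)

    def test_reproduces_printed_rescue_p(self):
        groups = [pc.ABNORMALITY_COUNTS[g] for g in pc.LATE_STAGE_GROUPS]
        result = fisher_exact_2xc(groups)
        assert result.p_value == pytest.approx(3.8e-16, rel=0.05)

    def test_degenerate_margin(self):
        assert fisher_exact_2xc([(0, 5), (0, 7)]).p_value == 1.0

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xc([(5, 3), (1, 4)])


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


class TestRankTests:
    def test_extreme_separation_exact(self):
        result = rank_test([[1, 2, 3], [4, 5, 6]], "mann_whitney")
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(0.1)
        assert result.notes == "exact"

    def test_identical_samples(self):
        result = rank_test([[1, 2, 3], [1, 2, 3]], "mann_whitney")
        assert result.p_value == pytest.approx(1.0, abs=0.05)

    def test_u1_plus_u2(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        u1 = rank_test([x, y], "mann_whitney").statistic
        u2 = rank_test([y, x], "mann_whitney").statistic
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    @given(
        x=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
        y=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_matches_permutation_oracle(self, x, y):
        if len(set(x) | set(y)) != len(x) + len(y):
            return  # oracle assumes tie-free input
        ours = rank_test([x, y], "mann_whitney")
        assert ours.notes == "exact"
        assert ours.p_value == pytest.approx(mann_whitney_oracle(x, y), rel=1e-9)

    def test_kruskal_identical_groups(self):
        result = rank_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]], "kruskal_wallis")
        assert result.statistic == pytest.approx(0.0, abs=1e-9)

    def test_kruskal_needs_three_groups(self):
        with pytest.raises(ValueError):
            rank_test([[1, 2], [3, 4]], "kruskal_wallis")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_test([[], [1, 2]], "mann_whitney")

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(0.5, 1, size=15)
        p1 = rank_test([x, y], "mann_whitney").p_value
        p2 = rank_test([y, x], "mann_whitney").p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------


class TestPairedT:
    def test_closed_form_example(self):
        # differences [1, 2, 3]: t = 2*sqrt(3), df 2
        pairs = [(2, 1), (4, 2), (6, 3)]
        result = paired_t_test(pairs, normality_check=False)
        assert result.statistic == pytest.approx(2 * math.sqrt(3), rel=1e-9)
        assert result.p_value == pytest.approx(0.0741799, rel=1e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([(1, 1), (2, 2), (3, 3)])

    def test_mean_zero_symmetry(self):
        pairs = [(0, 1), (2, 1), (0, 1), (2, 1)]
        result = paired_t_test(pairs, normality_check=False)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([(1, 2), (3, 4)])

    def test_shapiro_recorded(self):
        rng = np.random.default_rng(2)
        pairs = list(zip(rng.normal(size=10), rng.normal(size=10)))
        result = paired_t_test(pairs, normality_check=True)
        assert "shapiro_x_p=" in result.notes and "shapiro_y_p=" in result.notes


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


class TestLethalPhase:
    def test_printed_ci_counts(self):
        report = lethal_phase_analysis(counts=pc.LETHAL_PHASE_POOLED)
        ci = report["CI"]
        assert ci["blastulation_percent"] == pytest.approx(100 * 45 / 159)
        assert ci["hatch_percent"] == pytest.approx(100 * 48 / 2397)
        assert ci["deficit_percent_points"] == pytest.approx(26.3, abs=0.2)
        assert ci["test"]["p_value"] <= 2e-16  # below the reporting floor

    def test_equal_rates_null(self):
        counts = {"wt": {"blastula": (90, 100), "hatch": (90, 100)}}
        report = lethal_phase_analysis(counts=counts)
        assert report["wt"]["deficit_percent_points"] == 0.0
        assert report["wt"]["test"]["p_value"] == pytest.approx(1.0)

    def test_missing_cross_rejected(self):
        with pytest.raises(ValueError, match="missing crosses"):
            lethal_phase_analysis(
                counts=pc.LETHAL_PHASE_POOLED, crosses=["CI", "nonesuch"]
            )

    def test_simulated_cohort_deficit_matches_model(self):
        from ploidyscan import FateParams, simulate_cohort

        params = FateParams.default()
        n = 10_000
        cohort = simulate_cohort(params, n, seed=21)
        report = lethal_phase_analysis(cohort=cohort)
        cp = params.crosses["CI"]
        expected_deficit = 100 * (
            (cp.p_complete_loss * cp.p_blastula_given_haploid)
            + cp.p_normal * cp.p_blastula_given_diploid * (1 - cp.p_hatch_given_diploid)
        )
        se = 100 * 3 * math.sqrt(0.3 * 0.7 / n) * math.sqrt(2)
        assert report["CI"]["deficit_percent_points"] == pytest.approx(
            expected_deficit, abs=se
        )


class TestDefectRates:
    def test_printed_egg_to_adult(self):
        report = defect_rate_report(
            {name: kt for name, kt in pc.EGG_TO_ADULT.items()}
        )
        assert report["proportions"]["CI"]["percent_rounded"] == 69
        assert report["proportions"]["wild_type"]["percent_rounded"] == 95
        assert report["proportions"]["rescue"]["percent_rounded"] == 87

    def test_printed_abnormality_fraction(self):
        report = defect_rate_report({"ci_12_14": (72, 190)})
        assert report["proportions"]["ci_12_14"]["percent_rounded"] == 38

    def test_comparison_results_attached(self):
        report = defect_rate_report(
            pc.EGG_TO_ADULT, comparisons=[("CI", "wild_type", "fisher")]
        )
        (cmp,) = report["comparisons"]
        assert cmp["groups"] == ["CI", "wild_type"]
        assert cmp["test"]["p_value"] < 1e-6  # strong published difference

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            defect_rate_report({"empty": (0, 0)})

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            defect_rate_report(
                {"a": (1, 2)}, comparisons=[("a", "missing", "chisq")]
            )


class TestTypeOneErrorQuick:
    """Reduced-rep calibration checks; full 10k-rep runs live in the
    acceptance suite."""

    def test_chisq_null_rejection_rate(self):
        rng = np.random.default_rng(5)
        n, reps, alpha = 200, 1500, 0.05
        k = rng.binomial(n, 0.5, size=(reps, 2))
        rejections = 0
        for k1, k2 in k:
            p = contingency_test(
                Contingency2x2.from_proportions(k1, n, k2, n), "chisq"
            ).p_value
            rejections += p < alpha
        assert rejections / reps == pytest.approx(alpha, abs=0.02)

    def test_mann_whitney_null_rejection_rate(self):
        rng = np.random.default_rng(6)
        reps, alpha = 1000, 0.05
        rejections = 0
        for _ in range(reps):
            x, y = rng.normal(size=30), rng.normal(size=30)
            rejections += rank_test([x, y], "mann_whitney").p_value < alpha
        assert rejections / reps == pytest.approx(alpha, abs=0.02)
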