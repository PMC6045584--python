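"""Association statistics against exact/brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemoscreen.pharmaco_stats import (
    FociExperiment,
    anova_curve_comparison,
    foci_positive_fraction,
    mann_whitney_association,
    sensitivity_ranks,
    spearman_drug_correlation,
)


def exact_mann_whitney_p(g0, g1):
    """Two-sided exact p by enumerating all C(n0+n1, n1) label assignments."""
    pooled = np.concatenate([g0, g1])
    n = pooled.size
    n1 = len(g1)

    def u_of(idx):
        sel = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return np.sum(sel[:, None] > rest[None, :]) + 0.5 * np.sum(
            sel[:, None] == rest[None, :]
        )

    u_obs = u_of(range(n - n1, n))  # g1 occupies the tail of pooled
    us = np.array([u_of(idx) for idx in combinations(range(n), n1)])
    p_low = np.mean(us <= u_obs + 1e-12)
    p_high = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def anova_ss_oracle(points_a, points_b):
    """Classical balanced two-way (line x dose) decomposition, no interaction."""
    rows = [(d, s, "A") for d, s, _ in points_a] + [
        (d, s, "B") for d, s, _ in points_b
    ]
    df = pd.DataFrame(rows, columns=["dose", "sf", "line"])
    grand = df["sf"].mean()
    n = len(df)
    ss_line = sum(
        len(g) * (g["sf"].mean() - grand) ** 2 for _, g in df.groupby("line")
    )
    ss_dose = sum(
        len(g) * (g["sf"].mean() - grand) ** 2 for _, g in df.groupby("dose")
    )
    ss_total = ((df["sf"] - grand) ** 2).sum()
    ss_resid = ss_total - ss_line - ss_dose
    df_line = df["line"].nunique() - 1
    df_dose = df["dose"].nunique() - 1
    df_resid = n - 1 - df_line - df_dose
    f = (ss_line / df_line) / (ss_resid / df_resid)
    return float(stats.f.sf(f, df_line, df_resid))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_association(
            [1, 2, 3, 4, 5, 6], ["x", "x", "x", "y", "y", "y"]
        )
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.group_sizes == (3, 3)

    def test_identical_groups_p_one(self):
        res = mann_whitney_association(
            [1, 2, 3, 1, 2, 3], ["x", "x", "x", "y", "y", "y"]
        )
        assert res.p_value == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_association([1, 2, 3], ["x", "x", "x"])

    def test_direction_sign(self):
        res = mann_whitney_association(
            [-2.0, -1.5, -1.8, 0.3, 0.5, 0.1],
            ["mut", "mut", "mut", "wt", "wt", "wt"],
        )
        assert res.direction == 1  # wt median above mut median

    def test_matches_exact_enumeration_oracle(self):
        # tie-free random samples across all sizes with n0 + n1 <= 10
        rng = np.random.default_rng(42)
        for n0 in range(1, 9):
            for n1 in range(1, 9):
                if n0 + n1 > 10:
                    continue
                for _ in range(3):
                    scores = rng.standard_normal(n0 + n1)
                    labels = ["a"] * n0 + ["b"] * n1
                    if np.unique(scores).size < 2:
                        continue
                    res = mann_whitney_association(scores, labels)
                    expected = exact_mann_whitney_p(scores[:n0], scores[n0:])
                    assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_power_on_sensitive_vs_resistant_panels(self):
        # 5 sensitive (Z ~ N(-1.5, 0.3)) vs 15 resistant (Z ~ N(0.3, 0.3))
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            z = np.concatenate(
                [rng.normal(-1.5, 0.3, 5), rng.normal(0.3, 0.3, 15)]
            )
            labels = ["sens"] * 5 + ["res"] * 15
            if mann_whitney_association(z, labels).p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.95


class TestSpearman:
    def test_monotone_pairings(self):
        x = [1.0, 2.5, 3.1, 7.0]
        rho, _ = spearman_drug_correlation(x, [v**2 for v in x])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_drug_correlation(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_value(self):
        rho, _ = spearman_drug_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        rho0, p0 = spearman_drug_correlation(a, b)
        rho1, p1 = spearman_drug_correlation(np.exp(a), b)
        rho2, p2 = spearman_drug_correlation(a, 3 * b - 7)
        assert rho1 == pytest.approx(rho0) and p1 == pytest.approx(p0)
        assert rho2 == pytest.approx(rho0) and p2 == pytest.approx(p0)

    def test_missing_pairs_dropped(self):
        rho, _ = spearman_drug_correlation(
            [1, 2, np.nan, 3, 4], [2, 4, 5.0, 6, 8]
        )
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            spearman_drug_correlation([1, 2], [2, 1])


class TestSensitivityRanks:
    def test_lowest_z_is_rank_one(self):
        ranks = sensitivity_ranks(pd.Series({"a": -2.0, "b": 0.1, "c": -0.5}))
        assert ranks.tolist() == [1.0, 3.0, 2.0]

    def test_ties_share_minimum_rank(self):
        ranks = sensitivity_ranks(pd.Series({"a": -1.0, "b": -1.0, "c": 0.0}))
        assert ranks.tolist() == [1.0, 1.0, 3.0]

    def test_single_line(self):
        assert sensitivity_ranks(pd.Series({"a": 0.7})).tolist() == [1.0]

    def test_missing_scores_unranked(self):
        ranks = sensitivity_ranks(pd.Series({"a": -1.0, "b": np.nan, "c": 0.0}))
        assert np.isnan(ranks["b"]) and ranks["a"] == 1.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            sensitivity_ranks(pd.Series({"a": np.nan}))


def _curve_points(doses, sfs, n_rep, noise, rng):
    return [
        (d, s + rng.normal(0, noise), r)
        for r in range(1, n_rep + 1)
        for d, s in zip(doses, sfs)
    ]


class TestAnovaCurveComparison:
    def test_identical_datasets_p_one(self):
        rng = np.random.default_rng(0)
        pts = _curve_points([1, 10, 100], [0.9, 0.5, 0.1], 3, 0.02, rng)
        assert anova_curve_comparison(pts, list(pts)) == pytest.approx(1.0)

    def test_constant_offset_detected(self):
        rng = np.random.default_rng(1)
        a = _curve_points([1, 10], [0.9, 0.4], 3, 0.0, rng)
        b = [(d, s - 0.3, r) for d, s, r in a]
        assert anova_curve_comparison(a, b) < 1e-6

    def test_matches_ss_oracle_on_hand_instance(self):
        rng = np.random.default_rng(7)
        a = _curve_points([1, 10], [0.9, 0.4], 3, 0.05, rng)
        b = _curve_points([1, 10], [0.7, 0.3], 3, 0.05, rng)
        assert anova_curve_comparison(a, b) == pytest.approx(
            anova_ss_oracle(a, b), abs=1e-10
        )

    def test_matches_ss_oracle_on_random_designs(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            k = int(rng.integers(2, 6))
            r = int(rng.integers(2, 5))
            doses = sorted(rng.uniform(1, 1000, size=k))
            a = _curve_points(doses, rng.uniform(0, 1, k), r, 0.05, rng)
            b = _curve_points(doses, rng.uniform(0, 1, k), r, 0.05, rng)
            assert anova_curve_comparison(a, b) == pytest.approx(
                anova_ss_oracle(a, b), abs=1e-10
            )

    def test_mismatched_dose_grids_raise(self):
        rng = np.random.default_rng(3)
        a = _curve_points([1, 10], [0.9, 0.4], 2, 0.01, rng)
        b = _curve_points([1, 50], [0.9, 0.4], 2, 0.01, rng)
        with pytest.raises(ValueError, match="dose grids"):
            anova_curve_comparison(a, b)

    def test_single_replicate_raises(self):
        rng = np.random.default_rng(4)
        a = _curve_points([1, 10], [0.9, 0.4], 1, 0.01, rng)
        with pytest.raises(ValueError, match="replicate"):
            anova_curve_comparison(a, list(a))


class TestFoci:
    def test_fraction_above_strict_threshold(self):
        exp = FociExperiment(
            {"irradiated": [[7, 2, 9, 0], [6, 6, 1, 1]],
             "mock": [[0, 1, 0, 2], [1, 0, 0, 0]]},
            threshold=5,
        )
        fractions, _ = foci_positive_fraction(exp)
        assert fractions["irradiated"][0] == pytest.approx(0.5)

    def test_counts_equal_to_threshold_are_negative(self):
        exp = FociExperiment(
            {"a": [[5, 5, 5], [5, 5, 5]], "b": [[6, 6, 6], [6, 6, 6]]}, threshold=5
        )
        fractions, _ = foci_positive_fraction(exp)
        assert fractions["a"] == [0.0, 0.0]
        assert fractions["b"] == [1.0, 1.0]

    def test_identical_fractions_t_zero_p_one(self):
        exp = FociExperiment(
            {"a": [[7, 0], [7, 0]], "b": [[8, 1], [9, 2]]}, threshold=5
        )
        fractions, (t, p) = foci_positive_fraction(exp)
        assert fractions["a"] == fractions["b"] == [0.5, 0.5]
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_conditions_significant(self):
        exp = FociExperiment(
            {"proficient": [[8, 9, 7, 6], [9, 8, 8, 7], [7, 9, 6, 8]],
             "defective": [[1, 0, 2, 1], [0, 1, 0, 6], [1, 2, 0, 1]]},
            threshold=5,
        )
        _, (t, p) = foci_positive_fraction(exp, "proficient", "defective")
        assert p < 0.001 and t > 0

    def test_single_replicate_raises(self):
        exp = FociExperiment({"a": [[7, 0]], "b": [[8, 1], [9, 2]]})
        with pytest.raises(ValueError, match="replicates"):
            foci_positive_fraction(exp)
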