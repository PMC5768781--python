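"""Inter-/intra-sample heterogeneity statistics and group tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_matrix
from epihet.heterogeneity import (
    CpGGroupStats,
    group_distance_comparison,
    high_methylation_shift_test,
    intra_heterogeneity_comparison,
    intra_sample_heterogeneity,
    pairwise_distance,
    per_cpg_group_stats,
    quadrant_association,
    sample_intra_heterogeneity,
    select_changed_cpgs,
)
from epihet.methylio import ValidationError


class TestPairwiseDistance:
    def test_identical_profiles_at_zero(self):
        assert pairwise_distance([0.2, 0.5], [0.2, 0.5]) == 0.0

    def test_maximally_discordant_profiles(self):
        assert pairwise_distance([0, 0, 0], [1, 1, 1]) == pytest.approx(1e6)

    def test_worked_three_site_example(self):
        # |0.2-0.1| + |0.4-0.5| + |0.9-0.9| = 0.2 over 3 sites
        d = pairwise_distance([0.2, 0.4, 0.9], [0.1, 0.5, 0.9])
        assert d == pytest.approx(0.2 / 3 * 1e6)
        assert round(d, 2) == 66666.67

    def test_no_shared_sites_errors(self):
        with pytest.raises(ValidationError):
            pairwise_distance([], [])


def test_group_distance_separation():
    same = [0.5, 0.5, 0.5, 0.5]
    m = toy_matrix(
        {"c1": same, "c2": same, "c3": same,
         "e1": [0.1, 0.2, 0.3, 0.4], "e2": [0.9, 0.8, 0.7, 0.6],
         "e3": [0.5, 0.1, 0.9, 0.2]},
        groups={"c1": "control", "c2": "control", "c3": "control",
                "e1": "experimental", "e2": "experimental", "e3": "experimental"},
    )
    _, d_ctrl, d_exp = group_distance_comparison(m)
    assert (d_ctrl["distance"] == 0).all()
    assert (d_exp["distance"] > 0).all()


def test_identical_group_composition_not_significant():
    cols = {"a": [0.1, 0.5, 0.9], "b": [0.2, 0.6, 0.8], "c": [0.3, 0.4, 0.7]}
    values = {f"c_{k}": v for k, v in cols.items()}
    values.update({f"e_{k}": v for k, v in cols.items()})
    groups = {k: ("control" if k.startswith("c_") else "experimental")
              for k in values}
    res, _, _ = group_distance_comparison(toy_matrix(values, groups))
    assert res.pvalue > 0.05


def test_group_with_single_sample_errors():
    m = toy_matrix({"c1": [0.1], "e1": [0.2], "e2": [0.3]},
                   groups={"c1": "control", "e1": "experimental",
                           "e2": "experimental"})
    with pytest.raises(ValidationError, match="within-group"):
        group_distance_comparison(m)


def test_variance_inflation_raises_experimental_distances(sim_matrix):
    res, d_ctrl, d_exp = group_distance_comparison(sim_matrix)
    assert d_exp["distance"].median() > d_ctrl["distance"].median()
    assert res.pvalue < 0.05


class TestPerCpGGroupStats:
    def _matrix(self, ctrl, exp):
        values, groups = {}, {}
        for i, col in enumerate(ctrl):
            values[f"c{i}"] = col
            groups[f"c{i}"] = "control"
        for i, col in enumerate(exp):
            values[f"e{i}"] = col
            groups[f"e{i}"] = "experimental"
        return toy_matrix(values, groups)

    def test_constant_group(self):
        m = self._matrix([[0.1]] * 4, [[0.5]] * 4)
        t = per_cpg_group_stats(m).table
        assert t["mean_ctrl"].iloc[0] == pytest.approx(0.1)
        assert t["iqr_ctrl"].iloc[0] == 0.0

    def test_iqr_linear_interpolation_convention(self):
        # (0.10, 0.20, 0.30, 0.40): Q1 = 0.175, Q3 = 0.325 -> IQR = 0.15
        m = self._matrix([[0.10], [0.20], [0.30], [0.40]], [[0.5], [0.5]])
        t = per_cpg_group_stats(m).table
        assert t["iqr_ctrl"].iloc[0] == pytest.approx(0.15)

    def test_delta_mean_subtraction(self):
        m = self._matrix([[0.8], [0.8]], [[0.3], [0.3]])
        t = per_cpg_group_stats(m).table
        assert t["delta_mean"].iloc[0] == pytest.approx(-0.5)

    def test_singleton_group_iqr_zero_with_warning(self):
        m = self._matrix([[0.1], [0.3]], [[0.5]])
        with pytest.warns(UserWarning, match="single sample"):
            stats = per_cpg_group_stats(m)
        assert (stats.table["iqr_exp"] == 0).all()
        assert stats.singleton_group

    def test_iqr_location_invariance(self):
        base = self._matrix([[0.1], [0.2]], [[0.10], [0.20], [0.40], [0.15]])
        shifted = self._matrix([[0.1], [0.2]],
                               [[0.30], [0.40], [0.60], [0.35]])
        t0 = per_cpg_group_stats(base).table
        t1 = per_cpg_group_stats(shifted).table
        assert t0["iqr_exp"].iloc[0] == pytest.approx(t1["iqr_exp"].iloc[0])


class TestIntraSampleHeterogeneity:
    @pytest.mark.parametrize("m, h", [(0.0, 0.0), (1.0, 0.0), (0.5, 0.5),
                                      (0.8, 0.2), (0.25, 0.25)])
    def test_point_values(self, m, h):
        assert intra_sample_heterogeneity(m) == pytest.approx(h)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            intra_sample_heterogeneity(1.2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetric_about_half(self, m):
        assert intra_sample_heterogeneity(m) == pytest.approx(
            intra_sample_heterogeneity(1.0 - m))

    def test_fully_homogeneous_sample_scores_zero(self):
        m = toy_matrix({"a": [0.0, 1.0, 1.0, 0.0], "b": [0.5, 0.5, 0.5, 0.5]})
        summary = sample_intra_heterogeneity(m)
        assert summary["a"] == 0.0
        assert summary["b"] == 0.5

    def test_paired_comparison_on_matched_sites(self, sim_matrix):
        res = intra_heterogeneity_comparison(sim_matrix)
        assert res.paired and res.pvalue < 1.0


def brute_force_fisher(a, b, c, d):
    """Independent two-sided Fisher p: enumerate the margin-fixed tables."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pmf(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)
                / math.comb(n, r1))
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := pmf(x)) <= p_obs * (1 + 1e-7))


class TestHighMethylationShift:
    def test_identical_margins(self):
        m = toy_matrix(
            {"c1": [0.9, 0.8], "c2": [0.9, 0.8],
             "e1": [0.9, 0.8], "e2": [0.9, 0.8]},
            groups={"c1": "control", "c2": "control",
                    "e1": "experimental", "e2": "experimental"})
        res, counts = high_methylation_shift_test(m)
        assert res.pvalue == pytest.approx(1.0)
        assert counts.loc["control", "high"] == counts.loc["experimental", "high"]

    def test_exactly_at_threshold_is_not_high(self):
        m = toy_matrix(
            {"c1": [0.70], "c2": [0.70], "e1": [0.70], "e2": [0.70]},
            groups={"c1": "control", "c2": "control",
                    "e1": "experimental", "e2": "experimental"})
        _, counts = high_methylation_shift_test(m, threshold=0.70)
        assert counts["high"].sum() == 0

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        n = 160
        ctrl = np.concatenate([rng.uniform(0.75, 1.0, 90), rng.uniform(0.0, 0.65, 70)])
        exp = np.concatenate([rng.uniform(0.75, 1.0, 60), rng.uniform(0.0, 0.65, 100)])
        values = {"c1": ctrl, "c2": ctrl, "e1": exp, "e2": exp}
        m = toy_matrix(values, groups={"c1": "control", "c2": "control",
                                       "e1": "experimental", "e2": "experimental"})
        res, counts = high_methylation_shift_test(m)
        # (high, low) = ctrl (90, 70) vs exp (60, 100)
        assert counts.loc["control", "high"] == 90
        assert res.pvalue == pytest.approx(brute_force_fisher(90, 70, 60, 100),
                                           abs=1e-12)


def _stats(delta_mean, delta_iqr):
    import pandas as pd

    n = len(delta_mean)
    table = pd.DataFrame(
        {"mean_ctrl": 0.5, "mean_exp": 0.5, "iqr_ctrl": 0.1, "iqr_exp": 0.1,
         "delta_mean": delta_mean, "delta_iqr": delta_iqr},
        index=[f"chr1:{i + 1}:+" for i in range(n)],
    )
    return CpGGroupStats(table=table)


class TestSelectChangedCpGs:
    def test_selection_rules(self):
        stats = _stats([-0.25, -0.10, 0.20, 0.05], [0.05, 0.10, 0.0, 0.30])
        kept = select_changed_cpgs(stats, cutoff=0.20)
        # first site passes on delta_mean, last on delta_iqr; 0.20 exactly drops
        assert list(kept) == ["chr1:1:+", "chr1:4:+"]


class TestQuadrantAssociation:
    def test_p_matches_enumeration_oracle(self):
        dm = [-0.3] * 40 + [0.3] * 10 + [-0.3] * 10 + [0.3] * 40
        di = [0.2] * 40 + [0.2] * 10 + [-0.2] * 10 + [-0.2] * 40
        res, counts = quadrant_association(_stats(dm, di))
        assert counts.to_numpy().tolist() == [[40, 10], [10, 40]]
        assert res.pvalue == pytest.approx(brute_force_fisher(40, 10, 10, 40),
                                           abs=1e-12)

    def test_independent_counts(self):
        dm = ([-0.3] * 25 + [0.3] * 25) * 2
        di = [0.2] * 50 + [-0.2] * 50
        res, counts = quadrant_association(_stats(dm, di))
        assert res.statistic == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_single_site_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res, _ = quadrant_association(_stats([-0.3], [0.2]))
        assert res.pvalue == 1.0
        assert res.degenerate

    def test_zero_deltas_count_with_loss_cell(self):
        _, counts = quadrant_association(_stats([0.0, -0.1], [0.0, 0.1]))
        assert counts.loc["hypo", "iqr_down"] == 1  # the (0, 0) site
        assert counts.loc["hypo", "iqr_up"] == 1


def test_planted_sites_inflate_delta_iqr(sim_result, sim_stats):
    planted = sim_stats.table.index.isin(sim_result.truth.perturbed_sites)
    med_planted = sim_stats.table.loc[planted, "delta_iqr"].median()
    med_background = sim_stats.table.loc[~planted, "delta_iqr"].median()
    assert med_planted > med_background
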