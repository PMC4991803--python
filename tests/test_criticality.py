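import numpy as np
import pandas as pd
import pytest

from connvuln import criticality as crit


def vuln_frame(values_by_prop):
    n = len(next(iter(values_by_prop.values())))
    return pd.DataFrame(
        {f"V_{p}": v for p, v in values_by_prop.items()},
        index=[f"t{i}" for i in range(n)],
    )


class TestSdGrade:
    def test_arithmetic(self):
        assert crit.sd_grade(0.26, mean=0.10, sd=0.05) == 3

    def test_value_at_mean_is_zero(self):
        assert crit.sd_grade(0.10, mean=0.10, sd=0.05) == 0

    def test_below_mean_clipped_to_zero(self):
        assert crit.sd_grade(0.0, mean=0.10, sd=0.05) == 0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            crit.sd_grade([1.0, 1.0, 1.0])

    def test_floor_vs_round(self):
        assert crit.sd_grade(0.29, mean=0.10, sd=0.05, method="floor") == 3
        assert crit.sd_grade(0.29, mean=0.10, sd=0.05, method="round") == 4

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=50)
        g1 = crit.sd_grade(v)
        g2 = crit.sd_grade(3.7 * v + 11.0)
        assert np.array_equal(g1, g2)


class TestNodeCriticalSet:
    def test_all_equal_vulnerabilities_give_empty_sets(self):
        table = vuln_frame({p: [0.2] * 10 for p in "CEB"})
        sets, union = crit.node_critical_set(table)
        assert union == [] and all(len(s) == 0 for s in sets.values())

    def test_single_planted_outlier_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.1, 0.01, size=100)
        mean, sd = base.mean(), base.std(ddof=1)
        base[17] = mean + 10 * sd
        table = vuln_frame({"C": base, "E": base, "B": base})
        sets, union = crit.node_critical_set(table, multiplier=3)
        assert union == ["t17"]
        assert sets["E"].members["t17"] >= 3

    def test_threshold_consistency(self):
        rng = np.random.default_rng(1)
        table = vuln_frame({p: rng.exponential(0.05, 200) for p in "CEB"})
        sets, _ = crit.node_critical_set(table, multiplier=3)
        for p, cs in sets.items():
            for target in cs.members:
                assert table.loc[target, f"V_{p}"] > cs.mean + cs.multiplier * cs.sd
            # and non-members re-test below threshold
            non = table.index.difference(list(cs.members))
            assert (table.loc[non, f"V_{p}"] <= cs.threshold).all()

    def test_planted_outlier_recovery_rate(self):
        """>=95% exact recovery of k planted >=5 sd outliers over 200 trials."""
        hits, fp_counts = 0, []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            v = rng.normal(0.1, 0.02, size=100)
            k = int(rng.integers(1, 4))
            planted = rng.choice(100, size=k, replace=False)
            v[planted] = v.mean() + (5 + rng.random(k) * 3) * v.std(ddof=1)
            table = vuln_frame({"C": v, "E": v, "B": v})
            _, union = crit.node_critical_set(table, multiplier=3)
            found = {f"t{i}" for i in planted}
            got = set(union)
            if found <= got:
                hits += 1
            fp_counts.append(len(got - found))
        assert hits / 200 >= 0.95
        assert np.median(fp_counts) <= 2


class TestSdHistogram:
    def test_all_below_one_sd_is_empty(self):
        v = np.array([0.0, 0.0, 1.0, 1.0])  # max z-score 0.87 < 1
        assert crit.sd_histogram(v) == {}

    def test_constructed_grades_counted(self):
        # values engineered to have grades {1,1,1,2,2,3} plus background 0s
        mean, sd = 0.0, 1.0
        v = [0.0] * 20 + [1.1, 1.2, 1.3, 2.1, 2.2, 3.1]
        v = np.array(v)
        got = crit.sd_histogram(v, ddof=0)
        grades = crit.sd_grade(v, ddof=0)
        expected = {}
        for g in grades[grades >= 1]:
            expected[int(g)] = expected.get(int(g), 0) + 1
        for k in range(1, max(expected) + 1):
            expected.setdefault(k, 0)
        assert got == expected

    def test_total_equals_targets_at_or_above_one_sd(self):
        rng = np.random.default_rng(3)
        v = rng.exponential(1.0, 500)
        hist = crit.sd_histogram(v)
        assert sum(hist.values()) == int((crit.sd_grade(v) >= 1).sum())


class TestChangepoint:
    def test_two_slope_log_histogram_splits_at_six(self):
        # log-counts decay with slope -1 on bins 1-6, then plateau on 7-12
        hist = {k: 10 ** (6 - k) - 1 for k in range(1, 7)}
        hist.update({k: 9 for k in range(7, 13)})
        assert crit.changepoint(hist) == 6

    def test_perfectly_linear_ties_to_smallest_split(self):
        # exactly linear in log10(count + 1): every split fits perfectly
        hist = {k: 10 ** (8 - k) - 1 for k in range(1, 9)}
        assert crit.changepoint(hist) == 2  # smallest admissible split

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="4 bins"):
            crit.changepoint({1: 5, 2: 3, 3: 1})

    def test_invariant_to_input_dict_order(self):
        hist = {1: 100, 2: 40, 3: 12, 4: 5, 5: 5, 6: 5, 7: 4}
        shuffled = dict(sorted(hist.items(), key=lambda kv: -kv[0]))
        assert crit.changepoint(hist) == crit.changepoint(shuffled)


class TestEdgeCriterion:
    def test_most_conservative_wins(self):
        assert crit.edge_criterion({"C": 4, "E": 6, "B": 5}) == 6

    def test_all_equal(self):
        assert crit.edge_criterion({"C": 5, "E": 5, "B": 5}) == 5


class TestGroupComparison:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        mask = np.zeros(40, bool)
        mask[:20] = True
        v[mask] = v[~mask]  # make distributions identical
        res = crit.group_comparison(v, mask)
        assert res["U"] == pytest.approx(20 * 20 / 2, rel=0.1)
        assert res["p"] > 0.5

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, size=60)
        mask = np.zeros(60, bool)
        mask[:15] = True
        v[mask] += 10.0
        assert crit.group_comparison(v, mask)["p"] < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            crit.group_comparison([1.0, 2.0], [False, False])


class TestCorrelations:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        props = pd.DataFrame({"x": x})
        sv = pd.DataFrame({"sV_E": x, "sV_B": -x})
        out = crit.property_vulnerability_correlation(props, sv)
        assert out.loc["x", ("sV_E", "rho")] == pytest.approx(1.0)
        assert out.loc["x", ("sV_B", "rho")] == pytest.approx(-1.0)

    def test_independent_vectors_uncorrelated(self):
        rng = np.random.default_rng(9)
        props = pd.DataFrame({"x": rng.normal(size=279)})
        sv = pd.DataFrame({"sV_E": rng.normal(size=279)})
        out = crit.property_vulnerability_correlation(props, sv)
        assert abs(out.loc["x", ("sV_E", "rho")]) < 0.15
        assert out.loc["x", ("sV_E", "p")] > 0.05

    def test_zero_variance_flagged_missing(self):
        props = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        sv = pd.DataFrame({"sV_E": [0.1, 0.2, 0.3, 0.4]})
        out = crit.property_vulnerability_correlation(props, sv)
        assert np.isnan(out.loc["x", ("sV_E", "rho")])
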