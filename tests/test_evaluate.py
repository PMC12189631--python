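import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awsproc.evaluate import (
    build_report,
    dunnett_vs_reference,
    kruskal_dunn,
    margin_ratio,
    mean_abs_diff,
    rmse,
    tukey_hsd_test,
    variance_homogeneity,
)
from conftest import make_references


class TestRmse:
    def test_symmetric_errors(self):
        assert rmse([(310, 300), (320, 330)]) == pytest.approx(10.0)

    def test_perfect_agreement(self):
        assert rmse([(300, 300), (350, 350)]) == 0.0

    def test_single_pair(self):
        assert rmse([(305, 300)]) == pytest.approx(5.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rmse([])

    def test_rmse_at_least_mean_abs_diff(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pairs = list(zip(rng.uniform(300, 400, 20), rng.uniform(300, 400, 20)))
            assert rmse(pairs) >= mean_abs_diff(pairs) - 1e-12


class TestMarginRatio:
    def test_exact_boundary_counts_inside(self):
        assert margin_ratio([(315, 300)], 5) == 100.0

    def test_just_outside_ten_percent(self):
        assert margin_ratio([(331, 300)], 10) == 0.0

    def test_fractional_count(self):
        pairs = [(300, 300), (310, 300), (290, 300), (330, 300)]
        assert margin_ratio(pairs, 5) == 75.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            margin_ratio([(300, 0)], 5)

    def test_margins_nested(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            ref = rng.uniform(300, 400, 30)
            est = ref + rng.normal(0, 30, 30)
            pairs = list(zip(est, ref))
            assert margin_ratio(pairs, 5) <= margin_ratio(pairs, 10)


class TestVarianceHomogeneity:
    def test_identical_groups_give_f_one_p_one(self):
        g = list(np.random.default_rng(1).normal(350, 10, 30))
        out = variance_homogeneity({"ref": g, "m": list(g)}, "ref")
        assert out["F"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_doubled_scale_gives_f_four(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 25)
        out = variance_homogeneity({"ref": a, "m": 2 * a}, "ref")
        f = out["F"].iloc[0]
        assert f == pytest.approx(4.0)
        # p agrees with the closed-form two-sided F probability
        expect = 2 * min(stats.f.cdf(f, 24, 24), stats.f.sf(f, 24, 24))
        assert out["p"].iloc[0] == pytest.approx(expect)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            variance_homogeneity({"ref": [1.0, 2.0], "m": [1.0]}, "ref")


class TestDunnett:
    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "ref": rng.normal(350, 5, 30),
            "ok": rng.normal(350, 5, 30),
            "shifted": rng.normal(400, 5, 30),
        }
        out = dunnett_vs_reference(groups, "ref").set_index("group")
        assert out.loc["shifted", "p_adjusted"] < 0.05
        assert out.loc["ok", "p_adjusted"] > 0.05

    def test_identical_constant_groups_no_rejections(self):
        groups = {"ref": [350.0] * 10, "a": [350.0] * 10, "b": [350.0] * 10}
        out = dunnett_vs_reference(groups, "ref")
        assert (out["p_adjusted"] > 0.05).all()

    def test_missing_reference(self):
        with pytest.raises((KeyError, ValueError)):
            dunnett_vs_reference({"a": [1.0, 2.0]}, "ref")


class TestTukeyHsd:
    def test_identical_groups_not_significant(self):
        g = list(np.random.default_rng(4).normal(350, 10, 30))
        out = tukey_hsd_test({"a": g, "b": list(g), "c": list(g)})
        assert (out["p_adjusted"] > 0.99).all()

    def test_one_shifted_group_flags_exactly_its_pairs(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.normal(350, 5, 30),
            "b": rng.normal(350, 5, 30),
            "c": rng.normal(400, 5, 30),
        }
        out = tukey_hsd_test(groups)
        sig = out[out["p_adjusted"] < 0.05]
        assert sorted(map(tuple, sig[["group_a", "group_b"]].values)) == [("a", "c"), ("b", "c")]

    def test_two_groups_match_students_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        p_tukey = tukey_hsd_test({"a": a, "b": b})["p_adjusted"].iloc[0]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_tukey == pytest.approx(p_t, abs=1e-6)


class TestKruskalDunn:
    def test_hand_computed_h(self):
        # ranks 1..6, rank sums 6 and 15:
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7 = 3.857
        h, p, dunn = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(27 / 7, abs=1e-3)
        assert len(dunn) == 1

    def test_all_identical_defines_h_zero(self):
        h, p, _ = kruskal_dunn({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert h == 0.0 and p == 1.0

    def test_tie_correction_inflates_h(self):
        groups = {"a": [1, 2, 2, 3], "b": [2, 4, 4, 5]}
        h, _, _ = kruskal_dunn(groups)
        # uncorrected H from the same rank sums
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        r_a, r_b = ranks[:4].sum(), ranks[4:].sum()
        h_uncorr = 12 / (n * (n + 1)) * (r_a**2 / 4 + r_b**2 / 4) - 3 * (n + 1)
        assert h >= h_uncorr

    def test_dunn_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        groups = {k: rng.normal(m, 1, 15) for k, m in [("a", 0), ("b", 0.5), ("c", 2)]}
        _, _, dunn = kruskal_dunn(groups)
        assert (dunn["p_adjusted"] >= dunn["p_raw"] - 1e-12).all()
        assert dunn["p_adjusted"].between(0, 1).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2, 3]})


class TestBuildReport:
    def _inputs(self, windows):
        rng = np.random.default_rng(10)
        animals = [f"a{i}" for i in range(12)]
        w = windows[0]
        refs = make_references([(a, w.mid_date, float(rng.uniform(320, 380))) for a in animals])
        rows = []
        for rule in ("tukey", "sd"):
            for post in (False, True):
                for m in ("mean", "median", "linear_regression"):
                    for a in animals:
                        ref = refs[refs.animal_id == a]["weight_kg"].iloc[0]
                        rows.append((rule, post, a, w.label, m, ref + rng.normal(0, 5), 7))
        est = pd.DataFrame(
            rows, columns=["rule", "post", "animal_id", "window", "method", "estimate_kg", "n_days"]
        )
        return est, refs

    def test_layout_and_total_aggregation(self, windows):
        est, refs = self._inputs(windows)
        report, battery = build_report(est, refs, windows[:1])
        # 2 rules x 2 post states x 3 methods, each with window row + Total row
        assert len(report) == 12 * 2
        one = report[(report["rule"] == "tukey") & (~report["post"]) & (report["method"] == "mean")]
        feb = one[one["window"] == "Feb"].iloc[0]
        tot = one[one["window"] == "Total"].iloc[0]
        assert feb["rmse"] == pytest.approx(tot["rmse"])   # single window: Total == window
        assert feb["pct_within_5"] <= feb["pct_within_10"]
        assert "tukey/False" in battery
        assert "dunnett" in battery["tukey/False"]["Total"]

    def test_all_missing_method_flagged_not_dropped(self, windows):
        est, refs = self._inputs(windows)
        est.loc[est["method"] == "linear_regression", "estimate_kg"] = np.nan
        report, _ = build_report(est, refs, windows[:1])
        row = report[(report["method"] == "linear_regression") & (report["window"] == "Total")].iloc[0]
        assert row["n"] == 0 and row["n_excluded"] == 12

    def test_no_joinable_pairs_raises(self, windows):
        est, refs = self._inputs(windows)
        refs = refs.assign(animal_id=refs["animal_id"] + "_other")
        with pytest.raises(ValueError, match="no joinable"):
            build_report(est, refs, windows[:1])

    def test_unbiased_noise_gives_no_significant_differences(self, windows):
        """With unbiased estimator noise the battery should find no
        difference between any method and the reference (p > 0.05)."""
        est, refs = self._inputs(windows)
        _, battery = build_report(est, refs, windows[:1])
        for combo in ("tukey/False", "tukey/True", "sd/False", "sd/True"):
            dunnett = battery[combo]["Total"]["dunnett"]
            assert all(d["p_adjusted"] > 0.05 for d in dunnett)
            kw = battery[combo]["Total"]["kruskal_wallis"]
            assert kw["p"] > 0.05
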