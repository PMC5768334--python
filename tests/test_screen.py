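import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import lungmarkers as lm
from lungmarkers.screen import (
    FilterCriteria,
    FilterResult,
    GroupSummary,
    ProbeScreenRecord,
    ElevationStats,
)

# normal values with mean 4, sample sd exactly 0.5 -> cutoff 5.5
NORMALS_MEAN4_SD05 = [3.5, 4.0, 4.5]


class TestElevation:
    def test_cutoff_arithmetic(self):
        assert lm.elevation_cutoff(4.0, 0.5) == pytest.approx(5.5)
        assert lm.elevation_cutoff(6.0, 0.0) == pytest.approx(6.0)

    def test_cutoff_rejects_undefined_sd(self):
        with pytest.raises(ValueError):
            lm.elevation_cutoff(4.0, None)

    def test_hand_example(self):
        ele = lm.elevation_stats([5, 6, 7, 8], NORMALS_MEAN4_SD05)
        assert ele.cutoff == pytest.approx(5.5)
        assert ele.pct_elevated_tumor == pytest.approx(75.0)
        assert ele.avg_tumor_elevated == pytest.approx(7.0)
        assert ele.log2_ratio_elevated == pytest.approx(3.0)
        assert ele.pct_elevated_normal == pytest.approx(0.0)

    def test_tie_at_cutoff_not_elevated(self):
        ele = lm.elevation_stats([5.5, 5.5], NORMALS_MEAN4_SD05)
        assert ele.pct_elevated_tumor == 0.0

    def test_no_elevated_tumor_undefined_ratio(self):
        ele = lm.elevation_stats([4.0, 4.2], NORMALS_MEAN4_SD05)
        assert ele.pct_elevated_tumor == 0.0
        assert ele.avg_tumor_elevated is None
        assert ele.log2_ratio_elevated is None

    def test_planted_probe_fraction_recovered(self):
        # Monte-Carlo: half the tumors shifted 4 log2 units above N(6, 0.5)
        rng = np.random.default_rng(11)
        normal = rng.normal(6, 0.5, 400)
        tumor = rng.normal(6, 0.5, 200)
        tumor[: 100] += 4.0
        ele = lm.elevation_stats(tumor, normal)
        assert ele.pct_elevated_tumor == pytest.approx(50.0, abs=10.0)


class TestTwoSidedTTest:
    def test_identical_groups(self):
        assert lm.two_sided_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_complete_separation(self):
        p = lm.two_sided_t_test([0, 0.01, 0, 0.005], [10, 10.01, 10, 10.005])
        assert p < 1e-8

    def test_zero_variance_convention(self):
        assert lm.two_sided_t_test([2, 2], [2, 2]) == 1.0
        assert lm.two_sided_t_test([2, 2], [3, 3]) == 0.0

    def test_matches_welch_formula(self):
        # independent oracle: Welch statistic and Satterthwaite df by hand
        x = np.array([1.2, 3.4, 2.2, 5.0, 4.1])
        y = np.array([2.0, 2.1, 6.3, 3.3, 3.9])
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        expected = 2 * stats.t.sf(abs(t), df)
        assert lm.two_sided_t_test(x, y) == pytest.approx(expected, abs=1e-10)


def exact_mann_whitney_p(x, y):
    """Brute-force oracle: U null distribution over all rank assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    us = np.array(
        [
            u_stat(pooled[list(i)], np.delete(pooled, list(i)))
            for i in itertools.combinations(range(len(pooled)), nx)
        ]
    )
    u_obs = u_stat(x, y)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestMannWhitney:
    def test_identical_singletons(self):
        assert lm.mann_whitney_u([5.0], [5.0]) == 1.0

    def test_complete_separation_10v10(self):
        p = lm.mann_whitney_u(np.arange(10.0), np.arange(100.0, 110.0))
        assert p < 1e-3
        assert exact_mann_whitney_p(np.arange(4.0), np.arange(100.0, 104.0)) == pytest.approx(
            2 / 70
        )

    def test_asymptotic_close_to_exact_4v4(self):
        # The continuity-corrected normal approximation deviates from the
        # exact permutation distribution by at most ~0.031 at n=4 vs 4
        # (worst at mid-range U); in the decision-relevant region
        # (exact p < 0.3) agreement is within 0.01.
        pooled = np.arange(1.0, 9.0)
        for idx in itertools.combinations(range(8), 4):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            p_exact = exact_mann_whitney_p(x, y)
            p_asym = lm.mann_whitney_u(x, y)
            assert abs(p_exact - p_asym) < 0.035
            if p_exact < 0.3:
                assert abs(p_exact - p_asym) < 0.01


class TestHellinger:
    def test_identical_gaussians(self):
        assert lm.hellinger_gaussian(3.0, 1.2, 3.0, 1.2) == 0.0

    def test_large_separation_limit(self):
        assert lm.hellinger_gaussian(0.0, 1.0, 1e4, 1.0) == pytest.approx(1.0)

    def test_known_value(self):
        assert lm.hellinger_gaussian(0, 1, 2, 1) == pytest.approx(0.6273, abs=5e-5)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            lm.hellinger_gaussian(0, 0.0, 1, 1)

    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.01, 10), s2=st.floats(0.01, 10),
    )
    def test_symmetric_and_bounded(self, m1, m2, s1, s2):
        h = lm.hellinger_gaussian(m1, s1, m2, s2)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(lm.hellinger_gaussian(m2, s2, m1, s1))


class TestBonferroni:
    def test_published_denominator(self):
        thr = lm.bonferroni_threshold(0.05, 11838)
        assert float(f"{thr:.4e}") == pytest.approx(4.2237e-6)

    def test_trivial_cases(self):
        assert lm.bonferroni_threshold(0.05, 1) == 0.05
        assert lm.bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)


class TestMarkerScore:
    @pytest.mark.parametrize(
        "pct_t,pct_n,ratio,expected",
        [(50, 0, 3, 150), (25, 25, 4, 0), (30, 40, 2, -20)],
    )
    def test_examples(self, pct_t, pct_n, ratio, expected):
        assert lm.marker_score(pct_t, pct_n, ratio) == expected

    def test_undefined_ratio(self):
        assert lm.marker_score(50, 0, None) is None

    @given(
        pct_t=st.floats(0, 100), pct_n=st.floats(0, 100),
        r1=st.floats(0.1, 10), delta=st.floats(0.1, 5),
    )
    def test_increasing_in_ratio_when_tumor_exceeds_normal(self, pct_t, pct_n, r1, delta):
        if pct_t > pct_n:
            assert lm.marker_score(pct_t, pct_n, r1 + delta) > lm.marker_score(
                pct_t, pct_n, r1
            )


def make_record(avg_elev=7.0, pct_t=50.0, pct_n=0.0, ratio=3.0, t_p=1e-9, u_p=1e-9, h=0.8):
    ele = ElevationStats(
        cutoff=5.0,
        pct_elevated_tumor=pct_t,
        pct_elevated_normal=pct_n,
        avg_tumor_elevated=avg_elev,
        log2_ratio_elevated=ratio,
    )
    return ProbeScreenRecord(
        probe_id="p", gene=None,
        tumor=GroupSummary("lung_tumor", 60, 6.0, 1.0),
        normal=GroupSummary("lung_normal", 40, 4.0, 0.5),
        elevation=ele, t_p=t_p, u_p=u_p, hellinger=h,
    )


class TestApplyFilters:
    def test_all_criteria_met(self):
        res = lm.apply_filters(make_record(), FilterCriteria(), n_probes=11838)
        assert res.overall

    def test_ratio_boundary_inclusive(self):
        res = lm.apply_filters(make_record(ratio=2.0), FilterCriteria(), 11838)
        assert res.pass_log2_ratio and res.overall

    def test_fails_on_ratio_only(self):
        res = lm.apply_filters(make_record(ratio=1.9), FilterCriteria(), 11838)
        assert not res.pass_log2_ratio
        assert res.pass_avg_elevated and res.pass_pct_elevated
        assert res.pass_t_test and res.pass_u_test and res.pass_hellinger
        assert not res.overall

    def test_strict_thresholds(self):
        res = lm.apply_filters(
            make_record(avg_elev=5.0, pct_t=25.0, h=1 / 3), FilterCriteria(), 100
        )
        assert not res.pass_avg_elevated
        assert not res.pass_pct_elevated
        assert not res.pass_hellinger

    def test_undefined_elevation_fails(self):
        rec = make_record(avg_elev=None, ratio=None)
        res = lm.apply_filters(rec, FilterCriteria(), 100)
        assert not res.overall


class TestScreen:
    def test_planted_probe_rank_one(self, planted_compendium):
        comp, truth = planted_compendium
        df = lm.screen(comp)
        assert df.iloc[0]["probe_id"] in truth.probe_ids
        assert bool(df.iloc[0]["pass_overall"])

    def test_missing_group_is_error(self, toy_compendium):
        comp = toy_compendium
        groups = comp.sample_group.replace("lung_normal", "liver")
        broken = lm.ExpressionCompendium(values=comp.values, sample_group=groups)
        with pytest.raises(ValueError, match="lung_normal"):
            lm.screen(broken)

    def test_ties_ordered_by_probe_id(self, rng):
        # duplicated probe rows -> identical MarkerScore; order must be stable
        base = rng.normal(6, 0.5, 30)
        values = pd.DataFrame(
            [base, base, base],
            index=["pz", "pa", "pm"],
            columns=[f"s{i}" for i in range(30)],
        )
        groups = pd.Series(
            ["lung_tumor"] * 15 + ["lung_normal"] * 15, index=values.columns
        )
        comp = lm.ExpressionCompendium(values=values, sample_group=groups)
        df = lm.screen(comp)
        assert df["probe_id"].tolist() == ["pa", "pm", "pz"]

    def test_column_order_invariance(self, planted_compendium):
        comp, _ = planted_compendium
        perm = list(np.random.default_rng(3).permutation(comp.sample_ids))
        shuffled = lm.ExpressionCompendium(
            values=comp.values[perm], sample_group=comp.sample_group
        )
        a = lm.screen(comp).set_index("probe_id")
        b = lm.screen(shuffled).set_index("probe_id")
        pd.testing.assert_series_equal(a["marker_score"], b["marker_score"])
        pd.testing.assert_series_equal(a["pass_overall"], b["pass_overall"])

    def test_tightening_never_enlarges_passing_set(self, planted_compendium):
        comp, _ = planted_compendium
        loose = FilterCriteria(min_pct_elevated_tumor=10.0, alpha=0.05)
        base_pass = set(
            lm.screen(comp, loose).query("pass_overall")["probe_id"]
        )
        for tighter in [
            FilterCriteria(min_pct_elevated_tumor=30.0),
            FilterCriteria(min_log2_ratio=3.0),
            FilterCriteria(alpha=0.001),
            FilterCriteria(hellinger_min=0.6),
            FilterCriteria(min_avg_tumor_elevated=8.0),
        ]:
            tight_pass = set(lm.screen(comp, tighter).query("pass_overall")["probe_id"])
            assert tight_pass <= base_pass

    def test_extra_tissue_means_reported(self):
        spec = lm.CompendiumSpec(
            n_probes=20,
            group_sizes={"lung_tumor": 10, "lung_normal": 10, "liver": 5},
            planted=(
                lm.PlantedMarkerSpec(
                    probe_index=3, elevated_fraction=1.0, effect_log2=4.0,
                    leak_tissues={"liver": 4.0},
                ),
            ),
            seed=5,
        )
        comp, _ = lm.simulate_compendium(spec)
        df = lm.screen(comp).set_index("probe_id")
        assert "avg_liver" in df.columns
        planted_row = df.loc["probe_00003"]
        null_mean = df.drop("probe_00003")["avg_liver"].mean()
        assert planted_row["avg_liver"] > null_mean + 2.0


class TestGroupComparisons:
    def test_dunnett_single_group_reduces_to_pooled_t(self, rng):
        control = rng.normal(0, 1, 12)
        grp = rng.normal(0.5, 1, 10)
        res = lm.dunnett_control_comparisons(control, {"g": grp})
        expected = stats.ttest_ind(grp, control, equal_var=True).pvalue
        # scipy evaluates the multivariate-t probability numerically
        assert res["g"] == pytest.approx(expected, abs=1e-3)

    def test_dunnett_identical_groups_p_near_one(self):
        x = list(np.arange(10.0))
        res = lm.dunnett_control_comparisons(x, {"a": x, "b": x})
        assert all(p > 0.99 for p in res.values())

    def test_dunnett_familywise_error_controlled(self):
        rng = np.random.default_rng(42)
        hits = 0
        reps = 500
        for _ in range(reps):
            control = rng.normal(0, 1, 20)
            groups = {f"g{i}": rng.normal(0, 1, 15) for i in range(3)}
            ps = lm.dunnett_control_comparisons(control, groups)
            hits += any(p < 0.05 for p in ps.values())
        # 0.05 + 3 binomial sigmas at 500 reps
        assert hits / reps <= 0.08

    def test_tukey_two_groups_reduces_to_pooled_t(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 1, 12)
        res = lm.tukey_pairwise({"a": a, "b": b})
        expected = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert res[("a", "b")] == pytest.approx(expected, abs=1e-6)

    def test_tukey_identical_groups_p_near_one(self):
        x = list(np.arange(8.0))
        res = lm.tukey_pairwise({"a": x, "b": x, "c": x})
        assert all(p > 0.99 for p in res.values())

    def test_tukey_familywise_error_controlled(self):
        rng = np.random.default_rng(43)
        hits = 0
        reps = 300
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0, 1, 15) for i in range(4)}
            ps = lm.tukey_pairwise(groups)
            hits += any(p < 0.05 for p in ps.values())
        # 0.05 + 3 binomial sigmas at 300 reps
        assert hits / reps <= 0.09

    def test_tukey_requires_two_groups(self):
        with pytest.raises(ValueError):
            lm.tukey_pairwise({"a": [1.0, 2.0]})
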