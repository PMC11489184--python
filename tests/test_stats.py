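"""Well inclusion, cumulative ratios, outlier rule, BMR, ANOVA, flags."""

import numpy as np
import pandas as pd
import pytest

from meanet import (
    anova_oneway,
    anova_twoway,
    bmr_band,
    cumulative_ratios,
    exclude_outliers,
    flag_and_summarize,
    include_wells,
)
from meanet.metrics import PARAMETERS

DIVS = (7, 10, 14, 17, 21, 24, 28)


def metrics_frame(n_ctrl=6, n_cond=6, cond_scale=1.0, seed=0, compound="X", conc=10.0,
                  n_bursting=8):
    """Synthetic metrics table with positive raw values for every parameter."""
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("male", "female"):
        for grp, n, scale in (("DMSO", n_ctrl, 1.0), (compound, n_cond, cond_scale)):
            for w in range(n):
                well = f"{grp}-{sex}-{w}"
                base = rng.uniform(0.8, 1.2, len(PARAMETERS))
                for div in DIVS:
                    vals = base * (10.0 if grp == "DMSO" else 10.0 * scale)
                    row = dict(
                        experiment="e1", well=well, div=div, compound=grp,
                        concentration_um=0.0 if grp == "DMSO" else conc, sex=sex,
                        n_bursting_electrodes=n_bursting, n_included_electrodes=16,
                    )
                    row.update({p: v for p, v in zip(PARAMETERS, vals)})
                    rows.append(row)
    return pd.DataFrame(rows)


class TestIncludeWells:
    @pytest.mark.parametrize("n_bursting,kept", [(3, False), (4, True), (16, True)])
    def test_baseline_bursting_electrode_floor(self, n_bursting, kept):
        df = metrics_frame(n_ctrl=2, n_cond=0, n_bursting=n_bursting)
        out = include_wells(df)
        assert (len(out) > 0) is kept
        if not kept:
            assert out.empty  # exclusion applies to every DIV of the well


class TestCumulativeRatios:
    def test_control_curve_ends_at_exactly_100(self):
        ratios, _ = cumulative_ratios(metrics_frame())
        ctrl = ratios[(ratios["compound"] == "DMSO") & (ratios["div"] == 28)
                      & ~ratios["outlier"]]
        means = ctrl.groupby(["sex", "parameter"])["ratio_pct"].mean()
        assert np.allclose(means, 100.0, atol=1e-9)

    def test_doubled_condition_sits_at_200_everywhere(self):
        ratios, _ = cumulative_ratios(metrics_frame(cond_scale=2.0, seed=1))
        # wells share per-well baselines, so group means (not each well) are exact
        cond = ratios[ratios["compound"] == "X"]
        ctrl = ratios[ratios["compound"] == "DMSO"]
        for div in DIVS:
            m_cond = cond[cond["div"] == div].groupby("parameter")["ratio_pct"].mean()
            m_ctrl = ctrl[ctrl["div"] == div].groupby("parameter")["ratio_pct"].mean()
            assert np.allclose(m_cond / m_ctrl, 2.0, rtol=0.15)

    def test_all_zero_condition_gives_flat_zero_curve(self):
        df = metrics_frame(seed=2)
        df.loc[df["compound"] == "X", list(PARAMETERS)] = 0.0
        ratios, _ = cumulative_ratios(df)
        cond = ratios[ratios["compound"] == "X"]
        assert np.allclose(cond["ratio_pct"], 0.0)

    def test_cumulative_monotone_in_div(self):
        ratios, _ = cumulative_ratios(metrics_frame(seed=3))
        g = ratios.sort_values("div").groupby(["experiment", "well", "parameter"])
        for _, grp in list(g)[:50]:
            v = grp["cumulative_raw"].to_numpy()
            assert np.all(np.diff(v) >= -1e-12)

    def test_missing_raw_value_propagates_not_imputed(self):
        df = metrics_frame(seed=4)
        well = df["well"].iloc[0]
        df.loc[(df["well"] == well) & (df["div"] == 14), "burst_duration_s"] = np.nan
        ratios, _ = cumulative_ratios(df)
        sub = ratios[(ratios["well"] == well) & (ratios["parameter"] == "burst_duration_s")]
        assert sub[sub["div"] < 14]["ratio_pct"].notna().all()
        assert sub[sub["div"] >= 14]["ratio_pct"].isna().all()


class TestExcludeOutliers:
    def test_zero_variance_group_flags_nothing(self):
        df = pd.DataFrame({"g": ["a"] * 4, "v": [10.0] * 4})
        out, frac = exclude_outliers(df, ["g"], "v")
        assert not out["outlier"].any() and frac == 0.0

    def test_single_extreme_value_is_flagged(self):
        vals = [10.0, 10.5, 9.5, 10.2, 9.8, 30.0]
        df = pd.DataFrame({"g": ["a"] * len(vals), "v": vals})
        out, frac = exclude_outliers(df, ["g"], "v")
        assert out["outlier"].tolist() == [False] * 5 + [True]

    def test_small_groups_left_untouched(self):
        df = pd.DataFrame({"g": ["a", "a"], "v": [0.0, 100.0]})
        out, _ = exclude_outliers(df, ["g"], "v")
        assert not out["outlier"].any()

    def test_normal_groups_exclusion_rate_near_four_percent(self):
        rng = np.random.default_rng(5)
        sizes = rng.integers(12, 33, size=2000)
        df = pd.DataFrame({
            "g": np.repeat(np.arange(sizes.size), sizes),
            "v": rng.standard_normal(sizes.sum()),
        })
        _, frac = exclude_outliers(df, ["g"], "v")
        assert 0.03 < frac < 0.045


class TestBMR:
    def test_zero_variance_controls_collapse_the_band(self):
        df = metrics_frame(seed=6)
        # make all control wells identical
        for p in PARAMETERS:
            df.loc[df["compound"] == "DMSO", p] = 10.0
        ratios, _ = cumulative_ratios(df)
        band = bmr_band(ratios)
        assert np.allclose(band["half_width"], 0.0)
        assert np.allclose(band["lower_pct"], band["control_mean"])

    def test_half_width_is_control_sd(self):
        ratios, _ = cumulative_ratios(metrics_frame(seed=7))
        band = bmr_band(ratios)
        ctrl = ratios[(ratios["compound"] == "DMSO") & ~ratios["outlier"]]
        one = band.iloc[10]
        sd = ctrl[
            (ctrl["parameter"] == one["parameter"]) & (ctrl["sex"] == one["sex"])
            & (ctrl["div"] == one["div"])
        ]["ratio_pct"].std(ddof=1)
        assert one["half_width"] == pytest.approx(sd)


class TestAnova:
    def test_equal_means_give_small_F(self, rng):
        groups = {i: 5.0 + 0.0 * rng.standard_normal(10) + rng.standard_normal(10)
                  for i in range(3)}
        # force identical means
        groups = {i: g - g.mean() + 5.0 for i, g in groups.items()}
        res = anova_oneway(groups)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p > 0.99

    def test_two_groups_F_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        res = anova_oneway({"a": a, "b": b})
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_three_group_example_matches_hand_computation(self):
        groups = {
            "g1": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            "g2": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            "g3": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        }
        # explicit sums of squares, computed independently
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        F_hand = (ss_between / 2) / (ss_within / 15)
        res = anova_oneway(groups)
        assert res.F == pytest.approx(F_hand, abs=5e-4)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_tukey_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        arrays = [rng.normal(m, 1, n) for m, n in [(0, 8), (0.7, 13), (1.1, 10)]]
        res = anova_oneway({"a": arrays[0], "b": arrays[1], "c": arrays[2]})
        sm = pairwise_tukeyhsd(
            np.concatenate(arrays),
            np.concatenate([["a"] * 8, ["b"] * 13, ["c"] * 10]),
        )
        assert np.allclose(res.tukey["p_adj"].to_numpy(), sm.pvalues, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_twoway(pd.DataFrame({
                "concentration_um": [0.0] * 8,
                "sex": ["male", "female"] * 4,
                "ratio_pct": np.arange(8.0),
            }))

    def test_null_sex_effect_type_one_error_near_alpha(self):
        """With identical sex distributions the sex main-effect p-value is
        uniform: rejection rate ~ alpha."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            df = pd.DataFrame({
                "concentration_um": np.repeat([0.0, 10.0], 16),
                "sex": np.tile(np.repeat(["male", "female"], 8), 2),
                "ratio_pct": rng.normal(100, 10, 32),
            })
            res = anova_twoway(df)
            if res.table.loc["C(sex)", "PR(>F)"] <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert 0.02 <= rate <= 0.09  # ~3 SE band around 0.05

    def test_injected_sex_by_concentration_effect_detected(self):
        """A one-concentration sex contrast of ~2 SD is found with power > 0.8."""
        rng = np.random.default_rng(9)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            y = rng.normal(100, 10, 40)
            df = pd.DataFrame({
                "concentration_um": np.repeat([0.0, 10.0], 20),
                "sex": np.tile(np.repeat(["male", "female"], 10), 2),
                "ratio_pct": y,
            })
            df.loc[(df["concentration_um"] == 10.0) & (df["sex"] == "male"),
                   "ratio_pct"] += 20.0
            res = anova_twoway(df)
            sc = res.sex_contrasts
            p = sc.loc[sc["concentration_um"] == 10.0, "p_adj"].iloc[0]
            if p <= 0.05:
                hits += 1
        assert hits / n_sim > 0.8


class TestFlagsAndLOEC:
    def test_null_dataset_flag_rate_at_most_alpha(self):
        """Condition i.i.d. with control: flag rate stays at or below alpha.

        At the study's well counts the benchmark-response filter binds
        (a mean shift of one control SD is ~2.4 standard errors), so the
        expected rate is well below alpha; pooled over three datasets.
        """
        rates = []
        for seed in (10, 20, 30):
            ratios, _ = cumulative_ratios(metrics_frame(n_ctrl=12, n_cond=12, seed=seed))
            report = flag_and_summarize(ratios)
            rates.append(report.flags["significant"].mean())
        assert np.mean(rates) <= 0.05

    def test_strong_excitation_flagged_with_direction_and_loec(self):
        ratios, _ = cumulative_ratios(metrics_frame(cond_scale=2.0, seed=11))
        report = flag_and_summarize(ratios)
        sig = report.flags[report.flags["significant"]]
        assert len(sig) > 0
        assert set(sig["direction"]) == {"excitation"}
        assert (report.loec["loec_um"] == 10.0).all()
        assert set(report.loec["direction"]) == {"excitation"}

    def test_significant_but_inside_bmr_is_not_an_effect(self):
        flags = pd.DataFrame([{
            "parameter": "n_spikes", "compound": "X", "concentration_um": 10.0,
            "sex": "male", "div": 28, "p_vs_control": 0.01,
            "diff_from_control": 3.0, "bmr_half_width": 5.0,
        }])
        # the rule itself: p <= alpha but |diff| <= half-width -> no effect
        assert not (flags["p_vs_control"].iloc[0] <= 0.05
                    and abs(flags["diff_from_control"].iloc[0]) > flags["bmr_half_width"].iloc[0])

    def test_below_bmr_cells_do_not_count_toward_loec(self):
        # condition shifted by ~1.02x: reliably significant at large n but
        # within a widened BMR band
        df = metrics_frame(n_ctrl=16, n_cond=16, cond_scale=1.02, seed=12)
        ratios, _ = cumulative_ratios(df)
        band = bmr_band(ratios)
        band["half_width"] = 50.0  # everything is inside the band
        band["upper_pct"] = band["control_mean"] + 50.0
        band["lower_pct"] = band["control_mean"] - 50.0
        report = flag_and_summarize(ratios, band)
        assert not report.flags["significant"].any()
        assert set(report.loec["direction"]) == {"no effect"}
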