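"""Assumption checks, transform rule, mixed ANOVA, and two-sample branch."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copgait import trial_stats as ts
from copgait.errors import ValidationError


def two_by_two(rng, n_eg=10, n_cg=10, interaction=0.0, lognormal=False):
    rows, i = [], 0
    for g, n in (("EG", n_eg), ("CG", n_cg)):
        for _ in range(n):
            base = rng.normal(10, 2)
            for ci, c in enumerate(("pre", "post")):
                v = base + rng.normal(0, 1)
                if g == "EG" and ci == 1:
                    v += interaction
                if lognormal:
                    v = float(np.exp(v / 4.0))
                rows.append((f"s{i}", g, c, v))
            i += 1
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "value"])


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.049, "*"), (0.0099, "**"), (0.0009, "***"),
        (0.05, ""), (0.01, "*"), (0.001, "**"),
    ])
    def test_thresholds(self, p, stars):
        assert ts.significance_stars(p) == stars


class TestMixedAnova:
    def test_constant_data_all_f_zero(self):
        df = two_by_two(np.random.default_rng(0))
        df["value"] = 5.0
        res = ts.mixed_anova(df)
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_interaction_f_equals_squared_t_on_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            df = two_by_two(rng, interaction=rng.normal(0, 1))
            res = ts.mixed_anova(df)
            wide = df.pivot_table(index=["subject_id", "group"],
                                  columns="condition", values="value")
            wide = wide.reset_index()
            d = wide["post"] - wide["pre"]
            t, _ = stats.ttest_ind(d[wide.group == "EG"],
                                   d[wide.group == "CG"])
            assert res["interaction"].statistic == pytest.approx(t * t,
                                                                 rel=1e-9)

    def test_trial_main_f_equals_squared_one_sample_t_balanced(self):
        # balanced 2-level within design: the within main effect F equals
        # the squared one-sample t on the grand per-subject differences
        rng = np.random.default_rng(2)
        df = two_by_two(rng, interaction=0.4)
        res = ts.mixed_anova(df)
        wide = df.pivot_table(index=["subject_id", "group"],
                              columns="condition", values="value")
        wide = wide.reset_index()
        d = wide["post"] - wide["pre"]
        # one-sample t on the grand mean difference, with the group effect
        # residualized out of the error term
        d_centered = d - d.groupby(wide["group"]).transform("mean")
        s2 = float(d_centered @ d_centered) / (d.size - 2)
        f_expected = d.mean() ** 2 * d.size / s2
        assert res["trial_main"].statistic == pytest.approx(f_expected,
                                                            rel=1e-9)

    @pytest.mark.parametrize("n_cg", [10, 13])
    def test_matches_pingouin(self, n_cg):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = two_by_two(rng, n_cg=n_cg, interaction=0.5)
        res = ts.mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="condition",
                             subject="subject_id", between="group")
        pcol = [c for c in ref.columns if c.startswith("p")][0]
        for eff, src in [("group_main", "group"),
                         ("trial_main", "condition"),
                         ("interaction", "Interaction")]:
            row = ref[ref.Source == src].iloc[0]
            assert res[eff].statistic == pytest.approx(row["F"], rel=1e-6)
            assert res[eff].p == pytest.approx(row[pcol], rel=1e-6)
            assert res[eff].df == (row["DF1"], row["DF2"])

    def test_listwise_exclusion_of_incomplete_subjects(self):
        df = two_by_two(np.random.default_rng(4))
        df = df.drop(df[(df.subject_id == "s0")
                        & (df.condition == "post")].index)
        res = ts.mixed_anova(df)
        assert res["group_main"].df == (1, 17)


class TestAssumptions:
    def test_two_within_levels_always_spherical(self):
        df = two_by_two(np.random.default_rng(5))
        rep = ts.check_assumptions(df)
        assert rep.spherical and rep.spherical_p == 1.0

    def test_normal_data_apply_no_transform(self):
        rng = np.random.default_rng(6)
        df = two_by_two(rng, n_eg=15, n_cg=15)
        rep = ts.check_assumptions(df)
        out, rep2 = ts.apply_transform_rule(df, rep)
        assert rep2.transform_applied == "none"
        assert out is df  # untouched (idempotence)

    def test_lognormal_data_mostly_log_transformed(self):
        rng = np.random.default_rng(7)
        applied = 0
        for _ in range(20):
            df = two_by_two(rng, n_eg=20, n_cg=20, lognormal=True)
            rep = ts.check_assumptions(df)
            _, rep2 = ts.apply_transform_rule(df, rep)
            applied += rep2.transform_applied == "natural_log"
        assert applied >= 12

    def test_transform_skipped_for_nonpositive_values(self, caplog):
        rng = np.random.default_rng(8)
        df = two_by_two(rng, lognormal=True)
        df.loc[df.index[0], "value"] = -1.0
        rep = ts.check_assumptions(df)
        if rep.normal:  # ensure the rule would fire
            object.__setattr__(rep, "normal", False)
        with caplog.at_level("WARNING"):
            _, rep2 = ts.apply_transform_rule(df, rep)
        assert rep2.transform_applied == "none"

    def test_too_small_cells_rejected(self):
        df = two_by_two(np.random.default_rng(9), n_eg=2, n_cg=2)
        with pytest.raises(ValidationError):
            ts.check_assumptions(df)


class TestMannWhitney:
    def test_complete_separation_gives_zero(self):
        u, _ = ts.mann_whitney_u(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0

    def test_u1_plus_u2_identity(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 30, 2)
            x, y = rng.normal(0, 1, n1), rng.normal(0.3, 1, n2)
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            u1 = float(res.statistic)
            u = ts.mann_whitney_u(x, y)[0]
            assert u == min(u1, n1 * n2 - u1)
            assert u <= n1 * n2 / 2

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, 15).astype(float)  # heavy ties
            y = rng.integers(0, 6, 12).astype(float)
            u1 = sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                     for xi in x for yj in y)
            u = ts.mann_whitney_u(x, y)[0]
            assert u == pytest.approx(min(u1, x.size * y.size - u1))


class TestCompareTraining:
    def test_normal_homoscedastic_uses_t(self, rng):
        eg, cg = rng.normal(10, 1, 20), rng.normal(10.5, 1, 20)
        r = ts.compare_training(eg, cg)
        assert r.statistic_kind == "t"
        assert r.df == (38.0,)

    def test_non_normal_uses_u(self, rng):
        eg = np.exp(rng.normal(0, 1.5, 25))
        cg = np.exp(rng.normal(0.4, 1.5, 25))
        r = ts.compare_training(eg, cg)
        assert r.statistic_kind == "U"
        assert not r.assumptions.normal

    def test_normal_heteroscedastic_uses_welch(self):
        rng = np.random.default_rng(12)
        eg, cg = rng.normal(10, 0.5, 25), rng.normal(11, 4, 25)
        r = ts.compare_training(eg, cg)
        if r.statistic_kind == "t" and not r.assumptions.homoscedastic:
            assert r.df[0] != 48.0  # Welch-Satterthwaite, non-integer df

    def test_constant_data_rejected(self):
        with pytest.raises(ValidationError):
            ts.compare_training(np.ones(5), np.ones(5))


class TestBaselineTable:
    def _df(self, eg_vals, cg_vals, kind="continuous", var="v"):
        rows = []
        for i, v in enumerate(eg_vals):
            rows.append((f"e{i}", "EG", var, v, kind))
        for i, v in enumerate(cg_vals):
            rows.append((f"c{i}", "CG", var, v, kind))
        return pd.DataFrame(rows, columns=["subject_id", "group", "variable",
                                           "value", "kind"])

    def test_identical_proportions_chi2_zero(self):
        eg = ["yes"] * 15 + ["no"] * 5
        cg = ["yes"] * 15 + ["no"] * 5
        out = ts.baseline_table(self._df(eg, cg, kind="categorical"))
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_chi2_matches_hand_formula(self):
        # 2x2 counts {17,3; 18,2}: chi2 = sum (O-E)^2 / E
        eg = ["hs"] * 17 + ["no"] * 3
        cg = ["hs"] * 18 + ["no"] * 2
        obs = np.array([[17, 3], [18, 2]], dtype=float)
        row_tot = obs.sum(axis=1, keepdims=True)
        col_tot = obs.sum(axis=0, keepdims=True)
        exp = row_tot @ col_tot / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        out = ts.baseline_table(self._df(eg, cg, kind="categorical"))
        assert out.iloc[0]["statistic"] == pytest.approx(chi2_hand, rel=1e-12)

    def test_identical_continuous_samples_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = ts.baseline_table(self._df(vals, vals))
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_as_printed_paired_mode(self, rng):
        eg, cg = rng.normal(10, 1, 12), rng.normal(10, 1, 12)
        out = ts.baseline_table(self._df(eg, cg), as_printed=True)
        t_ref, p_ref = stats.ttest_rel(eg, cg)
        assert out.iloc[0]["statistic"] == pytest.approx(t_ref)
        assert out.iloc[0]["p"] == pytest.approx(p_ref)

    def test_continuous_means_reported(self, rng):
        eg, cg = rng.normal(48, 3, 20), rng.normal(48, 3, 20)
        out = ts.baseline_table(self._df(eg, cg))
        assert "±" in out.iloc[0]["EG"]


class TestProcedure:
    def test_injected_interaction_detected(self):
        from copgait import synthetic_gait as sg
        eff = [sg.EffectSpec("ss_cop_efficiency", "interaction", 2.0)]
        df = sg.simulate_summary_pair(20, "ss_cop_efficiency", effects=eff,
                                      rng=np.random.default_rng(30))
        results, _ = ts.run_mixed_procedure(df)
        assert results["interaction"].p < 0.05

    def test_analyze_gait_protocol_shapes(self):
        from copgait import synthetic_gait as sg
        rng = np.random.default_rng(31)
        frames = []
        for trial in ("GaitBaseline", "GaitPost", "TestPre", "TestPost",
                      "Training"):
            df = sg.simulate_summary_pair(6, "stride_length",
                                          conditions=(trial, "_x"), rng=rng)
            df = df[df.condition == trial]
            frames.append(pd.DataFrame({
                "subject_id": df.subject_id, "group": df.group,
                "trial": trial, "metric": "stride_length",
                "mean": df.value, "sd": np.abs(df.value) / 20.0,
                "n_units": 50,
            }))
        summaries = pd.concat(frames, ignore_index=True)
        res = ts.analyze_gait_protocol(summaries)
        assert set(res["analysis"]) == {"Gait", "Test", "Training"}
        gait = res[(res.analysis == "Gait") & (res.statistic_of == "mean")]
        assert set(gait["effect"]) == {"trial_main", "group_main",
                                       "interaction"}
        assert (res[res.analysis == "Training"]["statistic_kind"]
                .isin(["t", "U"])).all()
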