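import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from dediff import stats as st


def _test_events(n_intact=96, n_recombined=96, hits=96, crs=96,
                 nr_intact=0, nr_recombined=0):
    rows = []
    for i in range(n_intact):
        if i < nr_intact:
            resp = "none"
        else:
            resp = "old" if i - nr_intact < hits else "new"
        rows.append({"status": "intact", "response": resp})
    for i in range(n_recombined):
        if i < nr_recombined:
            resp = "none"
        else:
            resp = "new" if i - nr_recombined < crs else "old"
        rows.append({"status": "recombined", "response": resp})
    return pd.DataFrame(rows)


class TestScoreBehavior:
    def test_all_correct(self):
        s = st.score_behavior(_test_events())
        assert s.counts["hit"] == 96 and s.counts["CR"] == 96
        assert s.corrected_recognition == 1.0

    def test_counts_partition(self):
        s = st.score_behavior(_test_events(hits=85, crs=90))
        assert s.counts == {"hit": 85, "miss": 11, "CR": 90, "FA": 6,
                            "no-response": 0}
        assert s.corrected_recognition == pytest.approx(85 / 96 - 6 / 96)

    def test_random_guessing_corrected_near_zero(self, rng):
        # E[p_hit - p_fa] = 0 when responses are coin flips
        vals = []
        for _ in range(200):
            hits = rng.binomial(96, 0.5)
            fas = rng.binomial(96, 0.5)
            s = st.score_behavior(_test_events(hits=hits, crs=96 - fas))
            vals.append(s.corrected_recognition)
        assert abs(np.mean(vals)) < 0.02

    def test_no_response_denominators(self):
        ev = _test_events(hits=90, crs=90, nr_intact=6, nr_recombined=6)
        presented = st.score_behavior(ev, denominator="presented")
        responded = st.score_behavior(ev, denominator="responded")
        assert presented.p_hit == pytest.approx(90 / 96)
        assert responded.p_hit == pytest.approx(90 / 90)
        assert presented.counts["no-response"] == 12

    def test_unknown_response_raises(self):
        ev = pd.DataFrame({"status": ["intact"], "response": ["maybe"]})
        with pytest.raises(ValueError):
            st.score_behavior(ev)

    def test_unknown_denominator_raises(self):
        with pytest.raises(ValueError):
            st.score_behavior(_test_events(), denominator="bogus")


class TestIndependentT:
    def test_equal_means_zero(self):
        assert st.independent_t(1.0, 1.0, 10, 1.0, 2.0, 10).t == 0.0

    def test_table_values_pooled(self):
        # reference group summaries reproduce t(38) = 4.67 within rounding
        res = st.independent_t(85.05, 7.3, 20, 71.90, 10.3, 20)
        assert res.df == 38
        assert res.t == pytest.approx(4.67, abs=0.02)

    def test_p_matches_numeric_cdf(self):
        res = st.independent_t(3.0, 1.0, 8, 2.0, 1.5, 9)
        # independent oracle: integrate the t density directly
        pdf = sps.t(res.df).pdf
        p_num = 2 * quad(pdf, abs(res.t), np.inf)[0]
        assert res.p == pytest.approx(p_num, rel=1e-6)

    def test_matches_scipy_from_data(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1.2, 12)
        mine = st.independent_t_from_data(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_welch_df(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 3, 25)
        mine = st.independent_t_from_data(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            st.independent_t(1, 0, 10, 2, 0, 10)
        with pytest.raises(ValueError):
            st.independent_t(1, 1, 1, 2, 1, 10)


class TestPairedT:
    def test_identical_zero(self):
        res = st.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_sign_flip_antisymmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.3, 1, 10)
        assert st.paired_t(a, b).t == pytest.approx(-st.paired_t(b, a).t)

    def test_matches_scipy(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.4, 1, 14)
        mine = st.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)
        assert mine.df == 13

    def test_hand_computation(self):
        # d = (2, 2, 5): mean 3, sd sqrt(3), t = 3 / (sqrt(3)/sqrt(3)) = 3
        res = st.paired_t([3.0, 4.0, 8.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(3.0)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 4, 0.0125),
        (0.05, 1, 0.05),
        (0.10, 5, 0.02),
    ])
    def test_threshold(self, alpha, m, expected):
        assert st.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_three_targets_rounds_to_reference_value(self):
        assert round(st.bonferroni_threshold(0.05, 3), 4) == 0.0167

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            st.bonferroni_threshold(0.05, 0)


def _tidy(y_by_group_level, subjects_per_group):
    rows = []
    sid = 0
    for g, levels in y_by_group_level.items():
        for s in range(subjects_per_group):
            for lv, vals in levels.items():
                rows.append({"subject": f"s{sid + s}", "group": g,
                             "level": lv, "value": vals[s]})
        sid += subjects_per_group
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_equal_values_give_zero_f(self):
        df = _tidy({"a": {"x": [1, 1], "y": [1, 1]},
                    "b": {"x": [1, 1], "y": [1, 1]}}, 2)
        an = st.mixed_anova(df)
        assert (an["F"].dropna() == 0).all()

    def test_2x2_toy_against_hand_sums_of_squares(self):
        # two subjects per group; hand-computed classical partition
        df = _tidy({"a": {"x": [1.0, 2.0], "y": [3.0, 4.0]},
                    "b": {"x": [2.0, 4.0], "y": [2.0, 6.0]}}, 2)
        an = st.mixed_anova(df).set_index("effect")
        y = np.array([[1, 3], [2, 4], [2, 2], [4, 6]], float)
        grand = y.mean()
        subj = y.mean(1)
        ss_bs = 2 * ((subj - grand) ** 2).sum()
        gmeans = np.array([subj[:2].mean(), subj[2:].mean()])
        ss_g = 2 * 2 * ((gmeans - grand) ** 2).sum()
        lmeans = y.mean(0)
        ss_l = 4 * ((lmeans - grand) ** 2).sum()
        cells = np.array([y[:2].mean(0), y[2:].mean(0)])
        ss_i = 2 * ((cells - gmeans[:, None] - lmeans[None, :] + grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        assert an.loc["group", "ss"] == pytest.approx(ss_g)
        assert an.loc["level", "ss"] == pytest.approx(ss_l)
        assert an.loc["group * level", "ss"] == pytest.approx(ss_i)
        assert an.loc["subjects(group)", "ss"] == pytest.approx(ss_bs - ss_g)
        assert an.loc["error(level)", "ss"] == pytest.approx(
            ss_tot - ss_bs - ss_l - ss_i
        )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for g in ("young", "old"):
            for s in range(9):
                for lv in ("SE", "SS", "SC", "DC"):
                    rows.append({"subject": f"{g}{s}", "group": g, "level": lv,
                                 "value": rng.normal()})
        df = pd.DataFrame(rows)
        mine = st.mixed_anova(df).set_index("effect")
        theirs = pg.mixed_anova(df, dv="value", within="level",
                                subject="subject", between="group").set_index("Source")
        for mine_key, pg_key in [("group", "group"), ("level", "level"),
                                 ("group * level", "Interaction")]:
            assert mine.loc[mine_key, "F"] == pytest.approx(theirs.loc[pg_key, "F"])
            assert mine.loc[mine_key, "p"] == pytest.approx(theirs.loc[pg_key, "p_unc"])

    def test_dfs(self):
        df = _tidy({"a": {"w": [1, 2, 3], "x": [0, 1, 2], "y": [1, 1, 1],
                          "z": [2, 0, 1]},
                    "b": {"w": [1, 0, 3], "x": [2, 1, 2], "y": [0, 1, 1],
                          "z": [2, 2, 1]}}, 3)
        an = st.mixed_anova(df).set_index("effect")
        assert an.loc["group", "df"] == 1
        assert an.loc["level", "df"] == 3
        assert an.loc["group * level", "df"] == 3
        assert an.loc["error(level)", "df"] == (6 - 2) * 3

    def test_within_f_equals_paired_t_squared_single_group(self, rng):
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0.4, 1, 12)
        df = pd.DataFrame({
            "subject": [f"s{i}" for i in range(12)] * 2,
            "group": "only",
            "level": ["A"] * 12 + ["B"] * 12,
            "value": np.concatenate([a, b]),
        })
        an = st.mixed_anova(df).set_index("effect")
        t = st.paired_t(a, b)
        assert an.loc["level", "F"] == pytest.approx(t.t**2)
        assert an.loc["level", "p"] == pytest.approx(t.p)

    def test_missing_cell_raises(self):
        df = _tidy({"a": {"x": [1, 2], "y": [3, 4]},
                    "b": {"x": [2, 4], "y": [2, 6]}}, 2)
        with pytest.raises(ValueError):
            st.mixed_anova(df.iloc[:-1])

    def test_null_interaction_f_near_expectation(self, rng):
        # pure group shift, no interaction: mean F ~ dfe / (dfe - 2)
        fs = []
        for _ in range(500):
            y = rng.normal(0, 1, (12, 2))
            y[6:] += 1.0  # group main effect only
            rows = []
            for s in range(12):
                for j, lv in enumerate("xy"):
                    rows.append({"subject": f"s{s}",
                                 "group": "a" if s < 6 else "b",
                                 "level": lv, "value": y[s, j]})
            an = st.mixed_anova(pd.DataFrame(rows)).set_index("effect")
            fs.append(an.loc["group * level", "F"])
        dfe = 10.0
        expected = dfe / (dfe - 2)
        assert np.mean(fs) == pytest.approx(expected, rel=0.15)


class TestTypeOneCalibration:
    """Null simulations reject at ~nominal rate (reduced data sizes)."""

    N_REPS = 1500

    def test_independent_t_calibration(self, rng):
        rej = 0
        for _ in range(self.N_REPS):
            res = st.independent_t_from_data(rng.normal(size=8), rng.normal(size=8))
            rej += res.p < 0.05
        rate = rej / self.N_REPS
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / self.N_REPS) + 0.005

    def test_paired_t_calibration(self, rng):
        rej = 0
        for _ in range(self.N_REPS):
            res = st.paired_t(rng.normal(size=10), rng.normal(size=10))
            rej += res.p < 0.05
        rate = rej / self.N_REPS
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / self.N_REPS) + 0.005

    def test_mixed_anova_calibration(self, rng):
        # vectorized classical partition under the null, 2 groups x 2 levels
        n_per, reps = 8, 1500
        rej_int = 0
        for _ in range(reps):
            y = rng.normal(size=(2 * n_per, 2))
            d = y[:, 0] - y[:, 1]
            ss_i = n_per * ((d[:n_per].mean() - d.mean()) ** 2
                            + (d[n_per:].mean() - d.mean()) ** 2) / 2
            ss_e = (((d[:n_per] - d[:n_per].mean()) ** 2).sum()
                    + ((d[n_per:] - d[n_per:].mean()) ** 2).sum()) / 2
            f = ss_i / (ss_e / (2 * n_per - 2))
            rej_int += sps.f.sf(f, 1, 2 * n_per - 2) < 0.05
        rate = rej_int / reps
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / reps) + 0.005

    def test_mixed_anova_matches_vectorized_null(self, rng):
        # spot-check the fast formula above against the full implementation
        y = rng.normal(size=(6, 2))
        rows = [
            {"subject": f"s{s}", "group": "a" if s < 3 else "b",
             "level": lv, "value": y[s, j]}
            for s in range(6) for j, lv in enumerate("xy")
        ]
        an = st.mixed_anova(pd.DataFrame(rows)).set_index("effect")
        d = y[:, 0] - y[:, 1]
        ss_i = 3 * ((d[:3].mean() - d.mean()) ** 2 + (d[3:].mean() - d.mean()) ** 2) / 2
        ss_e = (((d[:3] - d[:3].mean()) ** 2).sum()
                + ((d[3:] - d[3:].mean()) ** 2).sum()) / 2
        f = ss_i / (ss_e / 4)
        assert an.loc["group * level", "F"] == pytest.approx(f)
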