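"""Behavioral statistics: outlier filter, error geometry, ANOVA oracle, pairwise."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symwm import behavior_stats as bs
from symwm import synth_behavior as sb
from symwm.schedule import compute_layout
from symwm.synth_behavior import ResponseRecord


def _rec(chosen, target_ignored=None, subject="s1", trial=0, rt=500.0, correct=False):
    return ResponseRecord(subject_id=subject, block=1, trial_index=trial,
                          chosen_anchor=chosen, rt_ms=rt, correct=correct)


class TestRtFilter:
    def _table(self, rts, subject="s1"):
        return pd.DataFrame({"subject_id": subject, "rt_ms": rts,
                             "correct": True, "responded": True})

    def test_identical_rts_none_removed(self):
        kept, log = bs.filter_rt_outliers(self._table([500.0] * 20))
        assert len(kept) == 20 and log.empty

    def test_single_extreme_rt_removed(self):
        # 49 trials at 500 ms and one at 5000 ms: bound ~ 590 + 2*636 < 5000
        kept, log = bs.filter_rt_outliers(self._table([500.0] * 49 + [5000.0]))
        assert len(kept) == 49
        assert log["rt_ms"].tolist() == [5000.0]

    def test_few_trials_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            kept, _ = bs.filter_rt_outliers(self._table([100.0, 9000.0]))
        assert len(kept) == 2

    def test_idempotent_under_original_bounds(self):
        tab = self._table(list(np.linspace(400, 700, 30)) + [4000.0])
        kept, _ = bs.filter_rt_outliers(tab)
        m, s = tab["rt_ms"].mean(), tab["rt_ms"].std(ddof=1)
        again = kept[(kept["rt_ms"] >= m - 2 * s) & (kept["rt_ms"] <= m + 2 * s)]
        assert len(again) == len(kept)


class TestErrorGeometry:
    def test_distance_zero_when_correct(self, layout, default_schedule):
        t = default_schedule.trials[0]
        assert bs.error_distance(_rec(t.target_anchor), t, layout) == 0.0

    def test_distance_opposite_is_diameter(self, layout, default_schedule):
        t = default_schedule.trials[0]
        r = _rec((t.target_anchor + 6) % 12)
        assert bs.error_distance(r, t, layout) == pytest.approx(400.0, abs=1e-9)

    def test_distance_adjacent_is_chord(self, layout, default_schedule):
        t = default_schedule.trials[0]
        r = _rec((t.target_anchor + 1) % 12)
        expected = 2 * 200 * np.sin(np.deg2rad(15))
        assert bs.error_distance(r, t, layout) == pytest.approx(expected, abs=1e-9)

    def test_angle_zero_same_and_180_opposite(self, layout, default_schedule):
        t = default_schedule.trials[0]
        assert bs.error_angle(_rec(t.target_anchor), t, layout) == pytest.approx(0.0, abs=1e-5)
        assert bs.error_angle(_rec((t.target_anchor + 6) % 12), t, layout) == \
            pytest.approx(180.0, abs=1e-5)

    def test_angle_adjacent_is_30_degrees(self, layout, default_schedule):
        t = default_schedule.trials[0]
        r = _rec((t.target_anchor + 1) % 12)
        assert bs.error_angle(r, t, layout) == pytest.approx(30.0, abs=1e-5)

    def test_angles_are_multiples_of_30(self, layout, default_schedule):
        t = default_schedule.trials[0]
        for k in range(12):
            a = bs.error_angle(_rec(k), t, layout)
            assert a == pytest.approx(round(a / 30) * 30, abs=1e-5)
            assert 0 <= a <= 180

    def test_out_of_range_anchor_rejected(self, layout, default_schedule):
        t = default_schedule.trials[0]
        with pytest.raises(ValueError):
            bs.error_distance(_rec(12), t, layout)


class TestFalsePositiveRate:
    def test_all_correct_gives_undefined(self, default_schedule):
        recs = [ResponseRecord("s1", t.block, t.trial_index, t.target_anchor,
                               500.0, True) for t in default_schedule.trials]
        out = bs.false_positive_rate(recs, default_schedule)
        assert out.empty or not out["defined"].any()

    def test_every_error_on_distractor_gives_one(self, default_schedule):
        recs = []
        for t in default_schedule.trials:
            d_anchor = next(a for sid, a in t.item_locations.items() if sid != t.probe_id)
            recs.append(ResponseRecord("s1", t.block, t.trial_index, d_anchor,
                                       500.0, False))
        out = bs.false_positive_rate(recs, default_schedule)
        assert out["rate"].iloc[0] == 1.0

    def test_uniform_errors_load4_rate_3_over_11(self, default_schedule):
        """Errors visiting each non-target anchor once: expected rate 3/11
        on high-load trials (3 distractor anchors of 11 candidates)."""
        recs = []
        for t in default_schedule.trials:
            if t.load != 4:
                continue
            others = [a for a in range(12) if a != t.target_anchor]
            for j, a in enumerate(others):
                recs.append(ResponseRecord("s1", t.block, t.trial_index, a,
                                           500.0, False))
        out = bs.false_positive_rate(recs, default_schedule)
        assert out["rate"].iloc[0] == pytest.approx(3 / 11, abs=1e-12)


def brute_force_rm_anova(Y):
    """Definitional sums-of-squares oracle for a (n, a, b) within design."""
    n, a, b = Y.shape
    grand = Y.mean()
    mS = Y.mean(axis=(1, 2))
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    mAB = Y.mean(axis=0)
    ss = {}
    ss["S"] = a * b * ((mS - grand) ** 2).sum()
    ss["A"] = n * b * ((mA - grand) ** 2).sum()
    ss["B"] = n * a * ((mB - grand) ** 2).sum()
    ss["AB"] = n * ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    ss["SA"] = b * ((mSA - mS[:, None] - mA[None, :] + grand) ** 2).sum()
    ss["SB"] = a * ((mSB - mS[:, None] - mB[None, :] + grand) ** 2).sum()
    ss["SAB"] = ((Y - mSA[:, :, None] - mSB[:, None, :] - mAB[None, :, :]
                  + mS[:, None, None] + mA[None, :, None] + mB[None, None, :]
                  - grand) ** 2).sum()
    out = {}
    for eff, err, dfe in (("A", "SA", a - 1), ("B", "SB", b - 1),
                          ("AB", "SAB", (a - 1) * (b - 1))):
        dferr = (n - 1) * dfe
        F = (ss[eff] / dfe) / (ss[err] / dferr)
        ges = ss[eff] / (ss[eff] + ss["S"] + ss["SA"] + ss["SB"] + ss["SAB"])
        out[eff] = (F, dfe, dferr, ges)
    return out


class TestRmAnova:
    def _table(self, Y):
        n, a, b = Y.shape
        rows = []
        for s in range(n):
            for i, sym in enumerate(["asym", "sym"][:a]):
                for j, load in enumerate(["high", "low"][:b]):
                    rows.append({"subject": f"s{s}", "symmetry": sym,
                                 "load": load, "y": Y[s, i, j]})
        return pd.DataFrame(rows)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            Y = rng.normal(size=(7, 2, 2))
            res = bs.rm_anova(self._table(Y), "y", ["symmetry", "load"]) \
                .set_index("effect")
            # cell array sorts levels alphabetically: asym<sym, high<low
            oracle = brute_force_rm_anova(Y)
            for eff, key in (("symmetry", "A"), ("load", "B"),
                             ("symmetry:load", "AB")):
                F, dfe, dferr, ges = oracle[key]
                assert res.loc[eff, "F"] == pytest.approx(F, rel=1e-10)
                assert res.loc[eff, "df_num"] == dfe
                assert res.loc[eff, "df_den"] == dferr
                assert res.loc[eff, "ges"] == pytest.approx(ges, rel=1e-10)

    def test_two_level_factor_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        res = bs.rm_anova(self._table(rng.normal(size=(6, 2, 2))),
                          "y", ["symmetry", "load"])
        assert (res["gg_epsilon"] == 1.0).all()

    def test_null_effect_gives_f_zero(self):
        Y = np.tile(np.arange(5)[:, None, None], (1, 2, 2)).astype(float)
        res = bs.rm_anova(self._table(Y), "y", ["symmetry", "load"])
        assert np.allclose(res["F"], 0.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        tab = self._table(rng.normal(size=(9, 2, 2)) + rng.normal(size=(9, 1, 1)))
        ours = bs.rm_anova(tab, "y", ["symmetry", "load"]).set_index("effect")
        theirs = pg.rm_anova(data=tab, dv="y", within=["symmetry", "load"],
                             subject="subject", effsize="ng2").set_index("Source")
        for eff, src in (("symmetry", "symmetry"), ("load", "load"),
                         ("symmetry:load", "symmetry * load")):
            assert ours.loc[eff, "F"] == pytest.approx(theirs.loc[src, "F"], rel=1e-8)
            assert ours.loc[eff, "ges"] == pytest.approx(theirs.loc[src, "ng2"], rel=1e-8)

    def test_one_factor_gg_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        rows = []
        for s in range(10):
            base = rng.normal(0, 2)
            for j, lev in enumerate("abcd"):
                rows.append({"subject": f"s{s}", "f": lev,
                             "y": base + j + rng.normal(0, 1 + 0.5 * j)})
        tab = pd.DataFrame(rows)
        ours = bs.rm_anova(tab, "y", ["f"])
        theirs = pg.rm_anova(data=tab, dv="y", within="f", subject="subject",
                             correction=True)
        assert ours["gg_epsilon"].iloc[0] == pytest.approx(
            theirs["eps"].iloc[0], rel=1e-6)
        assert ours["p_gg"].iloc[0] == pytest.approx(
            theirs["p_GG_corr"].iloc[0], rel=1e-6)

    def test_missing_cell_names_subject(self):
        tab = self._table(np.zeros((4, 2, 2)))
        tab = tab[~((tab.subject == "s2") & (tab.symmetry == "sym")
                    & (tab.load == "low"))]
        with pytest.raises(ValueError, match="s2"):
            bs.rm_anova(tab, "y", ["symmetry", "load"])


class TestPairwise:
    def _table(self, Y):
        n = Y.shape[0]
        rows = []
        for s in range(n):
            for i, sym in enumerate(["asym", "sym"]):
                for j, load in enumerate(["high", "low"]):
                    rows.append({"subject": f"s{s}", "symmetry": sym,
                                 "load": load, "y": Y[s, i, j]})
        return pd.DataFrame(rows)

    def test_identical_cells_null_contrast(self):
        Y = np.tile(np.arange(4)[:, None, None], (1, 2, 2)).astype(float)
        res = bs.pairwise_comparisons(self._table(Y), "y", ["symmetry", "load"])
        assert np.allclose(res["m_difference"], 0)
        assert (res["p_adjusted"] == 1.0).all()

    def test_bonferroni_multiplies_p(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 2, 2))
        res = bs.pairwise_comparisons(self._table(Y), "y", ["symmetry", "load"])
        m = len(res)
        for _, r in res.iterrows():
            assert r["p_adjusted"] == pytest.approx(min(1.0, r["p"] * m))
            assert r["p_adjusted"] >= r["p"]

    def test_pooled_error_df(self):
        Y = np.random.default_rng(2).normal(size=(37, 2, 2))
        res = bs.pairwise_comparisons(self._table(Y), "y", ["symmetry", "load"])
        assert (res["df"] == 36 * 3).all()

    def test_toy_matches_hand_pooled_contrast(self):
        """4-subject 2x2 table: t from the pooled condition-by-subject
        error term, computed by hand."""
        Y = np.array([[[1.0, 2.0], [3.0, 2.5]],
                      [[1.5, 2.2], [3.4, 2.1]],
                      [[0.8, 1.9], [2.9, 2.8]],
                      [[1.2, 2.4], [3.1, 2.2]]])
        tab = self._table(Y)
        res = bs.pairwise_comparisons(tab, "y", ["symmetry", "load"])
        Y2 = Y.reshape(4, 4)
        resid = Y2 - Y2.mean(1, keepdims=True) - Y2.mean(0, keepdims=True) + Y2.mean()
        ms = (resid ** 2).sum() / (3 * 3)
        means = Y2.mean(0)
        diff = means[0] - means[1]
        t_hand = diff / np.sqrt(2 * ms / 4)
        first = res.iloc[0]
        assert first["t"] == pytest.approx(t_hand, rel=1e-12)


class TestCovariatesAndCorrelation:
    def test_equal_accuracy_gives_zero(self):
        rows = [{"subject": "s1", "symmetry": sym, "load": load, "correct": c}
                for sym in ("sym", "asym") for load in ("low", "high")
                for c in (True, False)]
        out = bs.accuracy_covariates(pd.DataFrame(rows))
        assert out["acc_sym_minus_asym"].iloc[0] == 0.0

    def test_known_difference(self):
        rows = []
        for sym, p in (("sym", 0.6), ("asym", 0.49)):
            for load in ("low", "high"):
                rows += [{"subject": "s1", "symmetry": sym, "load": load,
                          "correct": i < p * 100} for i in range(100)]
        out = bs.accuracy_covariates(pd.DataFrame(rows))
        assert out["acc_sym_minus_asym"].iloc[0] == pytest.approx(11.0)

    def test_missing_level_raises(self):
        rows = [{"subject": "s1", "symmetry": "sym", "load": l, "correct": True}
                for l in ("low", "high")]
        with pytest.raises(ValueError, match="asym"):
            bs.accuracy_covariates(pd.DataFrame(rows))

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        out = bs.pearson_with_ci(x, 2 * x + 1)
        assert out["r"] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        out = bs.pearson_with_ci(np.array([1, 2, 3.0]), np.array([2, 4, 5.0]))
        assert out["r"] == pytest.approx(0.981980506, abs=1e-6)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        out = bs.pearson_with_ci(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(out["r"]) < 0.1

    def test_constant_variable_flagged(self):
        out = bs.pearson_with_ci(np.ones(10), np.arange(10.0))
        assert not out["defined"]
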