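"""Group inference: mixed models, ICC/R², BH-FDR, channel contrasts, post-hocs."""

import numpy as np
import pandas as pd
import pytest

from symwm import group


def _cell_table(effects, subjects=None):
    """Long probe x load table from an (n, 4) array ordered
    (asym/low, asym/high, sym/low, sym/high)."""
    cells = [("asym", "low"), ("asym", "high"), ("sym", "low"), ("sym", "high")]
    rows = []
    for s, row in enumerate(np.atleast_2d(effects)):
        sid = f"s{s}" if subjects is None else subjects[s]
        for (p, l), v in zip(cells, row):
            rows.append({"subject": sid, "probe": p, "load": l, "effect": v})
    return pd.DataFrame(rows)


class TestLme:
    def test_balanced_one_way_matches_closed_form(self):
        """REML variance components on balanced data equal the ANOVA
        method-of-moments estimators."""
        rng = np.random.default_rng(0)
        n_subj, n_rep = 12, 4
        b = rng.normal(0, 1.5, n_subj)
        rows = []
        for i in range(n_subj):
            for _ in range(n_rep):
                rows.append({"subject": f"s{i}", "probe": "asym", "load": "low",
                             "effect": 2.0 + b[i] + rng.normal(0, 1.0)})
        tab = pd.DataFrame(rows)
        fit = group.fit_random_intercept_lme(tab, interaction=False)
        # closed form from the one-way decomposition
        y = tab["effect"].to_numpy().reshape(n_subj, n_rep)
        ms_within = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (n_subj * (n_rep - 1))
        ms_between = n_rep * ((y.mean(1) - y.mean()) ** 2).sum() / (n_subj - 1)
        s2b = (ms_between - ms_within) / n_rep
        assert fit.sigma2_resid == pytest.approx(ms_within, abs=1e-5)
        assert fit.sigma2_subject == pytest.approx(s2b, abs=1e-5)

    def test_zero_between_subject_variance_boundary(self):
        rng = np.random.default_rng(1)
        tab = _cell_table(rng.normal(0, 1, (15, 4)))
        fit = group.fit_random_intercept_lme(tab)
        assert fit.icc < 0.15

    def test_icc_recovered_near_half(self):
        """sigma2_subject = sigma2_resid = 1 gives ICC near 0.5 on average."""
        rng = np.random.default_rng(2)
        iccs = []
        for _ in range(40):
            b = rng.normal(0, 1.0, 26)
            eff = b[:, None] + rng.normal(0, 1.0, (26, 4))
            fit = group.fit_random_intercept_lme(_cell_table(eff))
            iccs.append(fit.icc)
        assert np.mean(iccs) == pytest.approx(0.5, abs=0.05)

    def test_single_observation_per_subject_rejected(self):
        tab = _cell_table(np.zeros((3, 4))).groupby("subject").head(1)
        with pytest.raises(ValueError):
            group.fit_random_intercept_lme(tab)

    def test_interaction_term_recovered(self):
        rng = np.random.default_rng(3)
        base = np.array([1.0, 1.0, 1.0, 3.0])  # interaction on sym/high
        eff = base + rng.normal(0, 0.2, (20, 4)) + rng.normal(0, 0.5, (20, 1))
        fit = group.fit_random_intercept_lme(_cell_table(eff))
        fe = fit.fixed_effects.set_index("term")
        assert fe.loc["probe[sym]:load[high]", "beta"] == pytest.approx(2.0, abs=0.3)
        assert fe.loc["probe[sym]:load[high]", "p"] < 0.001


class TestIccR2:
    def _fit(self, var_fixed, s2b, s2e):
        return group.LmeFit(fixed_effects=pd.DataFrame(), sigma2_subject=s2b,
                            sigma2_resid=s2e, icc=s2b / (s2b + s2e),
                            r2_marginal=var_fixed / (var_fixed + s2b + s2e),
                            r2_conditional=(var_fixed + s2b) / (var_fixed + s2b + s2e),
                            converged=True, boundary=False, n_obs=0, n_subjects=0)

    def test_plug_in_arithmetic(self):
        # fixed-prediction variance 1, subject variance 1, residual 2
        icc, r2m, r2c = group.icc_and_r2(self._fit(1.0, 1.0, 2.0))
        assert r2m == pytest.approx(0.25)
        assert r2c == pytest.approx(0.5)
        assert icc == pytest.approx(1.0 / 3.0)

    def test_null_fixed_effects_zero_marginal(self):
        icc, r2m, r2c = group.icc_and_r2(self._fit(0.0, 1.0, 1.0))
        assert r2m == 0.0

    def test_no_subject_variance_equal_r2(self):
        icc, r2m, r2c = group.icc_and_r2(self._fit(1.0, 0.0, 1.0))
        assert r2m == r2c


class TestBhFdr:
    def test_hand_step_up(self):
        q, rej = group.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)
        assert rej.all()

    def test_all_ones(self):
        q, rej = group.bh_fdr(np.ones(5))
        assert np.allclose(q, 1.0) and not rej.any()

    def test_single_p_unchanged(self):
        q, _ = group.bh_fdr(np.array([0.037]))
        assert q[0] == pytest.approx(0.037)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q, _ = group.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            group.bh_fdr(np.array([0.5, 1.2]))


class TestChannelContrast:
    def _effects(self, data):
        rows = []
        for ch, vals in data.items():
            for s, v in enumerate(vals):
                rows.append({"subject": f"s{s}", "channel_id": ch,
                             "chroma": "hbo", "effect": v})
        return pd.DataFrame(rows)

    def test_z_sign_matches_mean(self):
        out = group.group_channel_contrast(self._effects({
            "up": [1.0, 1.2, 0.9, 1.1], "down": [-1.0, -0.8, -1.1, -0.9]}))
        out = out.set_index("channel_id")
        assert out.loc["up", "z"] > 0 > out.loc["down", "z"]

    def test_insufficient_subjects_flagged(self):
        out = group.group_channel_contrast(self._effects({"tiny": [1.0, 2.0]}))
        assert not out["testable"].iloc[0]

    def test_strong_effect_survives_fdr(self):
        rng = np.random.default_rng(5)
        data = {f"null{i}": rng.normal(0, 1, 20) for i in range(30)}
        data["signal"] = rng.normal(5, 1, 20)
        out = group.group_channel_contrast(self._effects(data)).set_index("channel_id")
        assert out.loc["signal", "significant"]


class TestPosthoc:
    def test_identical_cells_all_nonsignificant(self):
        eff = np.tile(np.arange(5)[:, None], (1, 4)).astype(float)
        for method in ("tukey", "bonferroni"):
            out = group.posthoc_cellwise(_cell_table(eff), method=method)
            assert (out["p_adjusted"] > 0.99).all()

    def test_tukey_no_more_conservative_than_bonferroni(self):
        rng = np.random.default_rng(6)
        eff = rng.normal(0, 1, (10, 4)) + np.array([0, 0.4, 0.8, 1.2])
        tab = _cell_table(eff)
        tk = group.posthoc_cellwise(tab, method="tukey")
        bf = group.posthoc_cellwise(tab, method="bonferroni")
        assert (tk["p_adjusted"] <= bf["p_adjusted"] + 1e-9).all()

    def test_tukey_q_matches_hand_computation(self):
        from scipy import stats
        eff = np.array([[1.0, 2.0, 3.0, 4.0],
                        [1.5, 2.1, 3.2, 3.8],
                        [0.9, 1.8, 2.9, 4.3]])
        tab = _cell_table(eff)
        out = group.posthoc_cellwise(tab, method="tukey")
        Y = eff
        resid = Y - Y.mean(1, keepdims=True) - Y.mean(0, keepdims=True) + Y.mean()
        ms = (resid ** 2).sum() / (2 * 3)
        # contrast asym/high - asym/low = col1 - col0
        row = out[out["contrast"].str.contains("asym/high - asym/low")].iloc[0]
        q_hand = abs(Y.mean(0)[1] - Y.mean(0)[0]) / np.sqrt(ms / 3)
        p_hand = stats.studentized_range.sf(q_hand, 4, 6)
        assert row["p_adjusted"] == pytest.approx(p_hand, rel=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            group.posthoc_cellwise(_cell_table(np.zeros((3, 4))), method="scheffe")
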