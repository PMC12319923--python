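"""Behavioural statistics: trimming, psychometrics, rm-ANOVA, Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toteeg import (SessionConfig, generate_trial_table, psychometric_summary,
                    rm_anova, rt_trim, tukey_hsd)

from oracles import brute_force_oneway_rm


class TestRtTrim:
    def test_constructed_outlier_excluded(self):
        rts = np.array([0.5] * 9 + [10.0])
        mask = rt_trim(rts, k=3.0)
        assert mask.sum() == 9
        assert not mask[-1]

    def test_identical_rts_all_retained(self):
        assert rt_trim(np.full(20, 0.61)).all()

    def test_normal_retention_fraction(self):
        rng = np.random.default_rng(0)
        mask = rt_trim(rng.standard_normal(10_000), k=3.0)
        assert mask.mean() == pytest.approx(0.9973, abs=0.002)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rt_trim([0.5])


class TestPsychometricSummary:
    def _table(self, seed=0):
        cfg = SessionConfig(n_participants=2, trials_per_block=30, seed=seed)
        return pd.concat([generate_trial_table(cfg, p) for p in (1, 2)],
                         ignore_index=True)

    def test_full_design_grid(self):
        out = psychometric_summary(self._table())
        assert len(out) == 2 * 5 * 5  # participants x blocks x contrasts
        assert {"p_correct", "p_confident", "mean_rt"} <= set(out.columns)

    def test_all_correct_block_gives_unit_proportion(self):
        table = self._table()
        table.loc[table["block"] == 3, "accuracy"] = 1
        out = psychometric_summary(table)
        assert (out.loc[out["block"] == 3, "p_correct"] == 1.0).all()

    def test_accuracy_increases_with_contrast(self):
        out = psychometric_summary(self._table(seed=5))
        pooled = out.groupby("contrast")["p_correct"].mean()
        rho = stats.spearmanr(pooled.index, pooled.values).statistic
        assert rho > 0.8

    def test_empty_cells_are_missing(self):
        table = self._table()
        table = table[~((table["block"] == 2) & (table["contrast"] == 0.15))]
        out = psychometric_summary(table)
        cell = out[(out["block"] == 2) & (out["contrast"] == 0.15)]
        assert cell["p_correct"].isna().all()
        assert (cell["n_trials"] == 0).all()


class TestRmAnova:
    def test_matches_brute_force_on_fixed_6x3(self):
        data = np.array([
            [3.1, 4.0, 5.2], [2.8, 3.5, 4.9], [3.5, 4.2, 5.0],
            [2.9, 3.9, 4.6], [3.3, 3.7, 5.5], [3.0, 4.1, 4.8]])
        mine = rm_anova(data, ("level",)).table.iloc[0]
        oracle = brute_force_oneway_rm(data)
        assert mine["ss"] == pytest.approx(oracle["ss"], rel=1e-12)
        assert mine["ss_error"] == pytest.approx(oracle["ss_error"], rel=1e-12)
        assert mine["F"] == pytest.approx(oracle["F"], rel=1e-12)
        assert (mine["df1"], mine["df2"]) == (oracle["df1"], oracle["df2"])

    def test_matches_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n, k = 10, 4
        data = (rng.standard_normal((n, 1)) + [0, .5, 1, 1.5]
                + rng.standard_normal((n, k)) * [1, 1, 2, 3])
        mine = rm_anova(data, ("block",)).table.iloc[0]
        df = pd.DataFrame({"y": data.ravel(),
                           "subj": np.repeat(np.arange(n), k),
                           "block": np.tile(np.arange(k), n)})
        ref = pg.rm_anova(dv="y", within="block", subject="subj", data=df,
                          correction=True, detailed=True).iloc[0]
        assert mine["F"] == pytest.approx(ref["F"], rel=1e-9)
        assert mine["p"] == pytest.approx(ref["p_unc"], rel=1e-9)
        assert mine["eps"] == pytest.approx(ref["eps"], rel=1e-6)
        assert mine["p_gg"] == pytest.approx(ref["p_GG_corr"], rel=1e-6)
        assert mine["mauchly_W"] == pytest.approx(ref["W_spher"], rel=1e-6)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n, a, b = 9, 3, 4
        data = rng.standard_normal((n, a, b)) + np.arange(a)[None, :, None] * 0.5
        mine = rm_anova(data, ("A", "B")).table.set_index("effect")
        df = pd.DataFrame({"y": data.ravel(),
                           "subj": np.repeat(np.arange(n), a * b),
                           "A": np.tile(np.repeat(np.arange(a), b), n),
                           "B": np.tile(np.arange(b), n * a)})
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subj", data=df,
                          detailed=True).set_index("Source")
        for eff_mine, eff_ref in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
            assert mine.loc[eff_mine, "F"] == pytest.approx(
                ref.loc[eff_ref, "F"], rel=1e-9)
            assert mine.loc[eff_mine, "p"] == pytest.approx(
                ref.loc[eff_ref, "p_unc"], rel=1e-9)

    def test_two_level_factor_has_unit_epsilon(self):
        rng = np.random.default_rng(1)
        res = rm_anova(rng.standard_normal((8, 2)), ("A",))
        assert res.table.iloc[0]["eps"] == 1.0
        res2 = rm_anova(rng.standard_normal((8, 2, 5)), ("A", "B")).table
        assert res2.set_index("effect").loc["A", "eps"] == 1.0

    def test_constant_shift_leaves_f_unchanged(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((7, 4, 3))
        a = rm_anova(data, ("A", "B")).table
        b = rm_anova(data + 42.0, ("A", "B")).table
        assert np.allclose(a["F"], b["F"])

    def test_gg_correction_never_decreases_p(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((9, 5)) * [1, 1, 2, 3, 4] + [0, 1.5, 3, 4.5, 6]
        row = rm_anova(data, ("A",)).table.iloc[0]
        assert row["eps"] < 1
        assert row["p_gg"] >= row["p"]

    def test_compound_symmetric_type_one_rate(self):
        """No effect + compound symmetry: uncorrected rejections ~5%."""
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            data = rng.standard_normal((10, 1)) + rng.standard_normal((10, 4))
            hits += rm_anova(data, ("A",)).table.iloc[0]["p"] < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_missing_participants_dropped(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((6, 3))
        data[0, 1] = np.nan
        res = rm_anova(data, ("A",))
        assert "n=5" in res.design

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.ones((2, 3)), ("A",))


class TestTukeyHsd:
    def test_equal_means_all_p_one(self):
        out = tukey_hsd([1.0, 1.0, 1.0], ms_error=0.5, df_error=20, n_per_cell=8)
        assert np.allclose(out["p_adj"], 1.0)
        assert len(out) == 3  # k(k-1)/2 pairs

    def test_separated_means_tiny_error(self):
        out = tukey_hsd([0.0, 5.0], ms_error=1e-8, df_error=20, n_per_cell=8)
        assert (out["p_adj"] < 1e-9).all()

    def test_q_matches_closed_form(self):
        means = [2.0, 3.5, 5.0]
        ms, n = 1.2, 9
        out = tukey_hsd(means, ms_error=ms, df_error=24, n_per_cell=n)
        for _, row in out.iterrows():
            q = abs(means[int(row["level_i"])] - means[int(row["level_j"])])
            q /= np.sqrt(ms / n)
            assert row["q"] == pytest.approx(q, rel=1e-12)
            assert row["p_adj"] == pytest.approx(
                stats.studentized_range.sf(q, 3, 24), abs=1e-9)
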