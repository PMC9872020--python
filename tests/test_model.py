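import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iscpipe.corrca import ISCSeries, WindowGrid
from iscpipe.model import (
    _RandomInterceptREML,
    build_design,
    condition_means_table,
    fit_engagement_model,
    posthoc_wilcoxon,
    signed_rank_exact_p,
    wilcoxon_signed_rank,
)
from iscpipe.movement import MovementSeries
from iscpipe.visual import ALDSeries


def make_grid(n, window_len=1.0, hop=0.5):
    starts = np.arange(n) * hop
    return WindowGrid(starts=starts, window_len=window_len, hop=hop,
                      blocks=np.array(["b0"] * n, dtype=object),
                      dropped=np.array([]))


def make_series(grid, subjects, isc, categories, ald):
    iscs = ISCSeries(subjects=subjects, global_isc=np.asarray(isc).mean(axis=1),
                     windows=np.asarray(isc, dtype=float), grid=grid, K=3)
    moves = MovementSeries(arm=np.zeros(1, bool), leg=np.zeros(1, bool),
                           categories=np.asarray(categories, dtype=str),
                           grid=grid, theta_low=1.0, theta_high=10.0)
    alds = ALDSeries(per_frame=np.zeros(1), per_window=np.asarray(ald, float),
                     grid=grid)
    return iscs, moves, alds


def synth_design(n_subjects=8, n_windows=120, tau=0.05, sigma=0.1,
                 effects=None, seed=0, ald_effect=0.0):
    """Ground-truth-known design table for model recovery tests."""
    rng = np.random.default_rng(seed)
    effects = effects or {"arm": 0.0, "leg": 0.0, "both": 0.0}
    cats = rng.choice(["neither", "arm", "leg", "both"], size=n_windows)
    ald = rng.uniform(0, 5, size=n_windows)
    rows = []
    for i in range(n_subjects):
        subj = f"S{i:02d}"
        grp = "children" if i < n_subjects // 2 else "adults"
        b = rng.normal(0, tau)
        for j in range(n_windows):
            y = (0.5 + b + effects.get(cats[j], 0.0) + ald_effect * ald[j]
                 + rng.normal(0, sigma))
            rows.append({"subject": subj, "window_start": j * 0.5,
                         "block": "b0", "isc": y, "group": grp,
                         "movement": cats[j], "ald": ald[j]})
    df = pd.DataFrame(rows)
    df.attrs["group_reference"] = "adults"
    return df


class TestBuildDesign:
    def test_two_subjects_three_windows(self):
        grid = make_grid(3)
        iscs, moves, alds = make_series(
            grid, ["a", "b"], [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]],
            ["neither", "arm", "both"], [1.0, 2.0, 3.0])
        df = build_design(iscs, moves, alds, {"a": "children", "b": "adults"})
        assert len(df) == 6
        assert set(df["movement"]) == {"neither", "arm", "both"}

    def test_grid_mismatch_rejected(self):
        g1, g2 = make_grid(3), make_grid(4)
        iscs, moves, alds = make_series(
            g1, ["a", "b"], [[0.1, 0.2, 0.3]] * 2,
            ["neither"] * 3, [1.0] * 3)
        moves.grid = g2
        with pytest.raises(ValueError, match="grid"):
            build_design(iscs, moves, alds, {"a": "children", "b": "adults"})

    def test_nan_ald_rows_dropped(self):
        grid = make_grid(3)
        iscs, moves, alds = make_series(
            grid, ["a", "b"], [[0.1, 0.2, 0.3]] * 2,
            ["neither", "arm", "leg"], [1.0, np.nan, 3.0])
        df = build_design(iscs, moves, alds, {"a": "children", "b": "adults"})
        assert len(df) == 4
        assert 0.5 not in df["window_start"].values

    def test_missing_group_rejected(self):
        grid = make_grid(2)
        iscs, moves, alds = make_series(
            grid, ["a", "b"], [[0.1, 0.2]] * 2, ["neither", "arm"], [1.0, 2.0])
        with pytest.raises(ValueError, match="group"):
            build_design(iscs, moves, alds, {"a": "children"})


class TestEngagementModel:
    def test_recovers_generating_effects(self):
        df = synth_design(effects={"arm": 0.05, "leg": 0.02, "both": 0.10},
                          seed=1)
        fit = fit_engagement_model(df)
        eff = fit.effects.set_index("effect")
        assert eff.loc["Both", "estimate"] == pytest.approx(0.10, abs=0.03)
        assert eff.loc["Arm", "estimate"] == pytest.approx(0.05, abs=0.03)
        assert eff.loc["Both", "p"] < 1e-6
        assert fit.converged

    def test_matches_closed_form_gls_at_reml_optimum(self):
        # dual route: the reported beta must equal the GLS solution computed
        # from scratch at the reported variance components
        df = synth_design(seed=2, ald_effect=0.01)
        fit = fit_engagement_model(df)
        s2, t2 = fit.residual_var, fit.random_intercept_var
        import statsmodels.formula.api as smf

        work = df.copy()
        mu, sd = work["ald"].mean(), work["ald"].std(ddof=0)
        work["ald_std"] = (work["ald"] - mu) / sd
        md = smf.mixedlm("isc ~ C(group, Treatment('adults'))"
                         " * C(movement, Treatment('neither')) + ald_std",
                         work, groups=work["subject"])
        m = _RandomInterceptREML(md.exog, md.endog,
                                 pd.Categorical(work["subject"]).codes)
        beta_std = m.gls_beta(s2, t2)
        j_ald = md.exog_names.index("ald_std")
        raw_ald = beta_std[j_ald] / sd
        eff = fit.effects.set_index("effect")
        assert eff.loc["ALD", "estimate"] == pytest.approx(raw_ald, rel=1e-8)

    def test_reference_levels_stable_under_row_permutation(self):
        df = synth_design(effects={"arm": 0.05, "leg": 0.0, "both": 0.08},
                          seed=3)
        fit1 = fit_engagement_model(df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled.attrs["group_reference"] = "adults"
        fit2 = fit_engagement_model(shuffled)
        e1 = fit1.effects.set_index("effect")["estimate"]
        e2 = fit2.effects.set_index("effect")["estimate"]
        pd.testing.assert_series_equal(e1, e2, atol=1e-8, rtol=1e-6)

    def test_duplication_shrinks_se_detected_by_df(self):
        df = synth_design(seed=4)
        fit1 = fit_engagement_model(df, df_method="residual")
        dup = pd.concat([df, df], ignore_index=True)
        dup.attrs["group_reference"] = "adults"
        fit2 = fit_engagement_model(dup, df_method="residual")
        e1 = fit1.effects.set_index("effect")
        e2 = fit2.effects.set_index("effect")
        for eff in ("Arm", "Leg", "Both"):
            assert e2.loc[eff, "estimate"] == pytest.approx(
                e1.loc[eff, "estimate"], abs=1e-6)
            assert e2.loc[eff, "se"] < e1.loc[eff, "se"]
        assert e2["df"].iloc[0] == pytest.approx(2 * len(df) - 9)

    def test_satterthwaite_balanced_oneway_oracle(self):
        # oracle: in a balanced one-way random-effects design the df of the
        # grand mean equals n_groups - 1 (the between-group MS df)
        rng = np.random.default_rng(5)
        N, n = 12, 40
        rows = []
        for g in range(N):
            b = rng.normal(0, 1.0)
            for _ in range(n):
                rows.append({"subject": f"g{g}", "y": 3.0 + b + rng.normal()})
        df = pd.DataFrame(rows)
        import statsmodels.formula.api as smf

        md = smf.mixedlm("y ~ 1", df, groups=df["subject"])
        res = md.fit(reml=True)
        m = _RandomInterceptREML(md.exog, md.endog,
                                 pd.Categorical(df["subject"]).codes)
        s2, t2, _ = m.refine(float(res.scale), float(np.asarray(res.cov_re)[0, 0]))
        dfs = m.satterthwaite_df(s2, t2)
        assert dfs[0] == pytest.approx(N - 1, rel=0.15)

    def test_between_vs_within_df_separation(self):
        df = synth_design(n_subjects=8, seed=6)
        fit = fit_engagement_model(df)
        eff = fit.effects.set_index("effect")
        assert eff.loc["Children", "df"] < 20       # between-subject effect
        assert eff.loc["Arm", "df"] > 500           # within-subject effect

    def test_too_few_subjects_per_group_rejected(self):
        df = synth_design(n_subjects=8, seed=7)
        df = df[df["subject"] != "S00"]
        df = df[df["subject"] != "S01"]
        df = df[df["subject"] != "S02"].copy()
        df.attrs["group_reference"] = "adults"
        with pytest.raises(ValueError, match="subjects"):
            fit_engagement_model(df)

    def test_constant_ald_rejected(self):
        df = synth_design(seed=8)
        df["ald"] = 1.0
        df.attrs["group_reference"] = "adults"
        with pytest.raises(ValueError):
            fit_engagement_model(df)


class TestWilcoxon:
    def test_exact_statistic_matches_enumeration_oracle(self):
        # n=8 hand-built differences, all positive
        diffs = np.array([0.3, 0.5, 0.1, 0.9, 0.2, 0.7, 0.4, 0.6])
        stat, p, method = wilcoxon_signed_rank(diffs)
        assert method == "exact"
        # oracle: exhaustive enumeration of all 2^8 sign patterns
        ranks = stats.rankdata(np.abs(diffs))
        total = ranks.sum()
        w_obs = ranks[diffs > 0].sum()
        stat_obs = min(w_obs, total - w_obs)
        count = sum(
            1 for signs in itertools.product([0, 1], repeat=8)
            if min(s := sum(r for r, z in zip(ranks, signs) if z), total - s)
            <= stat_obs + 1e-12)
        p_oracle = count / 2**8
        assert p == pytest.approx(p_oracle, rel=1e-12)
        # scipy reports W- for two-sided; all-positive diffs give min = 0
        assert stat == 0.0
        # package's own enumeration helper agrees
        w_plus, p_helper = signed_rank_exact_p(diffs)
        assert w_plus == total
        assert p_helper == pytest.approx(p_oracle, rel=1e-12)

    def test_all_zero_diffs_give_p_one(self):
        stat, p, method = wilcoxon_signed_rank(np.zeros(10))
        assert p == 1.0 and method == "degenerate"

    def test_exact_below_cutoff_approx_above(self):
        rng = np.random.default_rng(9)
        _, _, m_small = wilcoxon_signed_rank(rng.normal(size=20))
        _, _, m_big = wilcoxon_signed_rank(rng.normal(size=40))
        assert m_small == "exact"
        assert m_big == "approx"


class TestPosthoc:
    def test_identical_condition_means_p_one(self):
        grid = make_grid(8)
        cats = ["neither", "arm", "neither", "arm"] * 2
        isc = [[0.5] * 8] * 4  # every condition identical for every subject
        iscs, moves, alds = make_series(
            grid, ["a", "b", "c", "d"], isc, cats, [1, 2, 3, 4, 1, 2, 3, 4])
        df = build_design(iscs, moves, alds,
                          {"a": "children", "b": "children",
                           "c": "adults", "d": "adults"})
        out = posthoc_wilcoxon(df)
        # all subjects share identical means per condition => no difference
        assert (out["p_raw"] == 1.0).all()

    def test_bonferroni_bound(self):
        df = synth_design(effects={"arm": 0.02, "leg": 0.0, "both": 0.05},
                          seed=10)
        out = posthoc_wilcoxon(df)
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()
        big = out["p_raw"] * out["m_comparisons"] >= 1
        assert (out.loc[big, "p_bonferroni"] == 1.0).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_detects_strong_both_effect(self):
        # n=20 so each (group, ALD-level) panel has 10 paired subjects;
        # smallest attainable corrected p is then 6 * 2/2^10 ~ 0.012
        df = synth_design(n_subjects=20, effects={"arm": 0.0, "leg": 0.0,
                                                  "both": 0.3},
                          tau=0.01, sigma=0.05, seed=11)
        out = posthoc_wilcoxon(df)
        hit = out[(out["cond_a"] == "neither") & (out["cond_b"] == "both")]
        assert (hit["p_bonferroni"] < 0.05).all()

    def test_underpowered_flagged_still_computed(self):
        df = synth_design(n_subjects=4, seed=12)
        out = posthoc_wilcoxon(df)
        assert out["underpowered"].all()
        assert out["p_raw"].notna().all()

    def test_family_all_larger_correction(self):
        df = synth_design(seed=13)
        per_panel = posthoc_wilcoxon(df, family="per_panel")
        all_fam = posthoc_wilcoxon(df, family="all")
        assert (all_fam["m_comparisons"] > per_panel["m_comparisons"]).all()

    def test_explicit_cutoff_respected(self):
        df = synth_design(seed=14)
        out = posthoc_wilcoxon(df, ald_cutoff=2.5)
        assert (out["ald_cutoff"] == 2.5).all()

    def test_condition_means_table_shape(self):
        df = synth_design(seed=15)
        tab = condition_means_table(df)
        assert {"group", "ald_level", "movement", "mean"} <= set(tab.columns)
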