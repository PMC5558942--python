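"""Cross-species ANOVA/ANCOVA, assumption tests, period split and paired t."""

import numpy as np
import pandas as pd
import pytest

from endotrend import (ancova, assumption_tests, paired_t, split_periods,
                       two_way_anova)

from conftest import make_records


def brute_force_typ3_F(y, factors, effect, covariate=None):
    """Model-comparison F for one term: drop it from the full sum-coded model."""
    y = np.asarray(y, float)
    cls = np.where(np.asarray(factors["taxo_class"]) == "bird", 1.0, -1.0)
    hab = np.where(np.asarray(factors["habitat"]) == "aquatic", 1.0, -1.0)
    cols = {"taxo_class": cls, "habitat": hab, "interaction": cls * hab}
    if covariate is not None:
        cols["covariate"] = np.asarray(covariate, float)

    def rss(names):
        X = np.column_stack([np.ones(len(y))] + [cols[n] for n in names])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2)), X.shape[1]

    full_names = list(cols)
    rss_full, k_full = rss(full_names)
    rss_red, _ = rss([n for n in full_names if n != effect])
    df_den = len(y) - k_full
    return ((rss_red - rss_full) / 1) / (rss_full / df_den), df_den


def grid_design(cell_means, reps=5, spread=0.1):
    """Balanced 2x2 species design with a fixed symmetric noise pattern."""
    noise = spread * np.linspace(-1, 1, reps)
    rows = []
    for (cls, hab), mu in cell_means.items():
        for e in noise:
            rows.append({"taxo_class": cls, "habitat": hab, "r": mu + e})
    return pd.DataFrame(rows)


CELLS = [("bird", "aquatic"), ("bird", "terrestrial"),
         ("mammal", "aquatic"), ("mammal", "terrestrial")]


class TestTwoWayAnova:
    def test_habitat_effect_only_matches_oracle(self):
        d = grid_design(dict(zip(CELLS, [0.0, 1.0, 0.0, 1.0])))
        res = two_way_anova(d["r"], d["taxo_class"], d["habitat"])
        for effect in ("taxo_class", "habitat", "interaction"):
            F_oracle, df_den = brute_force_typ3_F(d["r"], d, effect)
            assert res[effect].F == pytest.approx(F_oracle, rel=1e-8)
            assert res[effect].df_den == df_den

    def test_unbalanced_design_matches_oracle(self, rng):
        sizes = dict(zip(CELLS, [10, 17, 4, 13]))
        rows = []
        for cell, n in sizes.items():
            for _ in range(n):
                rows.append({"taxo_class": cell[0], "habitat": cell[1],
                             "r": rng.normal(0.1 * (cell[1] == "aquatic"),
                                             0.1)})
        d = pd.DataFrame(rows)
        res = two_way_anova(d["r"], d["taxo_class"], d["habitat"])
        assert res["habitat"].df_den == sum(sizes.values()) - 4
        for effect in ("taxo_class", "habitat", "interaction"):
            F_oracle, _ = brute_force_typ3_F(d["r"], d, effect)
            assert res[effect].F == pytest.approx(F_oracle, rel=1e-8)

    def test_equal_cell_means_give_zero_F(self):
        d = grid_design(dict(zip(CELLS, [0.5] * 4)))
        res = two_way_anova(d["r"], d["taxo_class"], d["habitat"])
        assert res["taxo_class"].F == pytest.approx(0.0, abs=1e-20)
        assert res["habitat"].F == pytest.approx(0.0, abs=1e-20)

    def test_undersized_cell_fatal(self):
        d = grid_design(dict(zip(CELLS, [0, 0, 0, 0])), reps=2)
        d = d[~((d.taxo_class == "mammal") & (d.habitat == "aquatic"))
              | (d.index % 2 == 0)]
        with pytest.raises(ValueError, match="fewer than 2"):
            two_way_anova(d["r"], d["taxo_class"], d["habitat"])


class TestAncova:
    def test_unrelated_covariate_leaves_F_similar(self, rng):
        d = grid_design(dict(zip(CELLS, [0.0, 1.0, 0.0, 1.0])))
        cov = rng.standard_normal(len(d))  # unrelated to groups and response
        res0 = two_way_anova(d["r"], d["taxo_class"], d["habitat"])
        res1 = ancova(d["r"], d["taxo_class"], d["habitat"], cov)
        assert res1["habitat"].df_den == res0["habitat"].df_den - 1
        assert res1["habitat"].F == pytest.approx(res0["habitat"].F, rel=0.5)
        for effect in ("taxo_class", "habitat", "covariate"):
            F_oracle, _ = brute_force_typ3_F(d["r"], d, effect, covariate=cov)
            assert res1[effect].F == pytest.approx(F_oracle, rel=1e-8)

    def test_covariate_absorbs_identical_response(self, rng):
        d = grid_design(dict(zip(CELLS, [0.0, 0.3, 0.1, 0.4])))
        cov = d["r"].to_numpy().copy()
        d["r"] = cov + 0.001 * rng.standard_normal(len(d))
        res = ancova(d["r"], d["taxo_class"], d["habitat"], cov)
        assert res["covariate"].F > 100
        assert res["taxo_class"].F < 1

    def test_constant_covariate_fatal(self):
        d = grid_design(dict(zip(CELLS, [0.0, 1.0, 0.0, 1.0])))
        with pytest.raises(ValueError, match="constant"):
            ancova(d["r"], d["taxo_class"], d["habitat"], np.ones(len(d)))

    def test_parallelism_reported(self):
        d = grid_design(dict(zip(CELLS, [0.0, 1.0, 0.0, 1.0])))
        cov = np.tile(np.linspace(-1, 1, 5), 4)
        res = ancova(d["r"], d["taxo_class"], d["habitat"], cov)
        assert set(res.parallelism) == {"F", "df_num", "df_den", "p"}
        assert res.parallelism["df_num"] == 2


class TestAssumptionTests:
    def test_identical_groups_levene_zero(self):
        resid = np.r_[np.arange(5.0), np.arange(5.0)]
        groups = ["a"] * 5 + ["b"] * 5
        out = assumption_tests(resid, groups)
        assert out["levene_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_unequal_variance_detected(self, rng):
        resid = np.r_[rng.normal(0, 1, 200), rng.normal(0, 10, 200)]
        groups = ["a"] * 200 + ["b"] * 200
        assert assumption_tests(resid, groups)["levene_p"] < 1e-3

    def test_ks_calibrated_on_normal_residuals(self, rng):
        rejections = sum(
            assumption_tests(rng.standard_normal(1000), ["a"] * 500 + ["b"] * 500)["ks_p"] < 0.05
            for _ in range(40))
        # plain KS with estimated parameters is conservative: few rejections
        assert rejections <= 4


class TestPeriodSplit:
    def test_boundary_year_goes_to_first_period(self):
        tab = make_records("a", [1.0, 2.0], [1950, 1951])
        split = split_periods(tab, boundary=1950)
        assert split.records_pre.df["year"].tolist() == [1950]
        assert split.records_post.df["year"].tolist() == [1951]

    def test_boundary_below_all_years_leaves_post_complete(self, small_sim):
        tab = small_sim["records"]
        split = split_periods(tab, boundary=1800)
        assert len(split.records_pre) == 0
        pd.testing.assert_frame_equal(split.records_post.df, tab.df)

    def test_species_absent_from_period_is_unavailable(self, rng):
        years = rng.integers(1960, 2000, 60)
        mass = rng.normal(50, 2, 60)
        tab = make_records("late", mass, years,
                           list(rng.uniform(30, 60, 60)),
                           list(rng.uniform(-120, -100, 60)),
                           list(np.where(rng.integers(0, 2, 60), "male",
                                         "female")))
        split = split_periods(tab, boundary=1950)
        assert split.trends_pre.empty or (
            split.trends_pre.loc["late", "trend_class"] == "unavailable")
        assert split.trends_post.loc["late", "trend_class"] != "unavailable"


class TestPairedT:
    def test_hand_computed_example(self):
        r1 = np.array([0.5, 0.6, 0.7])
        r2 = r1 - np.array([0.1, 0.2, 0.3])
        out = paired_t(r1, r2)
        assert out["t"] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-9)
        assert out["df"] == 2

    def test_identical_periods_flagged_degenerate(self):
        x = np.array([0.1, 0.2, 0.3])
        out = paired_t(x, x)
        assert out["degenerate"] and np.isnan(out["t"])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            paired_t([0.1, 0.2], [0.1, 0.2, 0.3])

    def test_nan_pairs_dropped(self):
        out = paired_t([0.1, np.nan, 0.3, 0.5], [0.0, 0.2, 0.1, 0.2])
        assert out["n_pairs"] == 3
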