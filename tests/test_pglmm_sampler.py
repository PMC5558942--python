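"""Gibbs sampler correctness: reproducibility, OLS limit, pMCMC, DIC, contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from endotrend import (ChainConfig, PhylogeneticGLMM, PriorSpec, RecordTable,
                       SpeciesMeta, coefficient_contrast, phylo_covariance,
                       pmcmc, simulate_tree)
from endotrend.pglmm import build_design

CELLS = [("bird", "aquatic"), ("bird", "terrestrial"),
         ("mammal", "aquatic"), ("mammal", "terrestrial")]

FAST = dict(total=8_000, burn_in=2_000, thin=3)   # 2000 retained


def simulate_from_model(seed, n_species=8, per_species=80, beta=None,
                        sigma_a2=0.2, sigma_e2=1.0, model="C"):
    """Draw records whose mass IS the linear-mixed-model response.

    Fixed effects default to zero except those in ``beta``; use with
    ``standardize="none"`` so the fitted coefficients are on the same
    scale as the generating ones.
    """
    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    tree = simulate_tree(n_species, seed=seed + 1000, labels=labels)
    rows, meta = [], {}
    for i, sp in enumerate(labels):
        cls, hab = CELLS[i % 4]
        years = rng.integers(1915, 2014, per_species)
        rows.append(pd.DataFrame({
            "species_id": sp, "mass": 0.0, "year": years,
            "latitude": rng.uniform(30, 70, per_species),
            "longitude": rng.uniform(-130, -95, per_species),
            "sex": np.where(rng.integers(0, 2, per_species), "male",
                            "female")}))
        meta[sp] = SpeciesMeta(sp, cls, hab, per_species,
                               int(years.min()), int(years.max()))
    tab = RecordTable(pd.concat(rows, ignore_index=True), source="synthetic")
    X, _ = build_design(tab, meta, model=model)
    bvec = np.array([(beta or {}).get(c, 0.0) for c in X.columns])
    A = phylo_covariance(tree, species_order=labels).matrix
    u = np.linalg.cholesky(A + 1e-10 * np.eye(n_species)) @ \
        rng.standard_normal(n_species) * np.sqrt(sigma_a2)
    sp_idx = tab.df["species_id"].map(dict(zip(labels, range(n_species))))
    y = (X.to_numpy(float) @ bvec + u[sp_idx.to_numpy()]
         + np.sqrt(sigma_e2) * rng.standard_normal(len(tab.df)))
    tab.df["mass"] = y
    return tab, meta, tree, dict(zip(X.columns, bvec))


class TestChainConfig:
    def test_default_retains_two_thousand(self):
        assert ChainConfig().retained == 2000

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(total=1000, burn_in=1000, thin=10)
        with pytest.raises(ValueError):
            ChainConfig(total=1100, burn_in=1000, thin=33)


class TestPmcmc:
    def test_floor_is_one_over_n(self):
        assert pmcmc(np.ones(2000)) == 1.0 / 2000  # 5.0E-04

    def test_direct_count(self):
        assert pmcmc([-1.0, 2.0, 3.0, 4.0]) == 0.5

    def test_balanced_draws_give_one(self):
        assert pmcmc([-1, -2, 1, 2]) == 1.0

    def test_invariant_to_order_and_positive_scale(self, rng):
        d = rng.standard_normal(500) + 0.3
        assert pmcmc(d) == pmcmc(d[::-1]) == pmcmc(3.7 * d)

    def test_all_zero_is_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            assert np.isnan(pmcmc(np.zeros(10)))


class TestSampler:
    def test_same_seed_reproduces_chain_exactly(self):
        tab, meta, tree, _ = simulate_from_model(3, n_species=6,
                                                 per_species=40)
        kw = dict(model="period", standardize="none", total=2000,
                  burn_in=500, thin=5, random_state=42)
        f1 = PhylogeneticGLMM(**kw).fit(tab, meta=meta, tree=tree)
        f2 = PhylogeneticGLMM(**kw).fit(tab, meta=meta, tree=tree)
        pd.testing.assert_frame_equal(f1.chain_.draws, f2.chain_.draws,
                                      check_exact=True)
        assert f1.dic_ == f2.dic_

    def test_degenerate_phylo_variance_matches_ols(self):
        tab, meta, tree, _ = simulate_from_model(
            7, n_species=8, per_species=120, sigma_a2=0.0,
            beta={"year": -0.004, "abs_latitude": 0.01, "sex_male": 0.05})
        fit = PhylogeneticGLMM(
            model="period", standardize="none",
            priors=PriorSpec(fixed_phylo_variance=1e-10),
            random_state=5, **FAST).fit(tab, meta=meta, tree=tree)
        X, _ = build_design(tab, meta, model="period")
        ols = sm.OLS(tab.df["mass"], X).fit()
        for name in X.columns:
            post = fit.chain_.draws[name]
            assert abs(post.mean() - ols.params[name]) < 0.2 * post.std()

    def test_credible_interval_covers_generating_slope(self):
        hits = 0
        for seed in (21, 22, 23):
            tab, meta, tree, _ = simulate_from_model(
                seed, n_species=8, per_species=120,
                beta={"year": -0.005, "year_x_habitat_terrestrial": -0.008})
            fit = PhylogeneticGLMM(model="C", standardize="none",
                                   random_state=seed, **FAST).fit(
                tab, meta=meta, tree=tree)
            s = fit.summary_
            if s.loc["year", "l95"] <= -0.005 <= s.loc["year", "u95"]:
                hits += 1
        assert hits >= 2

    def test_centered_year_reports_raw_scale(self):
        tab, meta, tree, _ = simulate_from_model(
            9, n_species=8, per_species=100,
            beta={"year": -0.005, "year_x_habitat_terrestrial": -0.008,
                  "habitat_terrestrial": 0.3})
        kw = dict(model="C", standardize="none", **FAST)
        raw = PhylogeneticGLMM(center_year=False, random_state=1,
                               **kw).fit(tab, meta=meta, tree=tree)
        cen = PhylogeneticGLMM(center_year=True, random_state=2,
                               **kw).fit(tab, meta=meta, tree=tree)
        for name in ("year", "year_x_habitat_terrestrial",
                     "habitat_terrestrial", "intercept"):
            sd = raw.summary_.loc[name, "post_mean"] - \
                cen.summary_.loc[name, "post_mean"]
            scale = raw.chain_.draws[name].std()
            assert abs(sd) < 0.5 * scale + 1e-12

    def test_missing_tree_fatal(self, small_sim):
        with pytest.raises(ValueError, match="phylogeny"):
            PhylogeneticGLMM().fit(small_sim["records"],
                                   meta=small_sim["meta"], tree=None)


class TestDic:
    def test_reproducible_within_monte_carlo_band(self):
        tab, meta, tree, _ = simulate_from_model(13, n_species=8,
                                                 per_species=80)
        kw = dict(model="period", standardize="none", **FAST)
        d1 = PhylogeneticGLMM(random_state=1, **kw).fit(
            tab, meta=meta, tree=tree).dic_
        d2 = PhylogeneticGLMM(random_state=2, **kw).fit(
            tab, meta=meta, tree=tree).dic_
        assert abs(d1 - d2) < 10

    def test_prefers_generating_interaction_model(self):
        wins = 0
        for seed in range(10):
            tab, meta, tree, _ = simulate_from_model(
                100 + seed, n_species=8, per_species=125,
                beta={"year": -0.005, "year_x_habitat_terrestrial": -0.008})
            dics = {}
            for model in ("A", "C"):
                dics[model] = PhylogeneticGLMM(
                    model=model, standardize="none", random_state=seed,
                    total=4000, burn_in=1000, thin=2).fit(
                    tab, meta=meta, tree=tree).dic_
            wins += dics["C"] < dics["A"]
        assert wins >= 8


class TestContrast:
    def _chains(self, shift=0.0):
        tab, meta, tree, _ = simulate_from_model(31, n_species=6,
                                                 per_species=50)
        kw = dict(model="period", standardize="none", total=2000,
                  burn_in=500, thin=5)
        a = PhylogeneticGLMM(random_state=1, **kw).fit(
            tab, meta=meta, tree=tree).chain_
        b = PhylogeneticGLMM(random_state=2, **kw).fit(
            tab, meta=meta, tree=tree).chain_
        if shift:
            b.draws = a.draws + shift
        return a, b

    def test_pure_shift_recovered(self):
        a, b = self._chains(shift=0.5)
        s = coefficient_contrast(a, b).summary()
        assert np.allclose(s["post_mean"], 0.5)
        assert (s["pmcmc"] == 1.0 / a.retained).all()

    def test_null_contrast_not_at_floor(self):
        a, b = self._chains()
        s = coefficient_contrast(a, b, coefficients=["longitude"]).summary()
        assert s.loc["longitude", "pmcmc"] > 1.0 / a.retained

    def test_unequal_lengths_fatal(self):
        a, b = self._chains()
        b.draws = b.draws.iloc[:100]
        with pytest.raises(ValueError, match="retained-sample counts"):
            coefficient_contrast(a, b)
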