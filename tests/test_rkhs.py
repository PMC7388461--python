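"""Gibbs sampler for the multi-kernel RKHS model family."""

import numpy as np
import pandas as pd
import pytest

import hologen as hg
from helpers import blup_oracle
from hologen.rkhs import RKHSGibbsRegressor, _fixed_design


@pytest.fixture(scope="module")
def oracle_data():
    cfg = hg.SimulationConfig(
        n_sires=4, progeny_per_sire=10, pigs_per_pen=5, n_markers=400,
        n_otu=60, n_contemporary_groups=2, n_traits=2, seed=5,
    )
    return hg.simulate_dataset(cfg)


class TestMmeEquivalence:
    def test_fixed_variance_fit_solves_henderson_equations(self, oracle_data):
        """With variance components held fixed, posterior means of all
        effects match the closed-form BLUP solve to 1e-3, including
        predictions for masked animals."""
        d = oracle_data
        y = d.records["trait1"].copy()
        y.iloc[-8:] = np.nan
        var_k = {"G": 0.4, "M": 0.3}
        reg = RKHSGibbsRegressor(
            kernels={"G": d.G, "M": d.M},
            n_iter=3000, burn_in=500, thin=1,
            fix_variance_components={**var_k, "pen": 0.05, "residual": 0.3},
            random_state=7,
        )
        reg.fit(d.records, y)
        beta, u, pen, pred = blup_oracle(
            d.records, y, {"G": d.G, "M": d.M}, var_k, 0.05, 0.3
        )
        assert np.abs(reg.fixed_effects_.to_numpy() - beta).max() < 1e-3
        for name in var_k:
            assert np.abs(reg.random_effects_[name].to_numpy() - u[name]).max() < 1e-3
        assert np.abs(reg.pen_effects_.to_numpy() - pen).max() < 1e-3
        obs = np.isfinite(y.to_numpy())
        got = reg.predict(d.records.index[~obs].to_numpy())
        assert np.abs(got - pred[~obs]).max() < 1e-3

    def test_m1_masked_prediction_matches_blup_projection(self, oracle_data):
        d = oracle_data
        y = d.records["trait2"].copy()
        y.iloc[:6] = np.nan
        reg = RKHSGibbsRegressor(
            kernels={"G": d.G},
            n_iter=2000, burn_in=200, thin=1,
            fix_variance_components={"G": 0.5, "pen": 0.02, "residual": 0.5},
            random_state=3,
        )
        reg.fit(d.records, y)
        _, _, _, pred = blup_oracle(d.records, y, {"G": d.G}, {"G": 0.5}, 0.02, 0.5)
        obs = np.isfinite(y.to_numpy())
        got = reg.predict(d.records.index[~obs].to_numpy())
        assert np.abs(got - pred[~obs]).max() < 1e-3


class TestBaselineModel:
    def test_m0_fixed_effects_near_ols(self, oracle_data):
        """Pure-noise phenotypes with no pen variance: posterior mean cell
        predictions agree with the OLS fit within Monte-Carlo error."""
        d = oracle_data
        rng = np.random.default_rng(2)
        records = d.records.copy()
        records["noise"] = rng.normal(size=len(records))
        res = hg.fit_rkhs(
            records, "noise", hg.ModelSpec("M0"),
            hg.McmcSettings(n_iter=6000, burn_in=1000, thin=1, seed=4),
        )
        W, _ = _fixed_design(records)
        beta_ols, *_ = np.linalg.lstsq(W, records["noise"].to_numpy(), rcond=None)
        fitted_ols = W @ beta_ols
        fitted_fixed = W @ res.fixed_effects.to_numpy()
        assert np.abs(fitted_fixed - fitted_ols).max() < 0.15  # ~3 posterior SE

    def test_m0_prediction_is_fixed_plus_pen_only(self, oracle_data):
        d = oracle_data
        y = d.records["trait1"].copy()
        y.iloc[:5] = np.nan
        res = hg.fit_rkhs(y.to_frame("t").join(d.design), "t",
                          hg.ModelSpec("M0"), hg.McmcSettings.fast(seed=1))
        assert res.random_effects == {}
        yhat = hg.predict_masked(res, d.records)
        assert len(yhat) == 5


class TestPosteriorSummary:
    def test_forced_ratio_draws(self):
        draws = pd.DataFrame({
            "M": np.full(100, 29.0),
            "pen": np.full(100, 1.0),
            "residual": np.full(100, 70.0),
        })
        s = hg.summarize_posterior(draws)
        assert s.microbiability == pytest.approx(0.29)
        assert s.fraction_draws["M"].std() == 0

    def test_zero_variance_gives_zero_fraction(self):
        draws = pd.DataFrame({"M": np.zeros(50), "residual": np.ones(50)})
        s = hg.summarize_posterior(draws)
        assert s.microbiability == 0.0

    def test_matches_one_pass_recomputation(self, rng):
        draws = pd.DataFrame(
            rng.gamma(2.0, 1.0, size=(1000, 3)), columns=["G", "pen", "residual"]
        )
        s = hg.summarize_posterior(draws)
        arr = draws.to_numpy()
        fr = arr / arr.sum(axis=1, keepdims=True)
        assert np.abs(s.fraction_draws.to_numpy() - fr).max() < 1e-12
        assert np.allclose(s.table["frac_mean"].to_numpy(), fr.mean(axis=0))

    def test_fractions_sum_to_one_per_draw(self, rng):
        draws = pd.DataFrame(
            rng.gamma(1.0, 1.0, size=(200, 4)), columns=["G", "M", "pen", "residual"]
        )
        s = hg.summarize_posterior(draws)
        assert np.allclose(s.fraction_draws.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_draws_rejected(self):
        with pytest.raises(hg.HologenError):
            hg.summarize_posterior(pd.DataFrame({"G": []}))


class TestFitBehaviour:
    def test_deterministic_given_seed(self, oracle_data):
        d = oracle_data
        spec = hg.make_model_spec("M1", G=d.G)
        mcmc = hg.McmcSettings(n_iter=600, burn_in=100, thin=2, seed=9)
        a = hg.fit_rkhs(d.records, "trait1", spec, mcmc)
        b = hg.fit_rkhs(d.records, "trait1", spec, mcmc)
        assert a.summary.draws.equals(b.summary.draws)

    def test_duplicated_animal_gets_its_twin_prediction(self):
        """A masked animal whose kernel row duplicates a training animal
        receives (nearly) that animal's fitted value on noiseless data."""
        rng = np.random.default_rng(0)
        n = 24
        ids = np.array([f"A{i}" for i in range(n)])
        Xf = rng.normal(size=(n, 40))
        Xf[-1] = Xf[0]  # animal n-1 is a feature-duplicate of animal 0
        K = hg.RelationshipKernel(ids, Xf @ Xf.T / 40, "G")
        # uniform design: the twins must differ only through the kernel
        design = pd.DataFrame(
            {
                "sire": ["S1"] * 12 + ["S2"] * 12,
                "dam_line": ["DL1"] * n,
                "sex": ["M"] * n,
                "contemporary_group": ["CG1"] * n,
                "pen": ["P1"] * n,
            },
            index=ids,
        )
        u = Xf @ rng.normal(size=40) / np.sqrt(40)
        y = pd.Series(u, index=ids)
        y.iloc[-1] = np.nan
        reg = RKHSGibbsRegressor(
            kernels={"G": K}, n_iter=4000, burn_in=500, thin=1,
            fix_variance_components={"G": 1.0, "pen": 1e-4, "residual": 1e-3},
            random_state=5,
        )
        reg.fit(design, y)
        pred = reg.predict(["A23"])[0]
        fitted_twin = reg.predict(["A0"])[0]
        assert pred == pytest.approx(fitted_twin, abs=5e-3)
        assert pred == pytest.approx(u[0], abs=0.05)

    def test_adding_null_kernel_leaves_fractions_stable(self, oracle_data):
        """M3 vs M1 on microbiome-free data: the genomic fraction moves by
        no more than Monte-Carlo error."""
        import dataclasses

        d = oracle_data
        cfg = dataclasses.replace(
            d.config,
            var_fractions={
                "additive": 0.45, "microbiome": 0.0, "interaction": 0.0,
                "pen": 0.05, "residual": 0.50,
            },
        )
        records, _ = hg.simulate_phenotypes(d.G, d.M, d.design, cfg)
        m1 = hg.fit_rkhs(records, "trait1", hg.make_model_spec("M1", G=d.G),
                         hg.McmcSettings.fast(seed=21))
        m3 = hg.fit_rkhs(records, "trait1",
                         hg.make_model_spec("M3", G=d.G, M=d.M),
                         hg.McmcSettings.fast(seed=22))
        sd = m1.summary.table.loc["G", "frac_sd"]
        assert abs(m1.summary.heritability - m3.summary.heritability) < 3 * sd

    def test_missing_factor_level_rejected(self, oracle_data):
        d = oracle_data
        y = d.records["trait1"].copy()
        y[d.design["contemporary_group"] == "CG1"] = np.nan
        reg = RKHSGibbsRegressor(kernels=None, n_iter=50, burn_in=10)
        with pytest.raises(hg.HologenError, match="no observed records"):
            reg.fit(d.records, y)

    def test_unknown_animal_prediction_rejected(self, oracle_data):
        d = oracle_data
        res = hg.fit_rkhs(d.records, "trait1", hg.ModelSpec("M0"),
                          hg.McmcSettings(n_iter=200, burn_in=50, seed=0))
        with pytest.raises(hg.HologenError, match="absent"):
            res.model.predict(["nonexistent"])

    def test_model_spec_kernel_contract(self, oracle_data):
        d = oracle_data
        with pytest.raises(hg.HologenError, match="requires kernels"):
            hg.ModelSpec("M2", kernels={"G": d.G})
        with pytest.raises(hg.HologenError, match="needs a genomic"):
            hg.make_model_spec("M1")

    def test_permutation_leaves_posterior_stable(self, oracle_data):
        """Reordering animals consistently leaves variance summaries within
        Monte-Carlo error."""
        d = oracle_data
        perm = np.random.default_rng(1).permutation(len(d.records))
        ids = d.records.index.to_numpy()[perm]
        records_p = d.records.loc[ids]
        Gp = hg.RelationshipKernel(ids, d.G.matrix[np.ix_(perm, perm)], "G")
        spec = hg.make_model_spec("M1", G=d.G)
        spec_p = hg.make_model_spec("M1", G=Gp)
        a = hg.fit_rkhs(d.records, "trait1", spec, hg.McmcSettings.fast(seed=3))
        b = hg.fit_rkhs(records_p, "trait1", spec_p, hg.McmcSettings.fast(seed=3))
        sd = a.summary.table.loc["G", "frac_sd"]
        assert abs(a.summary.heritability - b.summary.heritability) < 3 * sd


class TestMcmcSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(hg.HologenError):
            hg.McmcSettings(n_iter=100, burn_in=100)
        with pytest.raises(hg.HologenError):
            hg.McmcSettings(thin=0)

    def test_retained_count(self):
        s = hg.McmcSettings(n_iter=1000, burn_in=200, thin=5)
        assert s.n_retained == 160
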