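"""Kernel construction, the Gibbs samplers, variance components,
prediction contracts and the bivariate trait model."""

import numpy as np
import pandas as pd
import pytest

import gxepred as gx
from gxepred.kernels import ModelDesign, build_kernels
from gxepred.models import (McmcSettings, extract_variance_components,
                            fit_bivariate_trait_model, fit_model, predict)
from gxepred.simulate import simulate_phenotypes


def toy_design():
    return ModelDesign(genotype=pd.Series(["g1", "g1", "g2", "g3"]),
                       environment=pd.Series(["e1", "e2", "e1", "e2"]))


def toy_H():
    labels = ["g1", "g2", "g3"]
    H = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.4], [0.25, 0.4, 1.0]])
    return pd.DataFrame(H, index=labels, columns=labels)


def toy_Omega():
    labels = ["e1", "e2"]
    return pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=labels,
                        columns=labels)


class TestBuildKernels:
    def test_environment_indicator(self):
        ks = build_kernels(toy_design(), toy_H(), toy_Omega())
        KE = ks.kernels["E"]
        assert KE[0, 2] == 1.0 and KE[0, 1] == 0.0
        assert set(np.unique(KE)) == {0.0, 1.0}

    def test_hadamard_reaction_norm_kernel(self):
        ks = build_kernels(toy_design(), toy_H(), toy_Omega())
        H, O = toy_H(), toy_Omega()
        genos = ["g1", "g1", "g2", "g3"]
        envs = ["e1", "e2", "e1", "e2"]
        for i in range(4):
            for j in range(4):
                expect = H.loc[genos[i], genos[j]] * O.loc[envs[i], envs[j]]
                assert ks.kernels["gW"][i, j] == pytest.approx(expect)

    def test_identity_h_gives_repeat_indicator(self):
        H = pd.DataFrame(np.eye(3), index=["g1", "g2", "g3"],
                         columns=["g1", "g2", "g3"])
        ks = build_kernels(toy_design(), H)
        Kg = ks.kernels["g"]
        assert Kg[0, 1] == 1.0      # same genotype g1 twice
        assert Kg[0, 2] == 0.0

    def test_unknown_label_named(self):
        d = ModelDesign(genotype=pd.Series(["gX"]),
                        environment=pd.Series(["e1"]))
        with pytest.raises(ValueError, match="gX"):
            build_kernels(d, toy_H())


@pytest.fixture(scope="module")
def fitted_small(small_dataset):
    ds = small_dataset
    design = ModelDesign.from_frame(ds.phenotypes)
    ks = build_kernels(design, ds.H, ds.Omega)
    model = fit_model(ds.phenotypes["value"].to_numpy(), ks, "RNMDs",
                      McmcSettings(iterations=1500, burn_in=400, thin=2,
                                   seed=13))
    return ds, ks, model


class TestFitModel:
    def test_gibbs_matches_closed_form_mixed_model(self, small_dataset):
        """With variances fixed at truth, posterior-mean effects must agree
        with the closed-form multi-kernel BLUP solution."""
        ds = small_dataset
        pheno = ds.phenotypes.iloc[:200].reset_index(drop=True)
        d = ModelDesign.from_frame(pheno)
        ks = build_kernels(d, ds.H, ds.Omega)
        y = pheno["value"].to_numpy()
        tv = ds.truth["variances"]
        fixed = {"E": tv["E"], "g": tv["g"], "eps": tv["eps"]}
        m = fit_model(y, ks, "MM",
                      McmcSettings(iterations=5000, burn_in=1000, thin=2,
                                   seed=5), fixed_variances=fixed)
        n = len(y)
        C = (fixed["E"] * ks.kernels["E"] + fixed["g"] * ks.kernels["g"]
             + fixed["eps"] * np.eye(n))
        Ci = np.linalg.inv(C)
        one = np.ones(n)
        mu = (one @ Ci @ y) / (one @ Ci @ one)
        for name in ("E", "g"):
            oracle = fixed[name] * ks.kernels[name] @ Ci @ (y - mu)
            assert np.corrcoef(m.effects[name], oracle)[0, 1] >= 0.99

    def test_constant_response_degenerates_gracefully(self):
        d = toy_design()
        ks = build_kernels(d, toy_H(), toy_Omega())
        y = np.full(4, 7.0)
        m = fit_model(y, ks, "MM", McmcSettings(800, 200, 2, seed=1))
        assert np.max(np.abs(m.fitted - 7.0)) < 0.05
        assert all(v > 0 for v in m.variances.values())

    def test_null_reaction_norm_component_shrinks(self, medium_dataset):
        """Data carrying no reaction-norm signal should leave the fitted
        gW variance a small share of the total (identification improves
        with n; ~2000 observations are needed to pin it below 5%)."""
        ds = medium_dataset
        fracs = []
        for seed in range(5):
            cfg = ds.config.with_(seed=100 + seed, variance_fractions={
                "E": 0.35, "g": 0.35, "gE": 0.0, "gW": 0.0, "eps": 0.30})
            pheno, _ = simulate_phenotypes(ds.design, ds.H, ds.Omega, cfg)
            d = ModelDesign.from_frame(pheno)
            ks = build_kernels(d, ds.H, ds.Omega)
            m = fit_model(pheno["value"].to_numpy(), ks, "RNMM",
                          McmcSettings(2000, 500, 2, seed=seed))
            fracs.append(extract_variance_components(m)["gW"] / 100.0)
        assert np.median(fracs) < 0.05

    def test_chain_reproducible_under_seed(self, fitted_small):
        ds, ks, model = fitted_small
        again = fit_model(ds.phenotypes["value"].to_numpy(), ks, "RNMDs",
                          McmcSettings(iterations=1500, burn_in=400, thin=2,
                                       seed=13))
        assert again.mu == model.mu
        for c in model.effects:
            assert np.array_equal(again.effects[c], model.effects[c])

    def test_fitted_plus_residual_reproduces_y(self, fitted_small):
        ds, _, model = fitted_small
        y = ds.phenotypes["value"].to_numpy()
        assert np.max(np.abs(model.residual_mean - (y - model.fitted))) < 1e-8

    def test_variance_draws_positive(self, fitted_small):
        _, _, model = fitted_small
        for name, chain in model.chains.items():
            if name != "mu":
                assert (chain > 0).all()


class TestVarianceComponents:
    def test_percentages_sum_to_100(self, fitted_small):
        _, _, model = fitted_small
        assert extract_variance_components(model).sum() == \
            pytest.approx(100.0, abs=1e-9)

    def test_mm_has_no_interaction_rows(self, small_dataset):
        ds = small_dataset
        pheno = ds.phenotypes.iloc[:150].reset_index(drop=True)
        d = ModelDesign.from_frame(pheno)
        ks = build_kernels(d, ds.H)
        m = fit_model(pheno["value"].to_numpy(), ks, "MM",
                      McmcSettings(600, 150, 2, seed=2))
        comps = extract_variance_components(m)
        assert set(comps.index) == {"E", "g", "eps"}


class TestPredict:
    def test_mm_identical_across_new_environments(self, fitted_small):
        ds, ks, _ = fitted_small
        pheno = ds.phenotypes.iloc[:150].reset_index(drop=True)
        d = ModelDesign.from_frame(pheno)
        m = fit_model(pheno["value"].to_numpy(), build_kernels(d, ds.H),
                      "MM", McmcSettings(600, 150, 2, seed=3))
        new = ModelDesign(genotype=pd.Series([ds.H.index[0]] * 3),
                          environment=pd.Series(["N1", "N2", "N3"]))
        p = predict(m, new, ds.H)
        assert p["predicted"].nunique() == 1

    def test_unrelated_genotype_predicted_at_intercept(self, fitted_small):
        ds, _, model = fitted_small
        H = ds.H.copy()
        H.loc["stranger", :] = 0.0
        H.loc[:, "stranger"] = 0.0
        H.loc["stranger", "stranger"] = 1.0
        new = ModelDesign(genotype=pd.Series(["stranger"]),
                          environment=pd.Series(["NEW"]))
        Omega_joint = ds.Omega.copy()
        Omega_joint.loc["NEW", :] = 0.0
        Omega_joint.loc[:, "NEW"] = 0.0
        Omega_joint.loc["NEW", "NEW"] = 1.0
        p = predict(model, new, H, Omega_joint)
        assert p["predicted"].iloc[0] == pytest.approx(model.mu)

    def test_duplicated_ec_row_reproduces_training_environment(
            self, small_dataset):
        """A new environment with an EC row identical to a training
        environment has identical kernel cross-rows, so its reaction-norm
        contribution equals the in-sample one."""
        ds = small_dataset
        pheno = ds.phenotypes.iloc[:200].reset_index(drop=True)
        d = ModelDesign.from_frame(pheno)
        ks = build_kernels(d, ds.H, ds.Omega)
        m = fit_model(pheno["value"].to_numpy(), ks, "RNMM",
                      McmcSettings(800, 200, 2, seed=4))
        env0 = pheno["environment"].iloc[0]
        geno0 = pheno["genotype"].iloc[0]
        Omega_joint = ds.Omega.copy()
        Omega_joint.loc["DUP", :] = Omega_joint.loc[env0, :]
        Omega_joint["DUP"] = Omega_joint[env0]
        Omega_joint.loc["DUP", "DUP"] = 1.0
        Omega_joint.loc[env0, "DUP"] = Omega_joint.loc["DUP", env0] = 1.0
        both = ModelDesign(genotype=pd.Series([geno0, geno0]),
                           environment=pd.Series([env0, "DUP"]))
        p = predict(m, both, ds.H, Omega_joint)
        gw_only = p["predicted"].iloc[1] - m.mu
        # rebuild the in-sample gW contribution explicitly
        from gxepred.models import prediction_coefficients
        coef = prediction_coefficients(m, ds.H, ds.Omega)
        Hc = ds.H.loc[[geno0], list(d.genotype)].to_numpy()
        Oc = ds.Omega.loc[[env0], list(d.environment)].to_numpy()
        in_sample_gw = m.variances["gW"] * ((Hc * Oc) @ coef).item()
        w_term = m.variances["W"] * (Oc @ coef).item()
        g_term = m.variances["g"] * (Hc @ coef).item()
        assert gw_only == pytest.approx(g_term + w_term + in_sample_gw,
                                        abs=1e-8)


class TestBivariate:
    @staticmethod
    def _simulate_pair(ds, rho_g, rho_e, seed, n_obs=None):
        rng = np.random.default_rng(seed)
        genos = list(ds.H.index)
        design = ds.design if n_obs is None else \
            ds.design.iloc[:n_obs].reset_index(drop=True)
        envs = design["environment"].unique()
        Lh = np.linalg.cholesky(ds.H.to_numpy()
                                + 1e-8 * np.eye(len(genos)))
        Cg = np.array([[1.0, rho_g], [rho_g, 1.0]])
        Ce = np.array([[1.0, rho_e], [rho_e, 1.0]])
        G = Lh @ rng.standard_normal((len(genos), 2)) @ \
            np.linalg.cholesky(Cg).T
        E = rng.standard_normal((len(envs), 2)) @ np.linalg.cholesky(Ce).T
        gmap = {g: i for i, g in enumerate(genos)}
        emap = {e: i for i, e in enumerate(envs)}
        rows = []
        for rec in design.itertuples(index=False):
            gi, ei = gmap[rec.genotype], emap[rec.environment]
            base = G[gi] + E[ei] + 0.4 * rng.standard_normal(2)
            for t, trait in enumerate(("t1", "t2")):
                rows.append((rec.genotype, rec.environment, trait, base[t]))
        return pd.DataFrame(rows, columns=["genotype", "environment",
                                           "trait", "value"])

    def test_duplicated_trait_perfect_correlations(self, medium_dataset):
        ds = medium_dataset
        pheno = ds.phenotypes.iloc[:800].copy()
        a = pheno.assign(trait="t1")
        b = pheno.assign(trait="t2")
        fit = fit_bivariate_trait_model(
            pd.concat([a, b], ignore_index=True), ds.H,
            McmcSettings(2000, 800, 2, seed=6))
        assert fit.genetic_correlation >= 0.99
        assert fit.environmental_correlation >= 0.99

    def test_recovers_planted_correlations(self, medium_dataset):
        ds = medium_dataset
        pheno = self._simulate_pair(ds, rho_g=0.7, rho_e=-0.4, seed=8,
                                    n_obs=1500)
        fit = fit_bivariate_trait_model(
            pheno, ds.H, McmcSettings(4000, 1500, 2, seed=8))
        assert fit.genetic_correlation == pytest.approx(0.7, abs=0.15)
        assert fit.environmental_correlation == pytest.approx(-0.4, abs=0.15)

    def test_independent_traits_near_zero(self, medium_dataset):
        ds = medium_dataset
        gcs, ecs = [], []
        for seed in range(5):
            pheno = self._simulate_pair(ds, 0.0, 0.0, seed=20 + seed,
                                        n_obs=1000)
            fit = fit_bivariate_trait_model(
                pheno, ds.H, McmcSettings(1500, 600, 2, seed=seed))
            gcs.append(abs(fit.genetic_correlation))
            ecs.append(abs(fit.environmental_correlation))
        assert np.median(gcs) < 0.2 and np.median(ecs) < 0.2

    def test_zero_variance_trait_rejected(self, small_dataset):
        ds = small_dataset
        pheno = ds.phenotypes.iloc[:100].copy()
        a = pheno.assign(trait="t1")
        b = pheno.assign(trait="t2", value=5.0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_bivariate_trait_model(pd.concat([a, b]), ds.H)
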