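import numpy as np
import pandas as pd
import pytest

from hybridgp.architecture import (
    ConfoundingError,
    degree_of_dominance,
    degree_of_dominance_from_shares,
    fit_dgblup,
    fit_directional,
    fit_enrichment,
    fit_gblup,
    fit_panel_interaction,
    plot_heritability,
    proportion_variance,
    rho_R,
    snp_enrichment,
    variance_partition_report,
)
from hybridgp.genotypes import Kernel, additive_kinship, binned_kinships, dominance_kinship
from hybridgp.panel import HybridPanel
from hybridgp.reml import fit_reml
from hybridgp.simulate import simulate_plot_data


class TestProportionVariance:
    def test_identity_kernel_closed_form(self, rng):
        """Single kernel = I, intercept only, sigma_u = sigma_e:
        share = ((n-1)/n) / ((n-1)/n + 1) exactly."""
        n = 50
        y = rng.normal(size=n)
        fit = fit_reml(y, np.ones((n, 1)), [Kernel("K", np.eye(n), "additive", n)])
        fit.variances["K"] = 1.0
        fit.variances["residual"] = 1.0
        shares = proportion_variance(fit)
        d = (n - 1) / n
        assert shares["K"] == pytest.approx(d / (d + 1), abs=1e-10)

    def test_zero_variance_gives_zero_share(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_gblup(pa, additive_kinship(ms.X))
        fit.variances["G"] = 0.0
        assert proportion_variance(fit)["G"] == 0.0

    def test_shares_sum_to_one(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_dgblup(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
        shares = proportion_variance(fit)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_reciprocal_scaling(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        G = additive_kinship(ms.X)
        fit = fit_gblup(pa, G)
        s1 = proportion_variance(fit)
        G2 = Kernel("G", 4.0 * G.K, "additive", G.m)
        fit2 = fit_gblup(pa, G2)
        fit2.variances["G"] = fit.variances["G"] / 4.0
        fit2.variances["residual"] = fit.variances["residual"]
        s2 = proportion_variance(fit2)
        assert s1["G"] == pytest.approx(s2["G"], abs=1e-6)


class TestSnpEnrichment:
    def test_single_bin_enrichment_is_one(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_gblup(pa, additive_kinship(ms.X))
        assert snp_enrichment(fit)["G"] == pytest.approx(1.0)

    def test_zero_variance_bin_enrichment_zero(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        bins = np.where(np.arange(ms.m) < ms.m // 3, "a", "b")
        ak = binned_kinships(ms.X, bins, tag="additive")
        fit = fit_enrichment(pa, ak)
        fit.variances[ak[0].name] = 0.0
        assert snp_enrichment(fit)[ak[0].name] == 0.0

    def test_snp_weighted_enrichments_average_to_one(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        bins = np.where(np.arange(ms.m) % 3 == 0, "a", "b")
        ak = binned_kinships(ms.X, bins, tag="additive")
        fit = fit_enrichment(pa, ak)
        enr = snp_enrichment(fit)
        total_m = sum(k.m for k in fit.kernels)
        weighted = sum(enr[k.name] * k.m / total_m for k in fit.kernels)
        assert weighted == pytest.approx(1.0, abs=1e-8)

    def test_one_bin_model_matches_gblup_loglik(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit_g = fit_gblup(pa, additive_kinship(ms.X))
        one_bin = binned_kinships(ms.X, np.full(ms.m, "genome"), tag="additive")
        fit_e = fit_enrichment(pa, one_bin)
        assert fit_e.loglik == pytest.approx(fit_g.loglik, abs=1e-6)


class TestDegreeOfDominance:
    def test_worked_share_conversions(self):
        """Printed genomic shares translate to dominance-additive SD ratios."""
        assert round(degree_of_dominance_from_shares(0.65, 0.35), 2) == 0.73
        assert round(degree_of_dominance_from_shares(0.59, 0.41), 2) == 0.83

    def test_equal_shares_give_one(self):
        assert degree_of_dominance_from_shares(0.5, 0.5) == pytest.approx(1.0)

    def test_zero_additive_share_undefined(self):
        with pytest.raises(ValueError):
            degree_of_dominance_from_shares(0.0, 0.5)

    def test_fit_version_consistent_with_shares(self, small_study):
        """Matches an independent recomputation from the partition formula."""
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_dgblup(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
        W = fit.W
        H = W @ np.linalg.solve(W.T @ W, W.T)
        I = np.eye(pa.n)
        dG = np.diag((I - H) @ additive_kinship(ms.X).K @ (I - H))
        dD = np.diag((I - H) @ dominance_kinship(ms.Z).K @ (I - H))
        tot = dG * fit.variances["G"] + dD * fit.variances["D"] + fit.variances["residual"]
        share_g = np.mean(dG * fit.variances["G"] / tot)
        share_d = np.mean(dD * fit.variances["D"] / tot)
        assert degree_of_dominance(fit) == pytest.approx(np.sqrt(share_d / share_g), rel=1e-6)


class TestModelWrappers:
    def test_single_tester_rejects_dominance(self, small_study):
        ms, pa = small_study.markers["nam"], small_study.panels["nam"]
        with pytest.raises(ConfoundingError):
            fit_dgblup(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))

    def test_directional_design_includes_inbreeding_columns(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_directional(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
        assert "F" in fit.fixed_names and "F2" in fit.fixed_names
        assert fit.W.shape[1] == 6  # intercept + 3 PCs + F + F^2

    def test_report_has_all_components(self, small_study):
        ms, pa = small_study.markers["ames"], small_study.panels["ames"]
        fit = fit_dgblup(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
        rep = variance_partition_report(fit)
        assert set(rep["component"]) == {"G", "D", "residual"}
        assert rep["share"].sum() == pytest.approx(1.0, abs=1e-8)


class TestPanelInteraction:
    def test_rho_formula(self):
        assert 3.0 / (3.0 + 1.0) == pytest.approx(0.75)

    def test_interaction_kernel_block_diagonal(self, small_study):
        pall = small_study.panels["all"]
        order = np.argsort(pall.table["panel"].to_numpy(), kind="stable")
        pa = pall.subset(order)
        ms = small_study.markers["all"].subset_hybrids(order)
        G = additive_kinship(ms.X)
        res = fit_panel_interaction(
            pa.g, pa.table["panel"].to_numpy(), pa.pcs, G, max_iter=5
        )
        K_int = [k for k in res.fit.kernels if k.name == "G_panel"][0].K
        labels = pa.table["panel"].to_numpy()
        off_block = K_int[np.ix_(labels == "ames", labels == "nam")]
        assert np.all(off_block == 0.0)

    def test_small_panel_rejected(self, small_study):
        pall = small_study.panels["all"]
        labels = pall.table["panel"].to_numpy().copy()
        labels[:] = "ames"
        labels[:3] = "tiny"
        with pytest.raises(ValueError, match="needs >="):
            fit_panel_interaction(
                pall.g, labels, pall.pcs, additive_kinship(small_study.markers["all"].X)
            )


class TestRhoR:
    def test_identical_and_antithetic(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert rho_R(v, v)[0] == pytest.approx(1.0)
        assert rho_R(v, -v)[0] == pytest.approx(-1.0)

    def test_too_few_common_hybrids(self):
        with pytest.raises(ValueError):
            rho_R([1.0, 2.0], [2.0, 1.0])

    def test_monte_carlo_mean_correlation(self, rng):
        target = 0.65
        rs = []
        cov = np.array([[1.0, target], [target, 1.0]])
        L = np.linalg.cholesky(cov)
        for _ in range(1000):
            xy = rng.normal(size=(23, 2)) @ L.T
            rs.append(rho_R(xy[:, 0], xy[:, 1])[0])
        assert abs(np.mean(rs) - target) < 0.03


class TestPlotHeritability:
    def test_zero_error_gives_h2_one(self, rng):
        g = rng.normal(size=40)
        plots = simulate_plot_data(g, n_envs=3, env_variance=0.5, error_variance=0.0, seed=3)
        res = plot_heritability(plots)
        assert res.H2 == pytest.approx(1.0, abs=1e-3)
        assert res.reliability == pytest.approx(1.0, abs=5e-3)

    def test_balanced_reliability_closed_form(self, rng):
        """sigma_g = sigma_e = 1 with r environments: r_g^2 ~ r/(r+1)."""
        r_env = 4
        g = rng.normal(size=150)
        plots = simulate_plot_data(g, n_envs=r_env, env_variance=0.3, error_variance=1.0, seed=5)
        res = plot_heritability(plots)
        assert res.reliability == pytest.approx(r_env / (r_env + 1), abs=0.08)
        assert res.H2 == pytest.approx(0.5, abs=0.1)

    def test_genotype_means_close_to_truth(self, rng):
        g = rng.normal(size=30)
        plots = simulate_plot_data(g, n_envs=4, env_variance=0.2, error_variance=0.05, seed=9)
        res = plot_heritability(plots)
        means = res.genotype_means.to_numpy()
        assert np.corrcoef(means, g)[0, 1] > 0.99

    def test_single_environment_errors(self, rng):
        plots = pd.DataFrame({"genotype": ["a", "b"], "env": ["e1", "e1"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="confounded"):
            plot_heritability(plots)
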