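"""Reproducible simulation experiments exercising the whole pipeline.

Each function runs a self-contained Monte-Carlo experiment at the package's
study conditions and returns summary statistics with known targets:
parameter recovery for the additive+dominance model, per-bin enrichment
recovery, directional-inbreeding inference, genotype-by-panel interaction
recovery, and GWAS null calibration.  They are used by the test suite and
by the acceptance script; sizes are desk-scale (hundreds of hybrids, a few
thousand SNPs) so a full sweep runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .architecture import (
    fit_dgblup,
    fit_directional,
    fit_enrichment,
    fit_panel_interaction,
    genomic_variances,
    per_snp_variance_fold,
)
from .genotypes import additive_kinship, binned_kinships, dominance_kinship
from .gwas import emmax_scan
from .reml import fit_reml, wald_test
from .simulate import SimulationConfig, simulate_phenotypes, simulate_study

DGBLUP_TARGETS = {"additive": 1.0, "dominance": 0.5, "residual": 1.0}


def dgblup_recovery(base_seed: int = 0, n_rep: int = 20, m_snps: int = 5000) -> dict:
    """Recovery of additive, dominance and residual variances by DGBLUP.

    Two-tester diversity panels (~500 hybrids) are simulated with component
    variances 1.0 / 0.5 / 1.0 on the phenotypic-contribution scale; each
    replicate is fitted and the estimated contribution of every component
    (sigma_c^2 times the mean adjusted kernel diagonal) is compared with its
    target.  Returns mean estimates and mean relative bias per component.
    """
    est = []
    for r in range(n_rep):
        cfg = SimulationConfig(
            seed=base_seed + r,
            n_founders=252,
            m_snps=m_snps,
            variance_spec={"additive": 1.0, "dominance": 0.5, "structure": 0.3, "residual": 1.0},
        )
        st = simulate_study(cfg, panels=("ames",))
        ms, pa = st.markers["ames"], st.panels["ames"]
        fit = fit_dgblup(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
        gv = genomic_variances(fit)
        est.append([gv["G"], gv["D"], gv["residual"]])
    est = np.asarray(est)
    means = est.mean(axis=0)
    targets = np.array([1.0, 0.5, 1.0])
    return {
        "n_rep": n_rep,
        "n": 2 * (252 - 2),
        "mean_additive": float(means[0]),
        "mean_dominance": float(means[1]),
        "mean_residual": float(means[2]),
        "rel_bias": dict(zip(("additive", "dominance", "residual"), (means / targets - 1.0))),
        "max_abs_rel_bias": float(np.max(np.abs(means / targets - 1.0))),
    }


def reml_profile_grid(y, W, K, resolution: float = 1e-4):
    """Brute-force oracle: grid search of the restricted likelihood.

    The model has one kernel plus residual; parameterized by the variance
    ratio h = s_u^2 / (s_u^2 + s_e^2), the total variance profiles out in
    closed form, so a 1-D grid over h locates the REML optimum.
    Returns (h_hat, profiled restricted log-likelihood at h_hat).
    """
    y = np.asarray(y, float)
    W = np.asarray(W, float)
    n, p = W.shape
    hs = np.arange(0.0, 1.0, resolution)
    best = (-np.inf, 0.0)
    I = np.eye(n)
    for h in hs:
        V0 = h * K + (1 - h) * I
        try:
            cho = cho_factor(V0, lower=True)
        except np.linalg.LinAlgError:
            continue
        logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ViW = cho_solve(cho, W)
        Viy = cho_solve(cho, y)
        WtViW = W.T @ ViW
        sign, logdet_w = np.linalg.slogdet(WtViW)
        beta = np.linalg.solve(WtViW, W.T @ Viy)
        ypy = float(y @ Viy - (W.T @ Viy) @ beta)
        if ypy <= 0:
            continue
        tau = ypy / (n - p)
        rll = -0.5 * (logdet_v + logdet_w + (n - p) * np.log(tau) + (n - p))
        if rll > best[0]:
            best = (rll, h)
    return best[1], best[0]


def reml_grid_check(base_seed: int = 0, n_rep: int = 5, n: int = 20) -> dict:
    """Compare fit_reml to the grid-search oracle on tiny one-kernel problems."""
    diffs = []
    rng = np.random.default_rng(base_seed)
    for _ in range(n_rep):
        Xg = rng.integers(0, 3, size=(n, 50)).astype(float)
        K = (Xg @ Xg.T) / Xg.shape[1]
        K /= np.trace(K) / n  # unit average diagonal keeps h interpretable
        W = np.ones((n, 1))
        h_true = 0.5
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = (L @ rng.normal(size=n)) * np.sqrt(h_true) + rng.normal(size=n) * np.sqrt(1 - h_true)
        kern = additive_kinship(Xg)
        kern.K = K
        fit = fit_reml(y, W, [kern])
        su, se = fit.variances[kern.name], fit.variances["residual"]
        h_fit = su / (su + se) if su + se > 0 else 0.0
        h_grid, _ = reml_profile_grid(y, W, K)
        diffs.append(abs(h_fit - h_grid))
    return {"n_rep": n_rep, "n": n, "max_ratio_diff": float(np.max(diffs))}


def enrichment_recovery(
    base_seed: int = 0, n_rep: int = 20, m_snps: int = 5000, fold: float = 10.0
) -> dict:
    """Recovery of a per-SNP variance fold between two genomic bins.

    NAM-like panels (single tester, additive model) with a high-reliability
    trait (residual 0.15); the enriched bin is a contiguous fifth of the
    genome (two of ten chromosomes), whose bin kernel is distinguishable at
    desk scale thanks to family linkage.  Each replicate fits the per-bin
    variance model and records the estimated per-SNP variance ratio between
    bins, under the 10x architecture and under a uniform (null) one.
    """
    vs = {"additive": 1.0, "dominance": 0.0, "structure": 0.3, "residual": 0.15}
    sig, nul = [], []
    n_used = None
    for r in range(n_rep):
        cfg = SimulationConfig(seed=base_seed + r, n_founders=252, m_snps=m_snps, variance_spec=vs)
        st = simulate_study(cfg, panels=("nam",))
        ms, pa = st.markers["nam"], st.panels["nam"]
        n_used = pa.n
        chrom = ms.snps["chrom"].to_numpy().astype(int)
        bins = np.where(chrom <= 2, "hot", "cold")
        ak = binned_kinships(ms.X, bins, tag="additive", prefix="G:")
        for target, out in ((fold, sig), (None, nul)):
            cfg2 = SimulationConfig(
                seed=base_seed + r,
                n_founders=252,
                m_snps=m_snps,
                variance_spec=vs,
                enrichment_spec=({"hot": target} if target else {}),
            )
            g, _ = simulate_phenotypes(pa, ms, cfg2, bins=bins if target else None)
            pa2 = pa.subset(np.arange(pa.n))
            pa2.g = g
            fit = fit_enrichment(pa2, ak, [])
            f = per_snp_variance_fold(fit)
            out.append(f["G:hot"] / f["G:cold"] if f["G:cold"] > 0 else np.inf)
    return {
        "n_rep": n_rep,
        "n": n_used,
        "median_fold_ratio": float(np.median(sig)),
        "null_median_fold_ratio": float(np.median(nul)),
    }


def directional_experiment(base_seed: int = 0, n_rep: int = 20, m_snps: int = 2000) -> dict:
    """Coverage and power for directional genomic-inbreeding effects.

    Arm one simulates a linear inbreeding effect tau1 = -0.5 (tau2 = 0) and
    counts 95% Wald confidence intervals covering the truth; arm two
    simulates a purely quadratic effect tau2 = -4 (strong inbreeding
    depression curvature on a high-reliability trait) and counts rejections
    of the quadratic Wald test at alpha = 0.05.
    """
    vs = {"additive": 1.0, "dominance": 0.5, "structure": 0.3, "residual": 0.2}
    cover = 0
    reject = 0
    tau1_true, tau2_true = -0.5, -4.0
    n_used = None
    for r in range(n_rep):
        for arm, taus in (("linear", (tau1_true, 0.0)), ("quadratic", (0.0, tau2_true))):
            cfg = SimulationConfig(
                seed=base_seed + r,
                n_founders=252,
                m_snps=m_snps,
                variance_spec=vs,
                inbreeding_effects=taus,
            )
            st = simulate_study(cfg, panels=("ames",))
            ms, pa = st.markers["ames"], st.panels["ames"]
            n_used = pa.n
            fit = fit_directional(pa, additive_kinship(ms.X), dominance_kinship(ms.Z))
            if arm == "linear":
                i = fit.fixed_names.index("F")
                se = float(np.sqrt(fit.beta_cov[i, i]))
                cover += int(abs(fit.beta[i] - tau1_true) <= 1.96 * se)
            else:
                _, p = wald_test(fit, [fit.fixed_names.index("F2")])
                reject += int(p < 0.05)
    return {
        "n_rep": n_rep,
        "n": n_used,
        "tau1": tau1_true,
        "tau2": tau2_true,
        "ci_coverage": cover,
        "quadratic_rejections": reject,
    }


def interaction_experiment(base_seed: int = 0, n_rep: int = 20, m_snps: int = 2000) -> dict:
    """Recovery of the across-panel genetic correlation rho_G.

    Joint two-panel studies (~470 hybrids) are simulated with no
    panel-specific variance (rho_G = 1) and with panel-specific variance
    equal to the main variance (rho_G = 0.5); the two-kernel model
    G / G o EE' is fitted jointly and rho_G recorded.
    """
    shared = {"additive": 1.0, "dominance": 0.0, "structure": 0.3, "residual": 0.5}
    rho_null, rho_mixed = [], []
    n_used = None
    for r in range(n_rep):
        for s_panel, out in ((0.0, rho_null), (1.0, rho_mixed)):
            vs = dict(shared, panel=s_panel)
            cfg = SimulationConfig(
                seed=base_seed + r,
                n_founders=62,
                m_snps=m_snps,
                n_ril_populations=4,
                rils_per_population=55,
                variance_spec=vs,
            )
            st = simulate_study(cfg)
            pall = st.panels["all"]
            n_used = pall.n
            res = fit_panel_interaction(
                pall.g,
                pall.table["panel"].to_numpy(),
                pall.pcs,
                additive_kinship(st.markers["all"].X),
            )
            out.append(res.rho_g)
    rho_null = np.asarray(rho_null)
    return {
        "n_rep": n_rep,
        "n": n_used,
        "fraction_null_ge_090": float(np.mean(rho_null >= 0.9)),
        "mean_rho_mixed": float(np.mean(rho_mixed)),
    }


def gwas_null_calibration(seed: int = 0, m_snps: int = 5000) -> dict:
    """Kolmogorov-Smirnov uniformity of EMMAX p-values on a permuted trait.

    Each test is exactly calibrated given an i.i.d. trait, but the KS
    uniformity check additionally needs the 5,000 p-values to be close to
    independent, so the study conditions remove every source of shared
    structure among the SNP columns: no population or family structure
    (independent founders), a single tester (each female appears in one
    hybrid — two testers pair the hybrids and the pair contrasts become
    common factors across all tests), and a pure-noise trait (the
    permutation null of a trait carrying genetic covariance is
    exchangeable but slightly non-Gaussian, which the highest-leverage
    SNPs detect at this many tests).
    """
    cfg = SimulationConfig(
        seed=seed,
        n_founders=502,
        m_snps=m_snps,
        testers=1,
        divergence=0.0,
        family_divergence=0.0,
        variance_spec={"additive": 0.0, "dominance": 0.0, "structure": 0.0, "residual": 1.0},
    )
    st = simulate_study(cfg, panels=("ames",))
    ms, pa = st.markers["ames"], st.panels["ames"]
    rng = np.random.default_rng(seed + 7)
    g_perm = rng.permutation(pa.g)
    res = emmax_scan(g_perm, pa.q_design(), ms, [additive_kinship(ms.X)])
    p = res.table["p_beta"].dropna().to_numpy()
    ks = stats.kstest(p, "uniform")
    return {"n": len(p), "ks_p": float(ks.pvalue)}
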