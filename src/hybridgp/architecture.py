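"""Named genomic models and derived genetic-architecture statistics.

The models assembled here all share the fixed design ``Q = [1 P]``
(intercept plus three population PCs) and differ in their random terms:

* GBLUP:        g = Q d + u + e,           u ~ N(0, G s_u^2)
* DGBLUP:       g = Q d + u + w + e,       w ~ N(0, D s_w^2)
* directional:  g = Q d + R t + u + w + e, R = [F F^2] genomic inbreeding
* enrichment:   u ~ N(0, sum_k G_k s_k^2), w ~ N(0, sum_l D_l s_l^2)
                with per-bin kernels from a functional-feature partition
* genotype-by-panel: u ~ N(0, G s_0^2 + [G o EE'] s_1^2)

Variance partitions use kernels adjusted for the fixed design,
``K~ = (I - H) K (I - H)`` with ``H = W (W'W)^-1 W'``, so that the reported
genomic-heritability shares refer to variation orthogonal to the fixed
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Kernel
from .panel import HybridPanel, panel_design
from .reml import VarianceComponentFit, fit_reml

__all__ = [
    "ConfoundingError",
    "fit_gblup",
    "fit_dgblup",
    "fit_directional",
    "fit_enrichment",
    "proportion_variance",
    "snp_enrichment",
    "degree_of_dominance",
    "degree_of_dominance_from_shares",
    "fit_panel_interaction",
    "rho_R",
    "plot_heritability",
    "variance_partition_report",
]


class ConfoundingError(ValueError):
    """Dominance requested on a single-tester panel, where additive and
    dominance effects are statistically equivalent (two genotype classes)."""


def _design(panel: HybridPanel, extra: np.ndarray | None = None, extra_names=()):
    W = panel.q_design()
    names = ["intercept"] + [f"pc{i+1}" for i in range(W.shape[1] - 1)]
    if extra is not None:
        W = np.column_stack([W, extra])
        names += list(extra_names)
    return W, names


def _reject_dominance(panel: HybridPanel, kernels) -> None:
    if panel.n_testers < 2 and any(k.tag == "dominance" for k in kernels):
        raise ConfoundingError(
            "dominance kernels are confounded with additive kernels on a "
            "single-tester panel; drop them or add a second tester"
        )


def fit_gblup(panel: HybridPanel, G: Kernel, **kwargs) -> VarianceComponentFit:
    """Polygenic additive model: g = Q d + u + e."""
    W, names = _design(panel)
    return fit_reml(panel.g, W, [G], fixed_names=names, **kwargs)


def fit_dgblup(panel: HybridPanel, G: Kernel, D: Kernel, **kwargs) -> VarianceComponentFit:
    """Additive + dominance model; requires a two-tester panel."""
    _reject_dominance(panel, [D])
    W, names = _design(panel)
    return fit_reml(panel.g, W, [G, D], fixed_names=names, **kwargs)


def fit_directional(
    panel: HybridPanel,
    G: Kernel,
    D: Kernel | None = None,
    center_f: bool = False,
    **kwargs,
) -> VarianceComponentFit:
    """DGBLUP extended with fixed linear and quadratic genomic-inbreeding effects.

    The coefficients on ``F`` and ``F^2`` measure directional dominance and
    its curvature (dominance x dominance epistasis).  ``center_f`` subtracts
    the panel-mean F before squaring.
    """
    if panel.F is None:
        raise ValueError("panel has no genomic inbreeding coefficients")
    kernels = [G] if D is None else [G, D]
    _reject_dominance(panel, kernels)
    F = panel.F - panel.F.mean() if center_f else panel.F
    R = np.column_stack([F, F**2])
    W, names = _design(panel, R, ["F", "F2"])
    return fit_reml(panel.g, W, kernels, fixed_names=names, **kwargs)


def fit_enrichment(
    panel: HybridPanel,
    additive_kernels: list[Kernel],
    dominance_kernels: list[Kernel] = (),
    **kwargs,
) -> VarianceComponentFit:
    """Functional-enrichment model with per-bin variance components."""
    dominance_kernels = list(dominance_kernels)
    _reject_dominance(panel, dominance_kernels)
    W, names = _design(panel)
    return fit_reml(
        panel.g, W, list(additive_kernels) + dominance_kernels, fixed_names=names, **kwargs
    )


# ------------------------------------------------- variance partitions


def _adjusted_diag_means(fit: VarianceComponentFit) -> dict[str, float]:
    """Mean diagonal of each kernel adjusted for the fixed design."""
    W = fit.W
    H = W @ np.linalg.solve(W.T @ W, W.T)
    n = fit.n
    out = {}
    for k in fit.kernels:
        IH_K = k.K - H @ k.K
        K_adj = IH_K - IH_K @ H
        out[k.name] = float(np.trace(K_adj)) / n
    return out


def genomic_variances(fit: VarianceComponentFit) -> dict[str, float]:
    """Estimated phenotypic-scale variance contributed by each kernel.

    ``sigma_c^2 * mean(diag K~_c)`` with the projection-adjusted kernel:
    the variance a component contributes orthogonally to the fixed design,
    directly comparable to a simulator's component-variance targets.  The
    residual variance is included unadjusted.
    """
    diag_means = _adjusted_diag_means(fit)
    out = {
        k.name: max(diag_means[k.name], 0.0) * fit.variances[k.name] for k in fit.kernels
    }
    out["residual"] = fit.variances["residual"]
    return out


def proportion_variance(fit: VarianceComponentFit) -> dict[str, float]:
    """Per-component shares of phenotypic variance (genomic heritabilities).

    Each kernel is adjusted for the fixed design, ``K~ = (I-H) K (I-H)``, and
    the share of component c is the average over individuals of
    ``K~_c,ii s_c^2 / (sum_d K~_d,ii s_d^2 + s_e^2)``.  The residual share is
    reported under ``"residual"``; all shares sum to 1.
    """
    W = fit.W
    H = W @ np.linalg.solve(W.T @ W, W.T)
    diags = {}
    for k in fit.kernels:
        IH_K = k.K - H @ k.K
        diags[k.name] = np.einsum("ij,ji->i", IH_K, np.eye(fit.n) - H)
    total = fit.variances["residual"] * np.ones(fit.n)
    for name, d in diags.items():
        total = total + np.clip(d, 0.0, None) * fit.variances[name]
    shares = {
        name: float(np.mean(np.clip(d, 0.0, None) * fit.variances[name] / total))
        for name, d in diags.items()
    }
    shares["residual"] = float(np.mean(fit.variances["residual"] / total))
    return shares


def snp_enrichment(fit: VarianceComponentFit) -> dict[str, float]:
    """Fold enrichment of genomic variance per bin kernel.

    For bin k*: the proportion of *genomic* (non-residual) variance explained
    by that bin, over its proportion of SNP effects m_k* / sum(m).  Computed
    from projection-adjusted kernels; a weighted average of the enrichments
    over bins (weights = SNP shares) is 1 by construction.
    """
    diag_means = _adjusted_diag_means(fit)
    genomic = {
        k.name: max(diag_means[k.name], 0.0) * fit.variances[k.name] for k in fit.kernels
    }
    total_var = sum(genomic.values())
    total_m = sum(k.m for k in fit.kernels)
    out = {}
    for k in fit.kernels:
        var_share = genomic[k.name] / total_var if total_var > 0 else 0.0
        snp_share = k.m / total_m
        out[k.name] = var_share / snp_share
    return out


def per_snp_variance_fold(fit: VarianceComponentFit, tag: str = "additive") -> dict[str, float]:
    """Estimated per-SNP effect-variance fold per bin, for kernels of one tag.

    Under the per-bin model the effect variance of a SNP in bin k is
    ``sigma_k^2 / m_k``; the fold is that quantity over its SNP-weighted
    average across bins, so a uniform architecture has fold 1 everywhere and
    the ratio of two bins' folds estimates their per-SNP variance ratio.
    """
    kernels = [k for k in fit.kernels if k.tag == tag]
    if not kernels:
        raise ValueError(f"no kernels with tag {tag!r}")
    per_snp = {k.name: fit.variances[k.name] / k.m for k in kernels}
    total_m = sum(k.m for k in kernels)
    avg = sum(fit.variances[k.name] for k in kernels) / total_m
    if avg <= 0:
        return {k.name: np.nan for k in kernels}
    return {name: v / avg for name, v in per_snp.items()}


def degree_of_dominance_from_shares(additive_share: float, dominance_share: float) -> float:
    """Ratio of dominance-to-additive SD from genomic-variance shares.

    The shares are renormalized to the genomic (non-residual) total, so e.g.
    a 35%/65% dominance/additive split gives sqrt(0.35/0.65) = 0.73.
    """
    if additive_share <= 0:
        raise ValueError("additive share must be positive")
    return float(np.sqrt(dominance_share / additive_share))


def degree_of_dominance(fit: VarianceComponentFit) -> float:
    """Average degree of dominance from a DGBLUP fit (one kernel per tag).

    The square root of the dominance-to-additive ratio of genomic-variance
    shares (residual cancels), i.e. the ratio of dominance to additive SD of
    genomic values.
    """
    add = [k for k in fit.kernels if k.tag == "additive"]
    dom = [k for k in fit.kernels if k.tag == "dominance"]
    if len(add) != 1 or len(dom) != 1:
        raise ValueError("fit must have exactly one additive and one dominance kernel")
    shares = proportion_variance(fit)
    if shares[add[0].name] <= 0:
        raise ValueError("additive genomic variance is zero; degree of dominance undefined")
    return float(np.sqrt(shares[dom[0].name] / shares[add[0].name]))


def variance_partition_report(
    fit: VarianceComponentFit, baseline: VarianceComponentFit | None = None
) -> pd.DataFrame:
    """Tabular per-component report: variance, share and fold enrichment."""
    shares = proportion_variance(fit)
    enr = snp_enrichment(fit)
    rows = []
    for k in fit.kernels:
        rows.append(
            {
                "component": k.name,
                "tag": k.tag,
                "bin": k.bin_label,
                "m_snps": k.m,
                "variance": fit.variances[k.name],
                "share": shares[k.name],
                "enrichment": enr[k.name],
            }
        )
    rows.append(
        {
            "component": "residual",
            "tag": "residual",
            "bin": "",
            "m_snps": 0,
            "variance": fit.variances["residual"],
            "share": shares["residual"],
            "enrichment": np.nan,
        }
    )
    return pd.DataFrame(rows)


# ------------------------------------------------- genotype-by-panel


@dataclass
class PanelInteractionResult:
    fit: VarianceComponentFit
    sigma0: float  # main polygenic variance, shared across panels
    sigma1: float  # panel-specific polygenic variance
    rho_g: float  # across-panel genetic correlation s0/(s0+s1)


def fit_panel_interaction(
    g: np.ndarray,
    panel_labels: np.ndarray,
    pcs: np.ndarray,
    G: Kernel,
    min_panel_size: int = 10,
    **kwargs,
) -> PanelInteractionResult:
    """Joint two-panel model with main and panel-specific polygenic terms.

    Random effects are u ~ N(0, G s0^2 + [G o EE'] s1^2) with E the one-hot
    panel design and 'o' the Hadamard product; fixed effects are [E P].
    The across-panel genetic correlation is rho_G = s0^2 / (s0^2 + s1^2).
    """
    panel_labels = np.asarray(panel_labels)
    E = panel_design(panel_labels)
    sizes = E.sum(axis=0)
    if np.any(sizes < min_panel_size):
        raise ValueError(f"every panel needs >= {min_panel_size} hybrids, got {sizes}")
    W = np.column_stack([E, pcs])
    K_int = Kernel(
        name="G_panel",
        K=G.K * (E @ E.T),
        tag="additive",
        m=G.m,
        bin_label="panel-specific",
    )
    names = [f"panel_{j}" for j in range(E.shape[1])] + [
        f"pc{i+1}" for i in range(np.asarray(pcs).shape[1])
    ]
    fit = fit_reml(g, W, [G, K_int], fixed_names=names, **kwargs)
    s0 = fit.variances[G.name]
    s1 = fit.variances["G_panel"]
    rho = s0 / (s0 + s1) if (s0 + s1) > 0 else np.nan
    return PanelInteractionResult(fit=fit, sigma0=s0, sigma1=s1, rho_g=float(rho))


def rho_R(means_a: np.ndarray, means_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of genotype means for hybrids common to two panels."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 common hybrids with aligned means")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ------------------------------------------------- plot-level heritability


@dataclass
class PlotHeritability:
    H2: float  # plot-basis broad-sense heritability s_g^2/(s_g^2+s_e^2)
    reliability: float  # average entry-mean reliability r_g^2
    sigma_g2: float
    sigma_env2: float
    sigma_e2: float
    genotype_means: pd.Series


def plot_heritability(
    plots: pd.DataFrame, covariate: str | None = None
) -> PlotHeritability:
    """Heritability, reliability and genotype means from plot records.

    ``plots`` needs columns ``genotype``, ``env`` and ``y`` (one unreplicated
    plot per genotype within each environment): y = g_i + env_j + e_ij with
    i.i.d. random genotype, environment and error terms.  An optional fixed
    covariate column (e.g. flowering time for yield) can be adjusted for.

    H^2 = s_g^2/(s_g^2 + s_e^2); the reliability is one minus the mean
    prediction-error variance of the random genotype effects over s_g^2; the
    genotype means come from the fixed-genotype variant of the same model.
    """
    genos = pd.unique(plots["genotype"])
    envs = pd.unique(plots["env"])
    if len(envs) < 2:
        raise ValueError("genotype and environment are confounded with a single environment")
    y = plots["y"].to_numpy(dtype=float)
    Zg = (plots["genotype"].to_numpy()[:, None] == genos[None, :]).astype(float)
    Ze = (plots["env"].to_numpy()[:, None] == envs[None, :]).astype(float)
    W = np.ones((len(y), 1))
    names = ["intercept"]
    if covariate is not None:
        W = np.column_stack([W, plots[covariate].to_numpy(dtype=float)])
        names.append(covariate)
    Kg = Kernel(name="genotype", K=Zg @ Zg.T, tag="additive", m=Zg.shape[1])
    Ke = Kernel(name="env", K=Ze @ Ze.T, tag="additive", m=Ze.shape[1])
    fit = fit_reml(y, W, [Kg, Ke], fixed_names=names)
    sg, se_env, se = fit.variances["genotype"], fit.variances["env"], fit.variances["residual"]
    H2 = sg / (sg + se) if (sg + se) > 0 else np.nan

    # prediction-error variance of genotype BLUPs: s_g^2 I - s_g^4 Zg' P Zg
    V = sg * Kg.K + se_env * Ke.K + se * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    ViW = Vinv @ fit.W
    P = Vinv - ViW @ np.linalg.solve(fit.W.T @ ViW, ViW.T)
    pev = sg - (sg**2) * np.einsum("ij,jk,ki->i", Zg.T, P, Zg)
    reliability = 1.0 - float(np.mean(pev)) / sg if sg > 0 else np.nan

    # fixed-genotype variant for genotype means
    Wg = Zg if covariate is None else np.column_stack([Zg, plots[covariate].to_numpy(float)])
    fit_fixed = fit_reml(y, Wg, [Ke], fixed_names=list(genos) + ([covariate] if covariate else []))
    means = pd.Series(fit_fixed.beta[: len(genos)], index=genos, name="genotype_mean")
    return PlotHeritability(
        H2=float(H2),
        reliability=float(reliability),
        sigma_g2=float(sg),
        sigma_env2=float(se_env),
        sigma_e2=float(se),
        genotype_means=means,
    )
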