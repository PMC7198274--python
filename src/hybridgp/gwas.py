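"""Single-SNP mixed-model scans (EMMAX), FDR, WPIP windows and QTL selection.

The scan fixes the variance components at their null-model REML estimates
(the EMMAX approximation), whitens the data by ``V^-1/2`` and runs a per-SNP
generalized least-squares regression of the genotype means on
``[Q, x_j]`` (additive) or ``[Q, x_j, z_j]`` (additive + dominance), with
Wald tests per coefficient.  Posterior inclusion probabilities (PIPs) from a
sparse Bayesian model are consumed as input and aggregated into sliding
500-kb windows (WPIP); high-confidence QTL combine an FDR threshold on the
scan with a WPIP threshold and 1-Mb greedy pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Kernel, MarkerSet
from .reml import VarianceComponentFit, fit_reml

__all__ = [
    "GwasResult",
    "emmax_scan",
    "bh_fdr",
    "wpip",
    "snp_max_wpip",
    "select_high_confidence",
]


@dataclass
class GwasResult:
    """Per-SNP scan table, the null fit, and optional window/QTL tables."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, se_beta, p_beta[, theta...]
    null_fit: VarianceComponentFit
    windows: pd.DataFrame | None = None
    qtl: pd.DataFrame | None = None


def _whiten(fit: VarianceComponentFit) -> np.ndarray:
    """V^-1/2 from the null fit's variance components."""
    n = fit.n
    V = fit.variances["residual"] * np.eye(n)
    for k in fit.kernels:
        V += fit.variances[k.name] * k.K
    w, U = np.linalg.eigh(V)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("null covariance is singular")
    return (U / np.sqrt(w)) @ U.T


def emmax_scan(
    g: np.ndarray,
    Q: np.ndarray,
    markers: MarkerSet,
    kernels: list[Kernel],
    include_dominance: bool = False,
    null_fit: VarianceComponentFit | None = None,
) -> GwasResult:
    """EMMAX-approximate single-SNP scan.

    Parameters
    ----------
    g : genotype means.
    Q : fixed design of the null model (intercept + PCs).
    markers : marker set providing X (and Z for the dominance scan).
    kernels : null-model kernels (G alone; G and D for the dominance scan).
    include_dominance : also fit a per-SNP heterozygosity effect theta_j.
    null_fit : optionally reuse an existing null REML fit.

    Collinear SNP columns are flagged with NaN effect and p-value.
    """
    g = np.asarray(g, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if null_fit is None:
        null_fit = fit_reml(g, Q, kernels)
    A = _whiten(null_fit)
    n, p = Q.shape
    yw = A @ g
    Qw = A @ Q
    Qq, _ = np.linalg.qr(Qw)
    yres = yw - Qq @ (Qq.T @ yw)
    yy = float(yres @ yres)
    Xw = A @ markers.X.astype(float)
    Xres = Xw - Qq @ (Qq.T @ Xw)
    tol = 1e-8 * n

    out = {
        "snp_id": markers.snps["snp_id"].to_numpy(),
        "chrom": markers.snps["chrom"].to_numpy(),
        "pos": markers.snps["pos"].to_numpy(),
    }
    if not include_dominance:
        xx = np.einsum("ij,ij->j", Xres, Xres)
        xy = Xres.T @ yres
        ok = xx > tol
        beta = np.where(ok, xy / np.where(ok, xx, 1.0), np.nan)
        rss = yy - np.where(ok, beta**2 * xx, 0.0)
        dof = n - p - 1
        s2 = rss / dof
        se = np.sqrt(np.where(ok, s2 / np.where(ok, xx, 1.0), np.nan))
        tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
        out.update(beta=beta, se_beta=se, p_beta=np.where(ok, pval, np.nan))
    else:
        Zw = A @ markers.Z.astype(float)
        Zres = Zw - Qq @ (Qq.T @ Zw)
        a = np.einsum("ij,ij->j", Xres, Xres)
        b = np.einsum("ij,ij->j", Xres, Zres)
        c = np.einsum("ij,ij->j", Zres, Zres)
        u = Xres.T @ yres
        v = Zres.T @ yres
        det = a * c - b**2
        ok_x = a > tol
        ok_joint = ok_x & (c > tol) & (det > tol * np.maximum(a, c))
        dof = n - p - 2
        beta = np.full(markers.m, np.nan)
        theta = np.full(markers.m, np.nan)
        se_b = np.full(markers.m, np.nan)
        se_t = np.full(markers.m, np.nan)
        p_b = np.full(markers.m, np.nan)
        p_t = np.full(markers.m, np.nan)
        j = ok_joint
        beta[j] = (c[j] * u[j] - b[j] * v[j]) / det[j]
        theta[j] = (a[j] * v[j] - b[j] * u[j]) / det[j]
        rss = yy - beta[j] * u[j] - theta[j] * v[j]
        s2 = np.clip(rss, 0.0, None) / dof
        se_b[j] = np.sqrt(s2 * c[j] / det[j])
        se_t[j] = np.sqrt(s2 * a[j] / det[j])
        p_b[j] = 2.0 * stats.t.sf(np.abs(beta[j] / se_b[j]), dof)
        p_t[j] = 2.0 * stats.t.sf(np.abs(theta[j] / se_t[j]), dof)
        # z collinear (e.g. no heterozygote variation): fall back to additive-only
        j = ok_x & ~ok_joint
        if j.any():
            dof1 = n - p - 1
            beta[j] = u[j] / a[j]
            rss1 = yy - beta[j] * u[j]
            s21 = np.clip(rss1, 0.0, None) / dof1
            se_b[j] = np.sqrt(s21 / a[j])
            p_b[j] = 2.0 * stats.t.sf(np.abs(beta[j] / se_b[j]), dof1)
        out.update(beta=beta, se_beta=se_b, p_beta=p_b, theta=theta, se_theta=se_t, p_theta=p_t)
    return GwasResult(table=pd.DataFrame(out), null_fit=null_fit)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j.

    NaN entries (dropped tests) are ignored in the ranking and returned NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def wpip(
    pips: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    window: int = 500_000,
    step: int = 250_000,
) -> pd.DataFrame:
    """Window posterior inclusion probabilities in sliding windows.

    Windows are anchored at position 0 on each chromosome, half-open
    ``[start, start + window)`` with starts at multiples of ``step``; the
    WPIP of a window is the sum of the PIPs of the SNPs inside it.
    """
    pips = np.asarray(pips, dtype=float)
    if np.any((pips < 0) | (pips > 1)):
        raise ValueError("PIPs must lie in [0, 1]")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    rows = []
    for c in pd.unique(chrom):
        sel = chrom == c
        cp = pos[sel]
        cpip = pips[sel]
        order = np.argsort(cp)
        cp, cpip = cp[order], cpip[order]
        csum = np.concatenate([[0.0], np.cumsum(cpip)])
        max_start = (cp.max() // step) * step
        starts = np.arange(0, max_start + 1, step, dtype=np.int64)
        lo = np.searchsorted(cp, starts, side="left")
        hi = np.searchsorted(cp, starts + window, side="left")
        scores = csum[hi] - csum[lo]
        rows.append(pd.DataFrame({"chrom": c, "start": starts, "wpip": scores}))
    return pd.concat(rows, ignore_index=True)


def snp_max_wpip(
    chrom: np.ndarray, pos: np.ndarray, windows: pd.DataFrame, window: int = 500_000
) -> np.ndarray:
    """For each SNP, the maximum WPIP over all windows covering it."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.zeros(len(pos))
    for c, grp in windows.groupby("chrom"):
        sel = chrom == c
        if not sel.any():
            continue
        starts = grp["start"].to_numpy(dtype=np.int64)
        scores = grp["wpip"].to_numpy(dtype=float)
        best = np.zeros(sel.sum())
        for s, w in zip(starts, scores):
            inside = (pos[sel] >= s) & (pos[sel] < s + window)
            best[inside] = np.maximum(best[inside], w)
        out[sel] = best
    return out


def select_high_confidence(
    table: pd.DataFrame,
    windows: pd.DataFrame,
    p_col: str = "p_beta",
    fdr: float = 0.05,
    wpip_min: float = 0.5,
    min_sep: int = 1_000_000,
    window: int = 500_000,
) -> pd.DataFrame:
    """High-confidence QTL: FDR <= ``fdr``, covering-window WPIP >= ``wpip_min``,
    then greedy pruning of SNPs within ``min_sep`` of a more significant kept
    SNP on the same chromosome (ties broken by lower genomic coordinate).
    """
    tab = table.copy()
    tab["q"] = bh_fdr(tab[p_col].to_numpy())
    tab["max_wpip"] = snp_max_wpip(
        tab["chrom"].to_numpy(), tab["pos"].to_numpy(), windows, window=window
    )
    cand = tab[(tab["q"] <= fdr) & (tab["max_wpip"] >= wpip_min)].copy()
    cand = cand.sort_values([p_col, "chrom", "pos"], kind="stable")
    kept_rows = []
    kept_pos: dict = {}
    for row in cand.itertuples(index=False):
        positions = kept_pos.setdefault(row.chrom, [])
        if any(abs(row.pos - kp) <= min_sep for kp in positions):
            continue
        positions.append(row.pos)
        kept_rows.append(row)
    return pd.DataFrame(kept_rows, columns=list(cand.columns))
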