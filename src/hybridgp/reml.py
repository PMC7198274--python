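"""Multi-kernel REML with GLS fixed effects, Wald/LRT tests and BLUP.

Fits the variance-component model

    y ~ N(W b,  sum_c sigma_c^2 K_c  +  sigma_e^2 I)

by restricted maximum likelihood.  Updates are average-information (AI) steps
with step-halving onto the feasible region and an expectation-maximization
fallback whenever an AI step fails to improve the restricted likelihood;
components driven to zero are clamped there and flagged as boundary
estimates.  Fixed effects are estimated by GLS at the optimum,
``b = (W'V^-1 W)^-1 W'V^-1 y`` with covariance ``(W'V^-1 W)^-1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .genotypes import Kernel

_TOL_LL = 1e-8
_MAX_ITER = 200


class NonPsdKernelError(ValueError):
    """A supplied relationship matrix is asymmetric or not PSD."""


@dataclass
class ModelSpec:
    """Response, fixed design and kernel list for one variance-component model."""

    y: np.ndarray
    W: np.ndarray
    kernels: list[Kernel]
    fixed_names: list[str] = field(default_factory=list)


@dataclass
class VarianceComponentFit:
    """REML estimates plus everything needed for tests and BLUP."""

    variances: dict[str, float]  # kernel names + "residual"
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    loglik: float  # restricted log-likelihood (constant dropped)
    n_iter: int
    converged: bool
    boundary: dict[str, bool]
    trace: list[float] = field(default_factory=list, repr=False)
    # plumbing retained for BLUP / variance partition
    y: np.ndarray = field(default=None, repr=False)
    W: np.ndarray = field(default=None, repr=False)
    kernels: list[Kernel] = field(default_factory=list, repr=False)
    Py: np.ndarray = field(default=None, repr=False)  # V^-1 (y - W beta)

    @property
    def n(self) -> int:
        return len(self.y)

    def kernel_variance(self, name: str) -> float:
        return self.variances[name]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variances": self.variances,
                "beta": self.beta.tolist(),
                "beta_cov": self.beta_cov.tolist(),
                "fixed_names": self.fixed_names,
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "boundary": self.boundary,
                "trace": self.trace,
            },
            indent=2,
        )


def _check_kernel(K: np.ndarray) -> None:
    if not np.allclose(K, K.T, atol=1e-8):
        raise NonPsdKernelError("kernel is not symmetric")
    n = K.shape[0]
    ridge = 1e-8 * max(np.trace(K) / n, 1.0)
    try:
        np.linalg.cholesky(K + ridge * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise NonPsdKernelError("kernel is not positive semidefinite") from exc


def _restricted_loglik(y, W, Ks, s):
    """Restricted log-likelihood and the quantities reused by the updates."""
    n, p = W.shape
    V = s[-1] * np.eye(n)
    for sc, K in zip(s[:-1], Ks):
        V += sc * K
    cho = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViW = cho_solve(cho, W)
    Viy = cho_solve(cho, y)
    WtViW = W.T @ ViW
    cw = cho_factor(WtViW, lower=True)
    logdet_w = 2.0 * np.sum(np.log(np.diag(cw[0])))
    # subtracting log|W'W| makes the value invariant to the fixed-design basis
    _, logdet_ww = np.linalg.slogdet(W.T @ W)
    beta = cho_solve(cw, W.T @ Viy)
    Py = Viy - ViW @ cho_solve(cw, ViW.T @ y)
    rll = -0.5 * (logdet_v + logdet_w - logdet_ww + float(y @ Py))
    return rll, beta, Py, ViW, cw, cho


def _projection(cho, ViW, cw, n):
    Vinv = cho_solve(cho, np.eye(n))
    return Vinv - ViW @ cho_solve(cw, ViW.T)


def fit_reml(
    y: np.ndarray,
    W: np.ndarray,
    kernels: Sequence[Kernel] = (),
    fixed_names: Sequence[str] | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL_LL,
) -> VarianceComponentFit:
    """Fit a multi-kernel variance-component model by REML.

    Parameters
    ----------
    y : response vector (genotype means).
    W : fixed-effect design, full column rank.
    kernels : relationship matrices (:class:`~hybridgp.genotypes.Kernel`);
        the i.i.d. residual is always included implicitly.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n, p = W.shape
    if n != len(y):
        raise ValueError("response and design have different lengths")
    if np.linalg.matrix_rank(W) < p:
        raise ValueError("fixed design is rank deficient")
    if n < p + 2:
        raise ValueError("too few observations for the fixed design")
    kernels = list(kernels)
    names = [k.name for k in kernels]
    if len(set(names)) != len(names):
        raise ValueError("kernel names must be unique")
    for k in kernels:
        if k.K.shape != (n, n):
            raise ValueError(f"kernel {k.name} does not match response length")
        _check_kernel(k.K)
    Ks = [np.asarray(k.K, dtype=float) for k in kernels]
    nk = len(Ks)
    fixed_names = list(fixed_names) if fixed_names is not None else [f"b{j}" for j in range(p)]

    # OLS gives the starting phenotypic variance and handles the no-kernel case
    bols, rss_arr, *_ = np.linalg.lstsq(W, y, rcond=None)
    rss = float(np.sum((y - W @ bols) ** 2))
    vphen = rss / (n - p)

    if nk == 0:
        s = np.array([vphen])
        rll, beta, Py, ViW, cw, cho = _restricted_loglik(y, W, [], s)
        cov = cho_solve(cw, np.eye(p))
        return VarianceComponentFit(
            variances={"residual": float(s[0])},
            beta=beta,
            beta_cov=0.5 * (cov + cov.T),
            fixed_names=fixed_names,
            loglik=rll,
            n_iter=0,
            converged=True,
            boundary={"residual": False},
            trace=[rll],
            y=y,
            W=W,
            kernels=[],
            Py=Py,
        )

    s = np.full(nk + 1, vphen / (nk + 1))
    rll, beta, Py, ViW, cw, cho = _restricted_loglik(y, W, Ks, s)
    trace = [rll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _projection(cho, ViW, cw, n)
        KPy = np.column_stack([K @ Py for K in Ks] + [Py])  # residual kernel = I
        # score: dl/ds_c = -1/2 (tr(P K_c) - y'P K_c P y)
        tr_pk = np.array([float(np.sum(P * K)) for K in Ks] + [float(np.trace(P))])
        ypkpy = Py @ KPy
        score = -0.5 * (tr_pk - ypkpy)
        # components pinned at 0 with no inward pull stay fixed
        free = (s > 0) | (score > 0)
        if not free.any():
            converged = True
            break
        ai = 0.5 * (KPy.T @ P @ KPy)
        af = ai[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(af + 1e-12 * np.eye(free.sum()), score[free])
        except np.linalg.LinAlgError:
            delta = score[free] / np.maximum(np.diag(af), 1e-12)

        def _propose(step):
            s_new = s.copy()
            s_new[free] = np.clip(s[free] + step * delta, 0.0, None)
            return s_new

        def _try_rll(s_try):
            try:
                return _restricted_loglik(y, W, Ks, s_try)
            except np.linalg.LinAlgError:
                return None

        accepted = False
        step = 1.0
        out = None
        for _ in range(25):
            s_try = _propose(step)
            out = _try_rll(s_try)
            if out is not None and out[0] >= rll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM fallback: guaranteed not to decrease the restricted likelihood
            s_try = s.copy()
            for c in range(nk + 1):
                if free[c]:
                    s_try[c] = s[c] + (s[c] ** 2) * (ypkpy[c] - tr_pk[c]) / n
            s_try = np.clip(s_try, 0.0, None)
            out = _try_rll(s_try)
            if out is None:
                converged = True  # cannot improve within the feasible region
                break
        new_rll = out[0]
        if new_rll >= rll:
            s = s_try
            rll, beta, Py, ViW, cw, cho = out
            trace.append(rll)
        delta_ll = trace[-1] - (trace[-2] if len(trace) > 1 else -np.inf)
        if abs(delta_ll) < tol:
            converged = True
            break

    cov = cho_solve(cw, np.eye(p))
    cov = 0.5 * (cov + cov.T)
    variances = {name: float(v) for name, v in zip(names, s[:-1])}
    variances["residual"] = float(s[-1])
    boundary = {name: bool(v <= 0.0) for name, v in zip(names, s[:-1])}
    boundary["residual"] = bool(s[-1] <= 0.0)
    return VarianceComponentFit(
        variances=variances,
        beta=beta,
        beta_cov=cov,
        fixed_names=fixed_names,
        loglik=rll,
        n_iter=it,
        converged=converged,
        boundary=boundary,
        trace=trace,
        y=y,
        W=W,
        kernels=kernels,
        Py=Py,
    )


def fit_spec(spec: ModelSpec, **kwargs) -> VarianceComponentFit:
    return fit_reml(spec.y, spec.W, spec.kernels, fixed_names=spec.fixed_names, **kwargs)


def wald_test(fit: VarianceComponentFit, indices: Sequence[int]) -> tuple[float, float]:
    """Wald chi-square test that the selected fixed effects are jointly zero."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    idx = list(indices)
    b = fit.beta[idx]
    C = fit.beta_cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular covariance of the tested coefficients") from exc
    return stat, float(stats.chi2.sf(stat, df=len(idx)))


def lrt(
    fit_full: VarianceComponentFit,
    fit_reduced: VarianceComponentFit,
    boundary: str = "chi2",
) -> tuple[float, float]:
    """Likelihood-ratio test between nested variance-component models.

    Both fits must share the same fixed design (REML likelihoods are only
    comparable then).  df = difference in number of variance components.
    ``boundary="mixture"`` uses the 1/2-1/2 chi-square mixture appropriate
    when the reduced model pins components at the boundary.
    """
    if fit_full.W.shape != fit_reduced.W.shape or not np.allclose(fit_full.W, fit_reduced.W):
        raise ValueError("fixed designs differ; REML likelihoods are not comparable")
    df = len(fit_full.variances) - len(fit_reduced.variances)
    if df < 0:
        raise ValueError("the full model has fewer components than the reduced model")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    if df == 0:
        return stat, 1.0
    if boundary == "mixture":
        p = 0.5 * stats.chi2.sf(stat, df)
        p += 0.5 * (stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0.0))
    else:
        p = stats.chi2.sf(stat, df)
    return stat, float(min(p, 1.0))


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: -2 sum(log p) ~ chi-square with 2k df."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, df=2 * len(p)))


def blup(
    fit: VarianceComponentFit,
    cross_kernels: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """BLUPs of the random effects for training or new individuals.

    ``cross_kernels`` maps a kernel name to its cross-relationship matrix
    ``C`` (n_new x n_train) built from the same SNP sets and scalings as the
    training kernel (e.g. ``X_new X_train' / m``).  With ``None``, in-sample
    BLUPs ``u_c = sigma_c^2 K_c V^-1 (y - W b)`` are returned.
    """
    out: dict[str, np.ndarray] = {}
    if cross_kernels is None:
        for k in fit.kernels:
            out[k.name] = fit.variances[k.name] * (k.K @ fit.Py)
        return out
    known = {k.name: k for k in fit.kernels}
    for name, C in cross_kernels.items():
        if name not in known:
            raise KeyError(f"no training kernel named {name!r}")
        C = np.asarray(C, dtype=float)
        if C.shape[1] != fit.n:
            raise ValueError(
                f"cross-kernel {name!r} has {C.shape[1]} training columns, expected {fit.n}"
            )
        out[name] = fit.variances[name] * (C @ fit.Py)
    return out


def predict(
    fit: VarianceComponentFit,
    W_new: np.ndarray | None = None,
    cross_kernels: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Fixed part plus summed BLUPs; in-sample when both arguments are None."""
    if W_new is None:
        W_new = fit.W
    pred = np.asarray(W_new, dtype=float) @ fit.beta
    for u in blup(fit, cross_kernels).values():
        pred = pred + u
    return pred
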