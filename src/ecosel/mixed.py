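"""Gaussian linear mixed models with nested random intercepts.

Fits y = X b + sum_k Z_k u_k + e where the grouping factors are strictly
nested (e.g. genotype within population cluster within ecotype), by direct
numerical maximization of the (restricted) log-likelihood over the
variance components on the log scale.  The marginal covariance
V = s2_res I + sum_k s2_k Z_k Z_k' is block diagonal in the outermost
factor, so the likelihood is accumulated block-wise via Cholesky factors.

This deliberately small engine covers the intercept-only variance
decompositions and the all-subsets climate fits; it is not a general
mixed-model interface (no crossed factors, no random slopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

_LOG_LO, _LOG_HI = -30.0, 20.0


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class NestedLMMFit:
    """Fitted nested-intercept mixed model.

    ``variances`` holds one entry per grouping factor (outermost first)
    followed by the residual variance; zero-boundary estimates are
    reported as exact 0.
    """

    variances: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    method: str
    n: int
    p: int
    converged: bool
    boundary: np.ndarray  # which variances hit the zero boundary

    @property
    def sigma2_residual(self) -> float:
        return float(self.variances[-1])


def _encode_groups(groups) -> list[np.ndarray]:
    return [np.asarray(np.unique(g, return_inverse=True)[1]) for g in groups]


def _build_blocks(y, X, codes):
    """Precompute per-block data and factor indicator matrices."""
    top = codes[0]
    blocks = []
    for lev in np.unique(top):
        idx = np.where(top == lev)[0]
        masks = [(codes[k][idx][:, None] == codes[k][idx][None, :]).astype(float)
                 for k in range(len(codes))]
        blocks.append((np.column_stack([X[idx], y[idx]]), masks))
    return blocks


def _block_loglik_parts(blocks, p, variances):
    """Accumulate logdet(V), X'V^-1 X, X'V^-1 y, y'V^-1 y block-wise."""
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for rhs, masks in blocks:
        nb = rhs.shape[0]
        V = np.zeros((nb, nb))
        for s2, M in zip(variances[:-1], masks):
            if s2 > 0:
                V += s2 * M
        V[np.diag_indices(nb)] += variances[-1]
        L = scipy.linalg.cholesky(V, lower=True)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        sol = scipy.linalg.solve_triangular(L, rhs, lower=True)
        Xs, ys = sol[:, :p], sol[:, p]
        XtViX += Xs.T @ Xs
        XtViy += Xs.T @ ys
        ytViy += ys @ ys
    return logdet, XtViX, XtViy, ytViy


def _loglik(log_var, blocks, n, p, method):
    variances = np.exp(np.clip(log_var, _LOG_LO, _LOG_HI))
    try:
        logdet, XtViX, XtViy, ytViy = _block_loglik_parts(blocks, p, variances)
        cf = scipy.linalg.cho_factor(XtViX)
        beta = scipy.linalg.cho_solve(cf, XtViy)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        return -np.inf, None, None
    quad = ytViy - beta @ XtViy
    if method == "reml":
        logdet_xtvix = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_xtvix + quad)
    else:
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return ll, beta, XtViX


def fit_nested_lmm(
    y,
    X,
    groups,
    method: str = "reml",
    n_restarts: int = 3,
    x0=None,
    polish: bool = True,
) -> NestedLMMFit:
    """Fit by bounded quasi-Newton on log variances, with restarts and a
    simplex polish; variances within 1e-8 of the boundary are snapped to 0.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row mismatch")
    codes = _encode_groups(groups)
    for k, g in enumerate(codes):
        if len(g) != len(y):
            raise ValueError(f"grouping factor {k} has wrong length")
    # nesting check: each fine level maps into exactly one coarse level
    for coarse, fine in zip(codes[:-1], codes[1:]):
        for lev in np.unique(fine):
            if len(np.unique(coarse[fine == lev])) > 1:
                raise ValueError("grouping factors are not nested (coarse to fine order)")
    q = len(codes)
    if len(np.unique(codes[0])) < 2:
        raise ValueError("outermost factor has a single level; its variance is unidentifiable")

    n, p = X.shape
    blocks = _build_blocks(y, X, codes)
    nll = lambda lv: -_loglik(lv, blocks, n, p, method)[0]
    var0 = max(float(np.var(y)), 1e-8)
    starts = [
        np.log(np.full(q + 1, var0 / (q + 1))),
        np.log(np.concatenate([np.full(q, var0 / 10), [var0]])),
        np.log(np.concatenate([np.full(q, var0), [var0 / 10]])),
    ][: max(1, n_restarts)]
    if x0 is not None:
        starts = [np.clip(np.asarray(x0, float), _LOG_LO, _LOG_HI)] + starts[: n_restarts - 1]

    best, trace = None, []
    for start in starts:
        res = scipy.optimize.minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(_LOG_LO, _LOG_HI)] * (q + 1),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        trace.append((res.x.copy(), float(res.fun), res.message))
        if best is None or res.fun < best.fun:
            best = res
    if polish:
        # simplex polish for tight agreement with closed forms on toy designs
        pol = scipy.optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 1200},
        )
        if pol.fun <= best.fun:
            best = pol
    if not np.isfinite(best.fun):
        raise ConvergenceError("restricted likelihood maximization failed", trace=trace)

    log_var = np.clip(best.x, _LOG_LO, _LOG_HI)
    ll, beta, XtViX = _loglik(log_var, blocks, n, p, method)
    variances = np.exp(log_var)
    boundary = variances < 1e-8 * max(variances.sum(), 1e-300)
    variances[boundary] = 0.0
    return NestedLMMFit(
        variances=variances,
        beta=beta,
        cov_beta=np.linalg.inv(XtViX),
        loglik=float(ll),
        method=method,
        n=len(y),
        p=X.shape[1],
        converged=bool(np.isfinite(ll)),
        boundary=boundary,
    )
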