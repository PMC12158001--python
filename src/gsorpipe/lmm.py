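"""Two-variance-component linear mixed model via eigen-rotation.

The model is ``y = X beta + g + e`` with ``g ~ N(0, G sigma_g2)`` and
``e ~ N(0, I sigma_e2)``.  After rotating by the eigenvectors of G the
covariance is diagonal, so the restricted likelihood reduces to a smooth
one-dimensional function of the heritability ratio which is maximized by
bounded scalar search; fixed effects then come from generalized least
squares in the rotated basis.  This is the workhorse behind heritability
estimation, the leave-one-chromosome-out association scan, and the
per-gene omics regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["VarianceComponents", "GEig", "eigen_grm", "reml_fit", "gls_fixed_effects"]

_H2_LO, _H2_HI = 1e-8, 1.0 - 1e-8


class ConvergenceError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """REML estimates for the two-component model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float  # restricted log-likelihood up to an additive constant

    @property
    def total(self) -> float:
        return self.sigma_g2 + self.sigma_e2


@dataclass
class GEig:
    """Cached eigendecomposition of a relationship matrix."""

    values: np.ndarray
    vectors: np.ndarray

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.vectors.T @ a


def eigen_grm(G: np.ndarray) -> GEig:
    vals, vecs = np.linalg.eigh(G)
    return GEig(np.maximum(vals, 0.0), vecs)


def _neg2_restricted_ll_profiled(h2, lam, yt, Xt):
    """-2 x restricted LL with total variance profiled out; returns aux too."""
    n, p = Xt.shape
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    r = yt - Xt @ beta
    ypy = float(np.sum(w * r * r))
    if ypy <= 0:
        return np.inf, None
    sigma_p2 = ypy / (n - p)
    crit = (n - p) * np.log(sigma_p2) + np.sum(np.log(d)) + logdet_xwx
    return crit, (sigma_p2, beta, XtWX)


def _neg2_restricted_ll(sg, se, lam, yt, Xt):
    """Unprofiled -2 restricted LL at (sigma_g2, sigma_e2)."""
    n, p = Xt.shape
    d = sg * lam + se
    if np.min(d) <= 0:
        return np.inf
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    r = yt - Xt @ beta
    return float(np.sum(np.log(d)) + logdet_xwx + np.sum(w * r * r))


def reml_fit(
    y: np.ndarray,
    G: np.ndarray | GEig,
    X: np.ndarray | None = None,
    min_n: int = 30,
) -> VarianceComponents:
    """REML variance components of ``y = X beta + g + e``.

    Parameters
    ----------
    y
        Response vector; must align with the rows of G.
    G
        Relationship matrix (or its cached eigendecomposition).
    X
        Fixed-effect design; defaults to an intercept column.

    The heritability ratio is found by bounded scalar maximization of the
    profiled restricted likelihood on the rotated model; ``se_h2`` comes
    from the numeric information matrix in (sigma_g2, sigma_e2) and the
    delta method.  Non-negativity holds by construction of the bound.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < min_n:
        raise ValueError(f"need n >= {min_n} samples for REML, got {n}")
    eig = G if isinstance(G, GEig) else eigen_grm(np.asarray(G))
    if np.ptp(eig.values) < 1e-8 * max(1.0, np.max(eig.values)):
        raise ConvergenceError("G is proportional to I: h2 is not identifiable")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    yt = eig.rotate(y)
    Xt = eig.rotate(X)
    lam = eig.values

    res = minimize_scalar(
        lambda h2: _neg2_restricted_ll_profiled(h2, lam, yt, Xt)[0],
        bounds=(_H2_LO, _H2_HI),
        method="bounded",
        options={"xatol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("restricted likelihood is degenerate on this input")
    h2 = float(res.x)
    crit, aux = _neg2_restricted_ll_profiled(h2, lam, yt, Xt)
    sigma_p2 = aux[0]
    # endpoint check: the bounded search can sit near an interior point when
    # the optimum is at a boundary
    for h2_edge in (_H2_LO, _H2_HI):
        crit_edge, aux_edge = _neg2_restricted_ll_profiled(h2_edge, lam, yt, Xt)
        if crit_edge < crit:
            h2, crit, sigma_p2 = h2_edge, crit_edge, aux_edge[0]
    sg, se = h2 * sigma_p2, (1.0 - h2) * sigma_p2
    se_h2 = _delta_se_h2(sg, se, lam, yt, Xt)
    return VarianceComponents(sg, se, h2, se_h2, loglik=-0.5 * crit)


def _delta_se_h2(sg, se, lam, yt, Xt) -> float:
    """se(h2) from the numeric Hessian of -2 RL and the delta method."""
    total = sg + se
    step = 1e-4 * max(total, 1e-12)
    f = lambda a, b: _neg2_restricted_ll(a, b, lam, yt, Xt)
    # central second differences (observed information = 0.5 * Hessian of -2RL)
    pts = {}
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            pts[(da, db)] = f(max(sg + da * step, 1e-12 * total),
                              max(se + db * step, 1e-12 * total))
    if not all(np.isfinite(v) for v in pts.values()):
        return float("nan")
    h_aa = (pts[(1, 0)] - 2 * pts[(0, 0)] + pts[(-1, 0)]) / step**2
    h_bb = (pts[(0, 1)] - 2 * pts[(0, 0)] + pts[(0, -1)]) / step**2
    h_ab = (pts[(1, 1)] - pts[(1, -1)] - pts[(-1, 1)] + pts[(-1, -1)]) / (4 * step**2)
    info = 0.5 * np.array([[h_aa, h_ab], [h_ab, h_bb]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    grad = np.array([se, -sg]) / total**2
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def gls_fixed_effects(
    y: np.ndarray,
    X: np.ndarray,
    eig: GEig,
    sigma_g2: float,
    sigma_e2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized-least-squares fixed effects under V = G sg2 + I se2.

    Returns ``(beta, se)`` with one entry per column of X.
    """
    yt = eig.rotate(np.asarray(y, dtype=float))
    Xt = eig.rotate(np.asarray(X, dtype=float))
    d = sigma_g2 * eig.values + sigma_e2
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    cov = np.linalg.inv(XtWX)
    beta = cov @ (XtW.T @ yt)
    return beta, np.sqrt(np.diag(cov))
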