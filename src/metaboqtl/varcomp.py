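"""REML variance components for pedigree traits.

Fits y ~ N(X beta, sigma2_g * 2Phi + sigma2_c * H + sigma2_e * I) by
restricted maximum likelihood, where 2Phi is the additive relationship
matrix from the pedigree and H is the 0/1 household-sharing matrix.
Heritability h2 and the household effect c2 are the corresponding variance
fractions.

Numerics: the kinship matrix is eigendecomposed once, making the
no-household likelihood evaluation O(n); with a household component the
block structure H = Z Z^T (Z the sample-by-household indicator) admits a
Woodbury identity, so each evaluation costs O(n q^2) for q households
instead of O(n^3).  The total variance is profiled out analytically and
the two remaining variance fractions are optimized by a derivative-free
simplex over a softmax parameterization (variances can never go
negative), with an explicit boundary refit when a component collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    InvalidArgumentError,
    MatrixError,
    UndefinedRatioError,
)
from .pedigree import KinshipMatrix

_LOG2PI = np.log(2.0 * np.pi)
_BOUNDARY_FRAC = 1e-6


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates for one trait."""

    sigma2_g: float
    sigma2_c: float
    sigma2_e: float
    beta: np.ndarray = field(repr=False)
    loglik: float = np.nan
    converged: bool = True
    identifiable: bool = True
    n: int = 0
    se_h2: float = np.nan
    se_c2: float = np.nan
    message: str = ""

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_c + self.sigma2_e

    @property
    def h2(self) -> float:
        return heritability(self)[0]

    @property
    def c2(self) -> float:
        return heritability(self)[1]


def heritability(v: VarianceComponents) -> tuple[float, float]:
    """(h2, c2) variance fractions; errors if the total variance is 0."""
    tot = v.total
    if tot <= 0:
        raise UndefinedRatioError("total variance is zero")
    return v.sigma2_g / tot, v.sigma2_c / tot


def heritability_table(fits: dict[str, VarianceComponents], path: str | None = None):
    """Per-trait summary (h2, c2, SEs, log-REML, convergence) as a frame.

    One row per metabolite — the tabular twin of a heritability/household
    bar chart.  Writes TSV when ``path`` is given.
    """
    import pandas as pd

    rows = []
    for name, v in fits.items():
        h2, c2 = heritability(v)
        rows.append(
            {
                "trait": name,
                "h2": h2,
                "c2": c2,
                "se_h2": v.se_h2,
                "se_c2": v.se_c2,
                "sigma2_g": v.sigma2_g,
                "sigma2_c": v.sigma2_c,
                "sigma2_e": v.sigma2_e,
                "log_reml": v.loglik,
                "converged": v.converged,
                "n": v.n,
            }
        )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def _blocks_from_household(H: np.ndarray) -> np.ndarray | None:
    """Return the indicator Z when H is exactly a block-ones matrix."""
    if not np.array_equal(H, H.T):
        return None
    n_comp, labels = connected_components(csr_matrix(H != 0), directed=False)
    Z = np.zeros((H.shape[0], n_comp))
    Z[np.arange(H.shape[0]), labels] = 1.0
    if np.array_equal(Z @ Z.T, H):
        return Z
    return None


class _RemlWorkspace:
    """Rotated data shared by all likelihood evaluations of one fit."""

    def __init__(self, y, X, A, H, eig=None):
        n, p = X.shape
        s, U = np.linalg.eigh(A) if eig is None else eig
        if s.min() < -1e-6 * max(s.max(), 1.0):
            raise MatrixError("kinship matrix is not positive semi-definite")
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.ys = U.T @ y
        self.Xs = U.T @ X
        self.n, self.p = n, p
        self.Zs = None
        self.Hs = None
        if H is not None:
            if H.shape != (n, n):
                raise MatrixError("household matrix shape mismatch")
            Z = _blocks_from_household(H)
            if Z is not None:
                self.Zs = U.T @ Z
            else:
                w = np.linalg.eigvalsh(H)
                if w.min() < -1e-8 * max(abs(w).max(), 1.0):
                    raise MatrixError("household matrix is not positive semi-definite")
                self.Hs = U.T @ H @ U
        self.has_household = H is not None

    # -- profiled restricted log-likelihood -------------------------------
    def neg_reml(self, h2: float, c2: float) -> tuple[float, dict]:
        n, p = self.n, self.p
        e2 = 1.0 - h2 - c2
        D = h2 * self.s + e2
        if D.min() <= 0 and self.Zs is None and self.Hs is None:
            return np.inf, {}
        B = np.column_stack([self.ys, self.Xs])

        if self.Zs is not None and c2 > 0:
            Dinv = 1.0 / D
            WD = self.Zs * Dinv[:, None]
            M = np.eye(self.Zs.shape[1]) + c2 * (self.Zs.T @ WD)
            cho = np.linalg.cholesky(M)
            tmp = np.linalg.solve(M, self.Zs.T @ (Dinv[:, None] * B))
            VinvB = Dinv[:, None] * B - c2 * WD @ tmp
            logdetV = float(np.sum(np.log(D)) + 2.0 * np.sum(np.log(np.diag(cho))))
        elif self.Hs is not None and c2 > 0:
            V = np.diag(D) + c2 * self.Hs
            cho, low = np.linalg.cholesky(V), True
            VinvB = np.linalg.solve(V, B)
            logdetV = float(2.0 * np.sum(np.log(np.diag(cho))))
        else:
            if D.min() <= 0:
                return np.inf, {}
            VinvB = B / D[:, None]
            logdetV = float(np.sum(np.log(D)))

        Vy, VX = VinvB[:, 0], VinvB[:, 1:]
        XtVX = self.Xs.T @ VX
        XtVy = self.Xs.T @ Vy
        try:
            cx = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError as exc:
            raise MatrixError("covariate matrix is rank deficient") from exc
        beta = np.linalg.solve(XtVX, XtVy)
        rss = float(self.ys @ Vy - XtVy @ beta)
        if rss <= 0:
            return np.inf, {}
        sigma2 = rss / (n - p)
        logdetXtVX = float(2.0 * np.sum(np.log(np.diag(cx))))
        neg2ll = (
            (n - p) * (_LOG2PI + np.log(sigma2) + 1.0) + logdetV + logdetXtVX
        )
        info = {"sigma2": sigma2, "beta": beta}
        return 0.5 * neg2ll, info


def _softmax_fracs(u: np.ndarray, with_c: bool) -> tuple[float, float]:
    if with_c:
        eg, ec = np.exp(np.clip(u, -30, 30))
        tot = 1.0 + eg + ec
        return eg / tot, ec / tot
    eg = np.exp(np.clip(u[0], -30, 30))
    return eg / (1.0 + eg), 0.0


def reml_fit(
    y,
    X,
    K,
    H: np.ndarray | None = None,
    compute_se: bool = True,
    xatol: float = 1e-5,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML fit of the polygenic (+ household) model.

    Parameters
    ----------
    y:
        Trait values; NaN entries are dropped (all matrices subset
        consistently).
    X:
        Covariate matrix including an intercept column.
    K:
        `KinshipMatrix` (or a raw kinship-coefficient matrix phi); the
        additive covariance uses 2*phi.
    H:
        Optional 0/1 household-sharing matrix; omit to fit the
        two-component polygenic model.

    Non-convergence is reported via the ``converged`` flag.  When a
    component is not identifiable from the design (e.g. kinship equal to
    the identity, or every household a singleton), the fit proceeds but
    ``identifiable`` is set to False.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    A = K.additive() if isinstance(K, KinshipMatrix) else 2.0 * np.asarray(K, float)
    keep = np.isfinite(y)
    if keep.sum() < X.shape[1] + 2:
        raise InvalidArgumentError("too few non-missing observations")
    if not keep.all():
        y = y[keep]
        X = X[keep]
        A = A[np.ix_(keep, keep)]
        H = H[np.ix_(keep, keep)] if H is not None else None
        eig = None  # the precomputed decomposition no longer applies
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MatrixError("covariate matrix is rank deficient")

    ws = _RemlWorkspace(y, X, A, H, eig=eig)
    with_c = H is not None

    identifiable = True
    msg = []
    if np.allclose(ws.s, ws.s[0]):
        identifiable = False
        msg.append("kinship proportional to identity: sigma2_g/sigma2_e not separable")
    if with_c:
        if ws.Zs is not None and ws.Zs.shape[1] == ws.n:
            identifiable = False
            msg.append("all households singleton: sigma2_c/sigma2_e not separable")
        elif ws.Hs is not None and np.allclose(ws.Hs, np.diag(np.diag(ws.Hs))):
            identifiable = False
            msg.append("household matrix diagonal: sigma2_c/sigma2_e not separable")

    def objective(u):
        h2, c2 = _softmax_fracs(np.atleast_1d(u), with_c)
        val, _ = ws.neg_reml(h2, c2)
        return val

    if with_c:
        starts = [np.log([0.3, 0.1]), np.log([0.05, 0.05]), np.log([0.6, 0.02])]
        starts = [st - np.log(1 - np.exp(st).sum()) for st in starts]
    else:
        starts = [np.array([np.log(f / (1 - f))]) for f in (0.3, 0.05, 0.7)]

    scored = sorted(starts, key=objective)
    best = None
    converged = False
    for st in scored:
        res = optimize.minimize(
            objective,
            st,
            method="Nelder-Mead",
            options=dict(xatol=xatol, fatol=1e-9, maxfev=400 * len(st)),
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            break

    h2, c2 = _softmax_fracs(np.atleast_1d(best.x), with_c)

    # explicit refit on the boundary when a component collapses
    if h2 < _BOUNDARY_FRAC or (with_c and c2 < _BOUNDARY_FRAC):
        fix_g = h2 < _BOUNDARY_FRAC
        fix_c = (not with_c) or c2 < _BOUNDARY_FRAC
        if fix_g and fix_c:
            h2, c2 = 0.0, 0.0
        elif fix_g:
            r = optimize.minimize_scalar(
                lambda v: ws.neg_reml(0.0, 1.0 / (1.0 + np.exp(-v)))[0],
                bounds=(-30, 5), method="bounded",
            )
            h2, c2 = 0.0, 1.0 / (1.0 + np.exp(-r.x))
            if c2 < _BOUNDARY_FRAC:
                c2 = 0.0
        else:
            r = optimize.minimize_scalar(
                lambda v: ws.neg_reml(1.0 / (1.0 + np.exp(-v)), 0.0)[0],
                bounds=(-30, 5), method="bounded",
            )
            h2, c2 = 1.0 / (1.0 + np.exp(-r.x)), 0.0
            if h2 < _BOUNDARY_FRAC:
                h2 = 0.0

    negll, info = ws.neg_reml(h2, c2)
    sigma2 = info["sigma2"]
    vc = VarianceComponents(
        sigma2_g=h2 * sigma2,
        sigma2_c=c2 * sigma2,
        sigma2_e=(1.0 - h2 - c2) * sigma2,
        beta=info["beta"],
        loglik=-negll,
        converged=converged,
        identifiable=identifiable,
        n=ws.n,
        message="; ".join(msg),
    )
    if compute_se and identifiable:
        se_h2, se_c2 = _fraction_se(ws, vc, with_c)
        vc = VarianceComponents(
            **{**vc.__dict__, "se_h2": se_h2, "se_c2": se_c2}
        )
    return vc


def _neg_reml_abs(ws: _RemlWorkspace, vg: float, vc_: float, ve: float) -> float:
    """Unprofiled negative restricted log-likelihood at absolute variances."""
    tot = vg + vc_ + ve
    if tot <= 0 or min(vg, vc_, ve) < 0:
        return np.inf
    val, info = ws.neg_reml(vg / tot, vc_ / tot)
    if not np.isfinite(val):
        return np.inf
    n, p = ws.n, ws.p
    sigma2 = info["sigma2"]
    # rescale the profiled likelihood to the requested total variance
    return val + 0.5 * (
        (n - p) * (np.log(tot) - np.log(sigma2)) + (n - p) * (sigma2 / tot - 1.0)
    )


def _fraction_se(
    ws: _RemlWorkspace, vc: VarianceComponents, with_c: bool
) -> tuple[float, float]:
    """Delta-method SEs for h2 and c2 from a numerical Hessian."""
    theta = [vc.sigma2_g, vc.sigma2_c, vc.sigma2_e] if with_c else [
        vc.sigma2_g,
        vc.sigma2_e,
    ]
    active = [i for i, v in enumerate(theta) if v > _BOUNDARY_FRAC * vc.total]
    if len(active) < 2:
        return np.nan, np.nan

    def f(vals):
        full = list(theta)
        for i, v in zip(active, vals):
            full[i] = v
        if with_c:
            return _neg_reml_abs(ws, full[0], full[1], full[2])
        return _neg_reml_abs(ws, full[0], 0.0, full[1])

    x0 = np.array([theta[i] for i in active])
    h = np.maximum(1e-4 * vc.total, 1e-4 * x0)
    k = len(x0)
    Hmat = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        for j in range(i, k):
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                Hmat[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                Hmat[i, j] = Hmat[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(Hmat)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    if np.any(np.diag(cov) < 0):
        return np.nan, np.nan

    tot = vc.total

    def ratio_se(num_idx):
        # gradient of theta_num / total over the active coordinates
        grad = np.array(
            [
                ((1.0 if i == num_idx else 0.0) * tot - theta[num_idx]) / tot**2
                for i in active
            ]
        )
        return float(np.sqrt(grad @ cov @ grad))

    se_h2 = ratio_se(0) if 0 in active else np.nan
    if with_c:
        se_c2 = ratio_se(1) if 1 in active else np.nan
    else:
        se_c2 = np.nan
    return se_h2, se_c2
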