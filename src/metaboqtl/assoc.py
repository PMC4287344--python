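"""Family-based mixed-model score-test GWAS and related statistics.

A polygenic null model y ~ N(X beta, sigma2_g * 2Phi + sigma2_e * I) is
fitted once per trait by REML; every variant is then tested with the
score statistic

    U = g~' V^-1 r,   chi2_1 = U^2 / (g~' V^-1 g~),

where r are the GLS residuals of the null fit and g~ is the coded
genotype projected onto the orthogonal complement of the covariates in
the V^-1 inner product (plain centering is the special case of an
intercept-only model).  This is the FASTA / "mmscore" construction:
variance components are estimated once, so a genome scan costs one matrix
whitening plus O(n) per variant.  The effect estimate beta = U / (g~'
V^-1 g~) and its SE are on the coded-allele scale.

The household variance component is excluded from the GWAS null model by
default (two-stage practice: polygenic null + score test); pass
``household=H`` to include it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import InsufficientDataError, InvalidArgumentError
from .pedigree import KinshipMatrix
from .varcomp import VarianceComponents, reml_fit

MODEL_CODINGS = {
    "additive": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
    "overdominant": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class AssocResult:
    variant_id: str
    model: str
    beta: float
    se: float
    chi2: float
    p: float
    n: int
    maf: float
    r2_pct: float
    reason: str = ""

    @property
    def testable(self) -> bool:
        return self.reason == ""


@dataclass(frozen=True)
class NullFit:
    """Whitened null model reused across all variants of one trait.

    ``Wt`` satisfies V^-1 = Wt' Wt for the fitted null covariance V, so
    all score-test quantities are inner products of whitened vectors.
    """

    sample_ids: tuple[str, ...]
    Wt: np.ndarray = field(repr=False)
    Xw: np.ndarray = field(repr=False)
    yw: np.ndarray = field(repr=False)
    rw: np.ndarray = field(repr=False)
    XtX_inv: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    var_resid: float = np.nan  # Var(y residualized on covariates), trait scale
    vc: VarianceComponents | None = None

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def with_covariates(self, extra: np.ndarray) -> "NullFit":
        """Augment the fixed effects (same variance components).

        Used for conditional analysis: the conditioning genotype enters
        as a covariate, the GLS fit is redone, V stays as estimated under
        the original null.
        """
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != self.n:
            extra = extra.T
        if extra.shape[0] != self.n:
            raise InvalidArgumentError("covariate length mismatch")
        Xw = np.column_stack([self.Xw, self.Wt @ extra])
        XtX = Xw.T @ Xw
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (Xw.T @ self.yw)
        rw = self.yw - Xw @ beta
        return replace(self, Xw=Xw, XtX_inv=XtX_inv, beta=beta, rw=rw)


def null_model(
    y,
    X,
    K,
    sample_ids=None,
    household: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullFit:
    """Fit the polygenic null and build the whitened-score workspace.

    ``eig`` optionally supplies a precomputed eigendecomposition
    ``(eigenvalues, U)`` of the additive matrix 2*Phi, shared across
    traits on the same cohort.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    A = K.additive() if isinstance(K, KinshipMatrix) else 2.0 * np.asarray(K, float)
    if y.shape[0] != A.shape[0] or X.shape[0] != A.shape[0]:
        raise InvalidArgumentError("y, X and kinship dimensions disagree")
    if not np.isfinite(y).all():
        raise InvalidArgumentError("null-model trait must be complete (drop NaNs first)")
    ids = tuple(sample_ids) if sample_ids is not None else tuple(
        f"s{i}" for i in range(len(y))
    )
    if len(ids) != len(y):
        raise InvalidArgumentError("sample_ids length mismatch")

    if eig is None:
        s, U = np.linalg.eigh(A)
        s = np.clip(s, 0.0, None)
    else:
        s, U = eig
    vc = reml_fit(y, X, 0.5 * A, H=household, compute_se=False, eig=(s, U))

    if household is None:
        d = vc.sigma2_g * s + vc.sigma2_e
        Wt = (U / np.sqrt(d)).T  # diag(1/sqrt(d)) @ U.T
    else:
        V = vc.sigma2_g * A + vc.sigma2_c * household + vc.sigma2_e * np.eye(len(y))
        L = np.linalg.cholesky(V)
        Wt = solve_triangular(L, np.eye(len(y)), lower=True)

    Xw = Wt @ X
    yw = Wt @ y
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ (Xw.T @ yw)
    rw = yw - Xw @ beta

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    var_resid = float(np.var(y - X @ ols_beta, ddof=X.shape[1]))
    return NullFit(ids, Wt, Xw, yw, rw, XtX_inv, beta, var_resid, vc)


def code_genotypes(dosage, coding: str, max_dev: float = 0.1) -> np.ndarray:
    """Apply a mode-of-inheritance coding to allele dosages.

    Additive passes dosages through unchanged.  The genotype-class
    codings round to hard calls first; dosages further than ``max_dev``
    from an integer are set missing.
    """
    if coding not in MODEL_CODINGS:
        raise InvalidArgumentError(f"unknown coding {coding!r}")
    g = np.asarray(dosage, dtype=float)
    if coding == "additive":
        return g.copy()
    hard = np.round(g)
    bad = np.abs(g - hard) > max_dev
    hard[bad] = np.nan
    codes = MODEL_CODINGS[coding]
    out = np.full_like(g, np.nan)
    for k in (0, 1, 2):
        out[hard == k] = codes[k]
    return out


def _impute_mean(g: np.ndarray) -> tuple[np.ndarray, int]:
    miss = ~np.isfinite(g)
    if miss.all():
        raise InsufficientDataError("all genotypes missing")
    if miss.any():
        g = g.copy()
        g[miss] = g[~miss].mean()
    return g, int((~miss).sum())


def score_test(
    nf: NullFit, g, coding: str = "additive", variant_id: str = ""
) -> AssocResult:
    """Mixed-model score test of one variant against the null fit.

    Missing dosages are mean-imputed (the per-variant n reflects the
    observed calls).  A monomorphic coded genotype yields a non-testable
    result (p missing, reason recorded) rather than an exception.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[0] != nf.n:
        raise InvalidArgumentError("genotype length does not match the null fit")
    raw, _ = _impute_mean(g) if np.isnan(g).any() else (g, len(g))
    freq = float(raw.mean() / 2.0)
    maf = min(freq, 1.0 - freq)

    coded = code_genotypes(g, coding)
    if not np.isfinite(coded).any():
        return AssocResult(variant_id, coding, np.nan, np.nan, np.nan, np.nan,
                           0, maf, np.nan, reason="all calls missing")
    coded, n_used = _impute_mean(coded)
    if np.ptp(coded) == 0:
        return AssocResult(variant_id, coding, np.nan, np.nan, np.nan, np.nan,
                           n_used, maf, np.nan, reason="monomorphic coding")

    gw = nf.Wt @ coded
    b = nf.XtX_inv @ (nf.Xw.T @ gw)
    gtil = gw - nf.Xw @ b
    den = float(gtil @ gtil)
    if den <= 1e-12:
        return AssocResult(variant_id, coding, np.nan, np.nan, np.nan, np.nan,
                           n_used, maf, np.nan, reason="coding collinear with covariates")
    U = float(gtil @ nf.rw)
    chi2 = U**2 / den
    beta = U / den
    se = 1.0 / np.sqrt(den)
    p = float(stats.chi2.sf(chi2, df=1))
    r2 = explained_variance(nf, coded, beta)
    return AssocResult(variant_id, coding, beta, se, chi2, max(p, 5e-324),
                       n_used, maf, r2)


def score_scan(nf: NullFit, dosages: np.ndarray, variant_ids=None) -> pd.DataFrame:
    """Vectorized additive score test over a samples x variants matrix."""
    G = np.asarray(dosages, dtype=float)
    if G.ndim != 2 or G.shape[0] != nf.n:
        raise InvalidArgumentError("dosage matrix must be n_samples x n_variants")
    m = G.shape[1]
    ids = list(variant_ids) if variant_ids is not None else [f"v{j}" for j in range(m)]
    miss = ~np.isfinite(G)
    n_used = (~miss).sum(axis=0)
    if miss.any():
        G = np.where(miss, np.nan, G)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(miss, col_mean[None, :], G)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    Gw = nf.Wt @ G
    B = nf.XtX_inv @ (nf.Xw.T @ Gw)
    Gtil = Gw - nf.Xw @ B
    den = np.einsum("ij,ij->j", Gtil, Gtil)
    U = Gtil.T @ nf.rw
    ok = den > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(ok, U**2 / den, np.nan)
        beta = np.where(ok, U / den, np.nan)
        se = np.where(ok, 1.0 / np.sqrt(den), np.nan)
    p = np.where(ok, stats.chi2.sf(chi2, df=1), np.nan)
    var_g = G.var(axis=0)
    r2 = np.where(ok, 100.0 * beta**2 * var_g / nf.var_resid, np.nan)
    return pd.DataFrame(
        {
            "id": ids,
            "model": "additive",
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": p,
            "n": n_used,
            "maf": maf,
            "r2_pct": np.clip(r2, 0.0, 100.0),
        }
    )


def genotype_model_scan(
    nf: NullFit,
    g,
    models=("additive", "dominant", "recessive", "overdominant"),
    variant_id: str = "",
) -> tuple[AssocResult, pd.DataFrame]:
    """Test one variant under several mode-of-inheritance codings.

    Dosages are rounded to hard genotype calls for the genotype-class
    codings; a coding that is constant after collapse (e.g. no homozygote
    carriers for the recessive model) is reported as skipped.  The best
    model is the one with the smallest p-value.
    """
    results = [score_test(nf, g, coding=mdl, variant_id=variant_id) for mdl in models]
    table = pd.DataFrame(
        {
            "model": [r.model for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "skipped_reason": [r.reason for r in results],
        }
    )
    testable = [r for r in results if r.testable]
    if not testable:
        raise InsufficientDataError("no testable coding for this variant")
    best = min(testable, key=lambda r: r.p)
    return best, table


def explained_variance(nf: NullFit, g_coded, beta: float) -> float:
    """Percent trait variance explained: 100 * beta^2 Var(g) / Var(resid y)."""
    if not np.isfinite(nf.var_resid) or nf.var_resid <= 0:
        raise InvalidArgumentError("trait residual variance is zero")
    var_g = float(np.var(np.asarray(g_coded, float)))
    return float(np.clip(100.0 * beta**2 * var_g / nf.var_resid, 0.0, 100.0))


def metabolome_threshold(alpha_gw: float, n_metabolites: int) -> float:
    """Metabolome-wide significance: genome-wide alpha / number of traits."""
    if n_metabolites < 1:
        raise InvalidArgumentError("n_metabolites must be >= 1")
    if not (0.0 < alpha_gw < 1.0):
        raise InvalidArgumentError("alpha_gw must be in (0, 1)")
    return alpha_gw / n_metabolites


def genomic_inflation(p_values) -> float:
    """Genomic-control lambda: median chi2-equivalent over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise InsufficientDataError("need at least 100 p-values")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def power_additive(n: int, maf: float, beta: float, alpha: float) -> float:
    """Analytic power of the additive 1-df test.

    Noncentrality NCP = n * 2 maf (1-maf) * beta^2 with beta in trait-SD
    units per allele; power is the upper tail of the noncentral
    chi-square beyond the central critical value at ``alpha``
    (two-sided).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not (0.0 < maf <= 0.5):
        raise InvalidArgumentError("maf must be in (0, 0.5]")
    if not (0.0 < alpha < 1.0):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    ncp = n * 2.0 * maf * (1.0 - maf) * beta**2
    crit = stats.chi2.isf(alpha, df=1)
    if ncp == 0.0:
        return alpha
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    exp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(p)}
    )
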