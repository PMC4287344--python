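"""Phenotype preparation for genetic analysis.

The fixed pipeline order is: sample exclusion (e.g. lipid-lowering
medication), single-shot removal of values beyond k standard deviations
from the mean, then rank transformation of the non-missing values.  The
outlier pass is deliberately not iterated — the mean and SD are computed
once on the input — and plain (average-tie) ranks are the default, with
inverse-normal scores available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError


@dataclass(frozen=True)
class TraitVector:
    """Per-sample trait values with NaN as missing and a history log."""

    values: np.ndarray = field(repr=False)
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_values(cls, values) -> "TraitVector":
        return cls(np.asarray(values, dtype=float))

    @property
    def mask(self) -> np.ndarray:
        """True where the value is present."""
        return np.isfinite(self.values)

    @property
    def n_present(self) -> int:
        return int(self.mask.sum())


def remove_outliers(t: TraitVector, k: float = 4.0) -> TraitVector:
    """Set values more than ``k`` SDs from the mean to missing.

    The mean and (sample) SD are computed once over the non-missing
    values; the rule is not re-applied after removal.  A constant vector
    has SD 0, so nothing is ever removed from it.
    """
    if k <= 0:
        raise InvalidArgumentError("k must be positive")
    m = t.mask
    if m.sum() < 2:
        raise InsufficientDataError("need at least 2 non-missing values")
    vals = t.values.copy()
    mean = vals[m].mean()
    sd = vals[m].std(ddof=1)
    n_removed = 0
    if sd > 0:
        out = m & (np.abs(vals - mean) > k * sd)
        vals[out] = np.nan
        n_removed = int(out.sum())
    return TraitVector(vals, t.history + (f"remove_outliers(k={k}, removed={n_removed})",))


def rank_transform(t: TraitVector, inverse_normal: bool = False) -> TraitVector:
    """Replace non-missing values by ranks 1..m (ties get average rank).

    With ``inverse_normal`` the ranks are mapped through the standard
    normal quantile function (Blom offset 0.5/m), for sensitivity
    analysis only.
    """
    m = t.mask
    if m.sum() < 1:
        raise InsufficientDataError("need at least 1 non-missing value")
    vals = np.full_like(t.values, np.nan)
    ranks = stats.rankdata(t.values[m], method="average")
    if inverse_normal:
        vals[m] = stats.norm.ppf((ranks - 0.5) / m.sum())
        tag = "rank_transform(inverse_normal)"
    else:
        vals[m] = ranks
        tag = "rank_transform"
    return TraitVector(vals, t.history + (tag,))


def exclude_samples(
    metadata: pd.DataFrame, flags: pd.DataFrame
) -> tuple[list, dict[str, int]]:
    """Retain samples with no exclusion flag set.

    ``flags`` holds one boolean column per exclusion reason, indexed by
    sample id; every flagged id must exist in ``metadata``.  Returns the
    retained id list (metadata order) and per-reason exclusion counts.
    """
    unknown = flags.index.difference(metadata.index)
    if len(unknown):
        raise KeyError(f"flagged sample ids not in metadata: {list(unknown[:5])}")
    aligned = flags.reindex(metadata.index).fillna(False).astype(bool)
    counts = {col: int(aligned[col].sum()) for col in aligned.columns}
    keep = ~aligned.any(axis=1)
    return list(metadata.index[keep]), counts


def partial_correlation(
    x: TraitVector, y: TraitVector, covariates: list[TraitVector] | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Residuals come from OLS of each variable on [1, covariates] over
    complete cases; the p-value uses the t distribution with
    n - n_covariates - 2 degrees of freedom.
    """
    covariates = covariates or []
    cols = [x.values, y.values] + [c.values for c in covariates]
    data = np.column_stack(cols)
    complete = np.isfinite(data).all(axis=1)
    n = int(complete.sum())
    k = len(covariates)
    if n < k + 3:
        raise InsufficientDataError(f"need >= {k + 3} complete cases, have {n}")
    d = data[complete]
    X = np.column_stack([np.ones(n)] + [d[:, 2 + j] for j in range(k)])
    coef, *_ = np.linalg.lstsq(X, d[:, :2], rcond=None)
    resid = d[:, :2] - X @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise InsufficientDataError("zero residual variance")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return r, float(p)


def prepare_trait(
    metadata: pd.DataFrame,
    trait: str,
    exclusion_flags: pd.DataFrame | None = None,
    k_sd: float = 4.0,
    inverse_normal: bool = False,
) -> tuple[pd.Series, dict]:
    """Exclude -> remove outliers -> rank transform, in that fixed order.

    Returns the transformed trait (indexed by retained sample ids) and a
    log dict with the exclusion counts and the transformation history.
    """
    if exclusion_flags is not None:
        kept, counts = exclude_samples(metadata, exclusion_flags)
    else:
        kept, counts = list(metadata.index), {}
    t = TraitVector.from_values(metadata.loc[kept, trait].to_numpy())
    t = remove_outliers(t, k=k_sd)
    t = rank_transform(t, inverse_normal=inverse_normal)
    series = pd.Series(t.values, index=pd.Index(kept, name=metadata.index.name))
    log = {"excluded": counts, "history": list(t.history), "n_retained": len(kept)}
    return series, log
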