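"""Conditional fine-mapping of sequence variants against lead GWAS SNPs.

For each (variant, lead) pair three mixed-model score tests are run: the
variant alone (marginal), the variant adjusted for the lead, and the lead
adjusted for the variant — the conditioning genotype enters the null-model
fixed effects so the score test stays exact under the mixed model.  The
pattern of the two adjusted p-values together with the dosage LD r^2
classifies the variant as explaining the lead signal, independent of it,
tagged by it, or indistinguishable from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import NullFit, score_test
from .errors import UndefinedLDError

DEFAULT_ALPHA_KEEP = 1e-3
DEFAULT_ALPHA_DROP = 0.05
COLLINEAR_R2 = 0.999


@dataclass(frozen=True)
class VariantTable:
    """Sequence variants with per-sample dosages and metadata.

    ``variants`` columns: id, chrom, pos, a1, a2 and a free-text
    ``function`` label (missense/intron/UTR...), passed through verbatim.
    """

    variants: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)  # samples x variants
    sample_ids: tuple[str, ...]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def observation_counts(self) -> np.ndarray:
        """Non-missing carriers (samples with at least one copy) per variant."""
        d = self.dosages
        return np.nansum(np.where(np.isfinite(d), d, 0.0) > 0.5, axis=0).astype(int)

    def dosage(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) != 1:
            raise KeyError(variant_id)
        return self.dosages[:, self.variants.index.get_loc(j[0])]


def filter_variants(
    v: VariantTable, min_obs: int = 5
) -> tuple[VariantTable, pd.DataFrame]:
    """Drop variants observed in fewer than ``min_obs`` carriers.

    A variant with exactly ``min_obs`` observations is retained (the rule
    removes "less than" the threshold).  Returns the filtered table and a
    removal log.
    """
    obs = v.observation_counts()
    keep = obs >= min_obs
    log = pd.DataFrame(
        {
            "id": v.variants["id"].to_numpy(),
            "observations": obs,
            "removed": ~keep,
        }
    )
    filtered = VariantTable(
        v.variants.loc[keep].reset_index(drop=True),
        v.dosages[:, keep],
        v.sample_ids,
    )
    return filtered, log


def ld_r2(gA, gB) -> float:
    """Squared Pearson correlation of dosages over complete pairs."""
    a = np.asarray(gA, dtype=float)
    b = np.asarray(gB, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLDError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


@dataclass(frozen=True)
class ConditionalResult:
    variant_id: str
    lead_id: str
    p_marginal: float
    p_variant_adj: float  # variant tested with the lead as covariate
    p_lead_adj: float  # lead tested with the variant as covariate
    r2: float
    beta: float
    se: float
    classification: str


def classify_signal(
    c: ConditionalResult,
    alpha_keep: float = DEFAULT_ALPHA_KEEP,
    alpha_drop: float = DEFAULT_ALPHA_DROP,
) -> str:
    """Classify a conditional pair from its adjusted p-values.

    explains_lead: the variant stays associated after adjusting for the
    lead while the lead signal collapses; independent: both survive
    mutual adjustment; tagged_by_lead: the variant adds nothing over the
    lead; anything in between is reported as indeterminate.
    """
    if c.classification == "indistinguishable":
        return "indistinguishable"
    p_b, p_c = c.p_variant_adj, c.p_lead_adj
    if np.isnan(p_b) or np.isnan(p_c):
        return "indistinguishable"
    if p_b < alpha_keep and p_c >= alpha_drop:
        return "explains_lead"
    if p_b < alpha_keep and p_c < alpha_keep:
        return "independent"
    if p_b >= alpha_drop:
        return "tagged_by_lead"
    return "indeterminate"


def conditional_pair(
    nf: NullFit,
    g_variant,
    g_lead,
    variant_id: str = "variant",
    lead_id: str = "lead",
    alpha_keep: float = DEFAULT_ALPHA_KEEP,
    alpha_drop: float = DEFAULT_ALPHA_DROP,
) -> ConditionalResult:
    """Reciprocal conditional association of a variant and a lead SNP."""
    g_v = np.asarray(g_variant, dtype=float)
    g_l = np.asarray(g_lead, dtype=float)
    r2 = ld_r2(g_v, g_l)
    marginal = score_test(nf, g_v, variant_id=variant_id)

    if r2 > COLLINEAR_R2:
        res = ConditionalResult(
            variant_id, lead_id, marginal.p, np.nan, np.nan, r2,
            marginal.beta, marginal.se, "indistinguishable",
        )
        return res

    nf_lead = nf.with_covariates(np.nan_to_num(g_l, nan=np.nanmean(g_l)))
    p_variant_adj = score_test(nf_lead, g_v, variant_id=variant_id).p
    nf_var = nf.with_covariates(np.nan_to_num(g_v, nan=np.nanmean(g_v)))
    p_lead_adj = score_test(nf_var, g_l, variant_id=lead_id).p

    res = ConditionalResult(
        variant_id, lead_id, marginal.p, p_variant_adj, p_lead_adj, r2,
        marginal.beta, marginal.se, "",
    )
    return ConditionalResult(
        **{**res.__dict__, "classification": classify_signal(res, alpha_keep, alpha_drop)}
    )


def conditional_table(
    nf: NullFit,
    variants: VariantTable,
    lead_dosage,
    lead_id: str,
    alpha_keep: float = DEFAULT_ALPHA_KEEP,
    alpha_drop: float = DEFAULT_ALPHA_DROP,
    proxy_r2: float = 0.8,
) -> pd.DataFrame:
    """Conditional-analysis table for all variants against one lead SNP.

    Output columns mirror the conventional fine-mapping report: alleles,
    marginal beta/SE/p, functional label pass-through, MAF, the two
    adjusted p-values, LD r^2, classification, and a proxy list of other
    table variants with r^2 >= ``proxy_r2``.
    """
    rows = []
    meta = variants.variants
    d = variants.dosages
    for j in range(variants.n_variants):
        vid = meta.iloc[j]["id"]
        res = conditional_pair(
            nf, d[:, j], lead_dosage, variant_id=vid, lead_id=lead_id,
            alpha_keep=alpha_keep, alpha_drop=alpha_drop,
        )
        marginal = score_test(nf, d[:, j], variant_id=vid)
        proxies = []
        for k in range(variants.n_variants):
            if k == j:
                continue
            try:
                if ld_r2(d[:, j], d[:, k]) >= proxy_r2:
                    proxies.append(meta.iloc[k]["id"])
            except UndefinedLDError:
                continue
        rows.append(
            {
                "id": vid,
                "chrom": meta.iloc[j].get("chrom", ""),
                "pos": meta.iloc[j].get("pos", np.nan),
                "a1": meta.iloc[j].get("a1", ""),
                "a2": meta.iloc[j].get("a2", ""),
                "beta": res.beta,
                "se": res.se,
                "p_marginal": res.p_marginal,
                "function": meta.iloc[j].get("function", ""),
                "maf": marginal.maf,
                "p_variant_adj": res.p_variant_adj,
                "p_lead_adj": res.p_lead_adj,
                "ld_r2": res.r2,
                "classification": res.classification,
                "proxies": ",".join(proxies),
            }
        )
    return pd.DataFrame(rows)
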