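"""Simulation of metabolite traits with genetic and household structure.

The generating model is

    y = sum_j beta_j (g_j - 2 p_j) + a + c + e,

with polygenic values a ~ MVN(0, sigma2_g * 2Phi), a household effect c
shared by all members of a household (variance sigma2_c), and independent
residuals e.  Variances are chosen so the trait has unit total variance in
expectation: sigma2_e = 1 - h2 - c2 - sum_j 2 p_j (1 - p_j) beta_j^2.
Covariates (age, BMI) and the medication flag are generated independently
of the trait; sex comes from the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .genotypes import GenotypeMatrix
from .pedigree import KinshipMatrix, Pedigree


@dataclass(frozen=True)
class QtlEffect:
    variant_id: str
    beta: float  # per effect-allele, in phenotypic SD units


@dataclass(frozen=True)
class SimulationConfig:
    """Variance budget and nuisance parameters for one simulated trait."""

    h2: float
    c2: float
    qtls: tuple[QtlEffect, ...] = ()
    seed: int = 0
    trait_name: str = "metabolite"
    medication_rate: float = 0.123  # matches 298/2416 in the emulated design

    def qtl_variance(self, mafs: dict[str, float]) -> float:
        total = 0.0
        for q in self.qtls:
            p = mafs[q.variant_id]
            total += 2.0 * p * (1.0 - p) * q.beta**2
        return total

    def residual_variance(self, mafs: dict[str, float]) -> float:
        if not (0.0 <= self.h2 <= 1.0 and 0.0 <= self.c2 <= 1.0):
            raise InvalidArgumentError("h2 and c2 must be fractions in [0, 1]")
        s2e = 1.0 - self.h2 - self.c2 - self.qtl_variance(mafs)
        if s2e < -1e-12:
            raise InvalidArgumentError(
                "variance budget exceeds 1 (h2 + c2 + QTL variance > 1)"
            )
        return max(s2e, 0.0)


def simulate_phenotype(
    ped: Pedigree,
    K: KinshipMatrix,
    G: GenotypeMatrix | None,
    cfg: SimulationConfig,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate one metabolite trait plus covariates for a cohort.

    ``ids`` restricts the phenotyped cohort to a subset of the pedigree
    (marginalizing the polygenic MVN is exact under subsetting).  Returns
    a PhenotypeTable: one row per sample with the trait, age, sex, bmi,
    medication flag and household id.
    """
    ids = list(ped.ids) if ids is None else list(ids)
    if G is None and cfg.qtls:
        raise InvalidArgumentError("QTL effects requested but no genotypes given")
    mafs = (
        {r["id"]: r["maf"] for _, r in G.variants.iterrows()} if G is not None else {}
    )
    s2e = cfg.residual_variance(mafs)

    rng = np.random.default_rng(cfg.seed)
    n = len(ids)
    y = np.zeros(n)

    if cfg.h2 > 0:
        A = K.subset(ids).additive()
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        y += np.sqrt(cfg.h2) * (L @ rng.standard_normal(n))
    else:
        rng.standard_normal(n)  # keep the stream layout stable across budgets

    households = ped.table.loc[ids, "household"]
    labels = list(dict.fromkeys(households))
    hh_effect = dict(zip(labels, np.sqrt(cfg.c2) * rng.standard_normal(len(labels))))
    y += households.map(hh_effect).to_numpy()

    if cfg.qtls:
        Gs = G.subset_samples(ids)
        for q in cfg.qtls:
            g = Gs.dosage(q.variant_id)
            y += q.beta * (g - 2.0 * mafs[q.variant_id])

    y += np.sqrt(s2e) * rng.standard_normal(n)

    age = np.clip(rng.normal(50.0, 15.0, n), 18.0, 93.0)
    bmi = np.clip(rng.normal(26.5, 4.2, n), 15.0, 55.0)
    medication = rng.random(n) < cfg.medication_rate

    return pd.DataFrame(
        {
            cfg.trait_name: y,
            "age": age,
            "sex": ped.table.loc[ids, "sex"].to_numpy(),
            "bmi": bmi,
            "medication": medication,
            "household": households.to_numpy(),
        },
        index=pd.Index(ids, name="iid"),
    )
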