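"""Reusable synthetic-data experiments.

Each function here runs one of the package's standard verification
studies end to end — simulate under a known truth, analyze with the same
code a user would run, and summarize recovery.  They are used both by the
test suite and by the reproduction script, so problem sizes are chosen to
emulate the isolate family design (a cohort of roughly two thousand
phenotyped descendants of 22 founder couples) while staying tractable on
a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import (
    NullFit,
    genomic_inflation,
    genotype_model_scan,
    null_model,
    score_scan,
    score_test,
)
from .finemap import conditional_pair
from .genotypes import simulate_genotypes
from .nmr import (
    PeakModel,
    PeakIntensityMatrix,
    Spectrum,
    deconvolute,
    detect_peaks,
    estimate_width_scale,
    group_peaks,
    peak_sum,
    quantify_cpmg,
)
from .pedigree import (
    KinshipMatrix,
    Pedigree,
    household_matrix,
    kinship_from_pedigree,
    simulate_pedigree,
)
from .phenosim import QtlEffect, SimulationConfig, simulate_phenotype
from .spectra import default_axis, make_signature_library, simulate_concentrations, simulate_spectra
from .varcomp import reml_fit

#: Default isolate-style design: 22 founder couples, four generations,
#: zero-truncated Poisson(2.55) children per couple -> ~2,000 descendants.
DEFAULT_DESIGN = dict(n_founder_couples=22, n_generations=4, mean_children=2.55)


@dataclass(frozen=True)
class Cohort:
    """A simulated pedigree with its analysis-ready matrices.

    The phenotyped cohort is the descendants (individuals with both
    parents known); founders and married-in spouses contribute genotypes
    and kinship but are not analyzed, which keeps every phenotyped sample
    inside a sibship household.
    """

    ped: Pedigree
    ids: tuple[str, ...]
    K: KinshipMatrix = field(repr=False)  # subset to `ids`
    eig: tuple[np.ndarray, np.ndarray] = field(repr=False)  # of 2*Phi
    H: np.ndarray = field(repr=False)  # household matrix over `ids`

    @property
    def n(self) -> int:
        return len(self.ids)

    def chol_additive(self) -> np.ndarray:
        s, U = self.eig
        return U * np.sqrt(np.clip(s, 0.0, None))  # A^(1/2), for MVN draws


def build_cohort(seed: int, target_n: int | None = None, **design) -> Cohort:
    """Simulate a pedigree and assemble its analysis matrices.

    ``target_n`` pins the phenotyped cohort size: when the pedigree
    yields more descendants, a random subset of exactly ``target_n`` is
    phenotyped (subsetting the polygenic MVN is exact), which removes
    the between-seed spread of the Poisson growth process.
    """
    params = {**DEFAULT_DESIGN, **design}
    ped = simulate_pedigree(seed=seed, **params)
    ids = tuple(ped.descendant_ids)
    if target_n is not None and len(ids) > target_n:
        rng = np.random.default_rng(seed + 777)
        keep = np.sort(rng.choice(len(ids), size=target_n, replace=False))
        ids = tuple(np.asarray(ids, dtype=object)[keep])
    K_full = kinship_from_pedigree(ped)
    K = K_full.subset(list(ids))
    A = K.additive()
    s, U = np.linalg.eigh(A)
    H = household_matrix(ped, list(ids))
    return Cohort(ped, ids, K, (np.clip(s, 0.0, None), U), H)


def _covariates(cohort: Cohort, seed: int) -> np.ndarray:
    """Intercept + age + sex design used by the null models."""
    rng = np.random.default_rng(seed)
    n = cohort.n
    age = np.clip(rng.normal(50.0, 15.0, n), 18.0, 93.0)
    sex = cohort.ped.sex_code(list(cohort.ids))
    return np.column_stack([np.ones(n), age, sex])


# ---------------------------------------------------------------------------
# variance-components recovery


def heritability_recovery(
    n_seeds: int = 10,
    h2: float = 0.4,
    c2: float = 0.05,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Simulate pedigrees with known (h2, c2) and re-estimate by REML.

    One fresh pedigree, trait and REML fit per seed; returns the per-seed
    estimates (mean absolute errors are the relevant summaries).
    """
    rows = []
    for k in range(n_seeds):
        seed = base_seed + 1000 * k
        # n = 2,000 exactly: grow a slightly larger pedigree, phenotype 2,000
        cohort = build_cohort(seed, target_n=2000, mean_children=2.75)
        cfg = SimulationConfig(h2=h2, c2=c2, seed=seed + 1)
        pheno = simulate_phenotype(cohort.ped, cohort.K, None, cfg, ids=list(cohort.ids))
        X = np.column_stack(
            [
                np.ones(cohort.n),
                pheno["age"].to_numpy(),
                (pheno["sex"] == "female").to_numpy(float),
            ]
        )
        fit = reml_fit(
            pheno[cfg.trait_name].to_numpy(), X, cohort.K, H=cohort.H, compute_se=False
        )
        rows.append(
            {
                "seed": seed,
                "n": cohort.n,
                "h2_hat": fit.h2,
                "c2_hat": fit.c2,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score-test calibration


def score_calibration(
    n_variants: int = 10_000,
    h2: float = 0.4,
    seed: int = 1,
) -> dict:
    """Null GWAS on a related cohort: type-I error and genomic inflation.

    The trait has polygenic covariance only; all variants are simulated
    independently of it, so every positive at alpha = 0.05 is a false
    positive.
    """
    cohort = build_cohort(seed)
    cfg = SimulationConfig(h2=h2, c2=0.0, seed=seed + 1)
    pheno = simulate_phenotype(cohort.ped, cohort.K, None, cfg, ids=list(cohort.ids))
    X = _covariates(cohort, seed + 2)
    y = pheno[cfg.trait_name].to_numpy()

    rng = np.random.default_rng(seed + 3)
    mafs = rng.uniform(0.05, 0.5, n_variants)
    spec = [(float(m), f"b{j}") for j, m in enumerate(mafs)]
    G = simulate_genotypes(cohort.ped, spec, seed=seed + 4).subset_samples(list(cohort.ids))

    nf = null_model(y, X, cohort.K, sample_ids=cohort.ids, eig=cohort.eig)
    scan = score_scan(nf, G.dosages, variant_ids=G.variants["id"])
    p = scan["p"].to_numpy()
    p = p[np.isfinite(p)]
    return {
        "n_samples": cohort.n,
        "n_variants": int(p.size),
        "type1_rate_005": float(np.mean(p < 0.05)),
        "lambda_gc": genomic_inflation(p),
        "p_values": p,
        "h2_null": nf.vc.h2,
    }


def ols_equivalence(n: int = 500, n_variants: int = 50, seed: int = 1) -> dict:
    """Score test under identity kinship vs the closed-form OLS oracle.

    With unrelated samples the mixed-model score test must reduce to the
    classical OLS Rao score test (null variance estimate RSS/(n-p)); the
    oracle below computes it by direct projection, independent of the
    REML/whitening machinery.
    """
    ped = simulate_pedigree(n // 2, 1, mean_children=0.0, seed=seed)
    ids = list(ped.ids)
    K = kinship_from_pedigree(ped)
    rng = np.random.default_rng(seed + 1)
    X = np.column_stack([np.ones(n), rng.normal(50, 10, n), rng.integers(0, 2, n)])
    y = X @ np.array([1.0, 0.01, 0.2]) + rng.standard_normal(n)
    spec = [(float(m), f"b{j}") for j, m in enumerate(rng.uniform(0.05, 0.5, n_variants))]
    G = simulate_genotypes(ped, spec, seed=seed + 2)

    nf = null_model(y, X, K, sample_ids=ids)
    from scipy import stats as _st

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta0
    sigma2 = (r @ r) / (n - X.shape[1])
    max_rel = 0.0
    for j in range(n_variants):
        g = G.dosages[:, j]
        if np.ptp(g) == 0:
            continue
        got = score_test(nf, g).p
        cg, *_ = np.linalg.lstsq(X, g, rcond=None)
        gt = g - X @ cg
        chi = (gt @ y) ** 2 / ((gt @ gt) * sigma2)
        want = float(_st.chi2.sf(chi, 1))
        max_rel = max(max_rel, abs(got - want) / want)
    return {"max_rel_p_diff": max_rel, "n": n, "n_variants": n_variants}


# ---------------------------------------------------------------------------
# mode-of-inheritance recovery


def moi_recovery(
    n_reps: int = 100,
    maf: float = 0.3,
    delta: float = 0.5,
    h2: float = 0.3,
    seed: int = 1,
    generating: str = "recessive",
) -> dict:
    """Recover the generating genotype model by the best-p model scan.

    Each replicate simulates one bi-allelic variant and a trait whose
    genetic effect follows ``generating`` (recessive: only two-copy
    carriers shift by ``delta`` SD; additive: per-allele ``delta/2``),
    plus a polygenic background, then asks which coding wins.
    """
    cohort = build_cohort(seed)
    spec = [(maf, f"rep{k}") for k in range(n_reps)]
    G = simulate_genotypes(cohort.ped, spec, seed=seed + 1).subset_samples(list(cohort.ids))
    X = _covariates(cohort, seed + 2)
    L = cohort.chol_additive()
    rng = np.random.default_rng(seed + 3)
    best_models = []
    for k in range(n_reps):
        g = G.dosages[:, k]
        if generating == "recessive":
            effect = delta * (g == 2).astype(float)
        elif generating == "additive":
            effect = 0.5 * delta * g
        else:
            raise ValueError(f"unknown generating model {generating!r}")
        y = (
            effect
            - effect.mean()
            + np.sqrt(h2) * (L @ rng.standard_normal(cohort.n))
            + np.sqrt(1.0 - h2) * rng.standard_normal(cohort.n)
        )
        nf = null_model(y, X, cohort.K, sample_ids=cohort.ids, eig=cohort.eig)
        best, _ = genotype_model_scan(nf, g)
        best_models.append(best.model)
    wanted = "recessive" if generating == "recessive" else ("additive", "dominant")
    if isinstance(wanted, str):
        hits = sum(m == wanted for m in best_models)
    else:
        hits = sum(m in wanted for m in best_models)
    return {
        "n_reps": n_reps,
        "n_samples": cohort.n,
        "best_models": best_models,
        "recovery_rate": hits / n_reps,
    }


# ---------------------------------------------------------------------------
# fine-mapping architecture recovery


def tag_maf_for_r2(p_causal: float, r2: float) -> float:
    """Tag MAF giving dosage r^2 ~ ``r2`` with a comonotone block partner."""
    return p_causal / (r2 * (1.0 - p_causal) + p_causal)


def finemap_recovery(
    n_loci: int = 100,
    beta_causal_tag: float = 0.7,
    beta_two_causal: float = 0.5,
    maf: float = 0.2,
    r2_tag: float = 0.9,
    h2: float = 0.3,
    seed: int = 1,
) -> dict:
    """Classify simulated locus architectures with conditional analysis.

    Half the loci are one causal variant plus a tag in high LD (the lead
    SNP is the tag; truth = explains_lead), half are two independent
    causal variants (lead = the first; truth = independent for the
    second).  Returns the fraction of loci classified correctly.
    """
    cohort = build_cohort(seed)
    X = _covariates(cohort, seed + 2)
    L = cohort.chol_additive()
    rng = np.random.default_rng(seed + 3)

    spec = []
    truths = []
    p_tag = tag_maf_for_r2(maf, r2_tag)
    for i in range(n_loci):
        if i % 2 == 0:
            spec += [(maf, f"ct{i}"), (p_tag, f"ct{i}")]
            truths.append("explains_lead")
        else:
            spec += [(maf, f"tc{i}a"), (maf, f"tc{i}b")]
            truths.append("independent")
    G = simulate_genotypes(cohort.ped, spec, seed=seed + 4).subset_samples(list(cohort.ids))

    records = []
    for i, truth in enumerate(truths):
        g1 = G.dosages[:, 2 * i]
        g2 = G.dosages[:, 2 * i + 1]
        if truth == "explains_lead":
            beta = beta_causal_tag
            effect = beta * (g1 - g1.mean())
            variant, lead = g1, g2
        else:
            beta = beta_two_causal
            effect = beta * (g1 - g1.mean()) + beta * (g2 - g2.mean())
            variant, lead = g2, g1
        qtl_var = min(float(np.var(effect)), 0.6)
        y = (
            effect
            + np.sqrt(h2) * (L @ rng.standard_normal(cohort.n))
            + np.sqrt(max(1.0 - h2 - qtl_var, 0.05)) * rng.standard_normal(cohort.n)
        )
        nf = null_model(y, X, cohort.K, sample_ids=cohort.ids, eig=cohort.eig)
        res = conditional_pair(nf, variant, lead, variant_id=f"v{i}", lead_id=f"l{i}")
        records.append(
            {
                "locus": i,
                "truth": truth,
                "classification": res.classification,
                "r2": res.r2,
                "p_variant_adj": res.p_variant_adj,
                "p_lead_adj": res.p_lead_adj,
            }
        )
    table = pd.DataFrame(records)
    accuracy = float((table["truth"] == table["classification"]).mean())
    return {"table": table, "accuracy": accuracy, "n_samples": cohort.n}


# ---------------------------------------------------------------------------
# NMR recovery studies


def three_peak_fixture() -> tuple[Spectrum, list[PeakModel], list[PeakModel]]:
    """Noiseless 3-peak spectrum with pairwise overlap (1.5 FWHM apart)."""
    w = 0.02
    truth = [
        PeakModel(center=3.00, width=w, amplitude=1.0, eta=0.3),
        PeakModel(center=3.00 + 1.5 * w, width=w, amplitude=0.8, eta=0.5),
        PeakModel(center=3.00 + 3.0 * w, width=w, amplitude=0.6, eta=0.7),
    ]
    ppm = np.linspace(2.85, 3.22, 900)
    s = Spectrum(ppm, peak_sum(ppm, truth), kind="jres")
    bumps = [0.8, 1.2, 0.85, 1.15]  # deterministic +-20 % perturbations
    init = [
        PeakModel(
            center=p.center + 0.2 * w * (1 if k % 2 else -1),
            width=p.width * bumps[k % 4],
            amplitude=p.amplitude * bumps[(k + 1) % 4],
            eta=0.5,
        )
        for k, p in enumerate(truth)
    ]
    return s, truth, init


def deconvolution_recovery() -> dict:
    """Known-truth fit of the overlapping 3-peak fixture."""
    s, truth, init = three_peak_fixture()
    fitted, diag = deconvolute(s, init, max_iter_per_dim=400, n_restarts=4)
    fitted = sorted(fitted, key=lambda p: p.center)
    rel = {}
    for name in ("center", "width", "amplitude", "eta"):
        rel[name] = max(
            abs(getattr(f, name) - getattr(t, name)) / abs(getattr(t, name))
            for f, t in zip(fitted, truth)
        )
    return {
        "max_rel_error": max(rel.values()),
        "max_rel_amplitude_error": rel["amplitude"],
        "per_param": rel,
        "converged": diag.converged,
        "residual_norm": diag.residual_norm,
    }


def snr_amplitude_recovery(n_seeds: int = 20, snr: float = 100.0, seed: int = 1) -> dict:
    """Amplitude recovery of a single peak at a given amplitude/noise SNR."""
    truth = PeakModel(center=2.0, width=0.01, amplitude=1.0, eta=0.4)
    ppm = np.linspace(1.9, 2.1, 600)
    clean = peak_sum(ppm, [truth])
    errors = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        y = clean + rng.normal(0.0, truth.amplitude / snr, ppm.size)
        s = Spectrum(ppm, y, kind="jres")
        init = detect_peaks(s, min_prominence=0.2)
        fitted, _ = deconvolute(s, init[:1], max_iter_per_dim=400, n_restarts=2)
        best = max(fitted, key=lambda p: p.amplitude)
        errors.append(abs(best.amplitude - truth.amplitude) / truth.amplitude)
    return {"max_rel_amplitude_error": float(max(errors)), "errors": errors}


def quantification_end_to_end(
    n_samples: int = 40,
    n_metabolites: int = 6,
    snr: float = 50.0,
    seed: int = 1,
) -> dict:
    """Simulate spectra, run the full quantification path, compare to truth.

    Basis peaks are deconvoluted from the batch-mean JRES projection; each
    sample's CPMG spectrum is then quantified against the (re-broadened)
    basis, peaks are grouped by across-sample correlation, and group
    intensities are correlated with the generating concentrations.
    Returns the worst per-metabolite Pearson r.
    """
    sigs = make_signature_library(n_metabolites, seed=seed)
    conc = simulate_concentrations(n_samples, sigs, seed=seed + 1)
    ref_height = 0.5  # typical tallest signature line at unit concentration
    sset = simulate_spectra(
        sigs,
        conc,
        noise_sd_cpmg=0.5 * ref_height / snr,
        noise_sd_jres=ref_height / snr,
        seed=seed + 2,
        ppm=default_axis(),
    )

    mean_jres = Spectrum(sset.ppm, sset.jres.mean(axis=0), kind="jres")
    init = detect_peaks(mean_jres, min_prominence=0.02)
    basis, _ = deconvolute(mean_jres, init)
    scale = estimate_width_scale([sset.cpmg_spectrum(i) for i in range(3)], basis)

    inten = np.array(
        [
            quantify_cpmg(sset.cpmg_spectrum(i), basis, width_scale=scale).amplitudes
            for i in range(sset.n_samples)
        ]
    )
    P = PeakIntensityMatrix(
        inten,
        pd.DataFrame(
            {
                "center": [p.center for p in basis],
                "width": [p.width for p in basis],
                "eta": [p.eta for p in basis],
            }
        ),
        sset.sample_ids,
    )
    labels = group_peaks(P, r_threshold=0.8)
    group_intensity = {
        lab: inten[:, labels == lab].sum(axis=1) for lab in np.unique(labels)
    }
    per_met = {}
    for s in sigs:
        truth = conc[s.name].to_numpy()
        best = max(
            abs(np.corrcoef(truth, gi)[0, 1]) for gi in group_intensity.values()
        )
        per_met[s.name] = float(best)
    return {
        "min_correlation": min(per_met.values()),
        "per_metabolite": per_met,
        "n_basis_peaks": len(basis),
        "n_groups": len(group_intensity),
        "width_scale": scale,
    }
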