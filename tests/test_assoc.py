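import numpy as np
import pytest
from scipy import stats

from metaboqtl.assoc import (
    code_genotypes,
    explained_variance,
    genomic_inflation,
    genotype_model_scan,
    metabolome_threshold,
    null_model,
    power_additive,
    score_scan,
    score_test,
)
from metaboqtl.errors import InsufficientDataError, InvalidArgumentError
from metaboqtl.genotypes import simulate_genotypes
from metaboqtl.phenosim import SimulationConfig, simulate_phenotype


@pytest.fixture(scope="module")
def related_fit(small_cohort):
    cfg = SimulationConfig(h2=0.4, c2=0.0, seed=51)
    ph = simulate_phenotype(
        small_cohort["ped"], small_cohort["K_full"], None, cfg,
        ids=small_cohort["ids"],
    )
    n = len(ph)
    X = np.column_stack(
        [np.ones(n), ph["age"].to_numpy(), (ph["sex"] == "female").to_numpy(float)]
    )
    y = ph["metabolite"].to_numpy()
    nf = null_model(y, X, small_cohort["K"], sample_ids=small_cohort["ids"])
    G = simulate_genotypes(
        small_cohort["ped"], [(0.3, f"b{j}") for j in range(12)], seed=52
    ).subset_samples(list(small_cohort["ids"]))
    return {"nf": nf, "y": y, "X": X, "G": G}


class TestNullModel:
    def test_identity_kinship_residuals_equal_ols(self, unrelated_cohort):
        c = unrelated_cohort
        nf = null_model(c["y"], c["X"], c["K"], sample_ids=list(c["ped"].ids))
        beta, *_ = np.linalg.lstsq(c["X"], c["y"], rcond=None)
        # whitening under V = s2*I only rescales; compare unwhitened resid
        sigma = np.sqrt(nf.vc.total)
        np.testing.assert_allclose(nf.rw * sigma, c["y"] - c["X"] @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, related_fit):
        nf = related_fit["nf"]
        assert np.abs(nf.Xw.T @ nf.rw).max() < 1e-8

    def test_dimension_mismatch_rejected(self, small_cohort):
        with pytest.raises(InvalidArgumentError):
            null_model(np.zeros(10), np.ones((10, 1)), small_cohort["K"])


class TestScoreTest:
    def test_matches_ols_score_oracle_under_identity(self, unrelated_cohort):
        """Classical Rao score test, computed by direct projection."""
        c = unrelated_cohort
        y, X, G = c["y"], c["X"], c["G"]
        n, p = X.shape
        nf = null_model(y, X, c["K"], sample_ids=list(c["ped"].ids))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = (r @ r) / (n - p)
        for j in range(G.n_variants):
            g = G.dosages[:, j]
            if np.ptp(g) == 0:
                continue
            cg, *_ = np.linalg.lstsq(X, g, rcond=None)
            gt = g - X @ cg
            chi = (gt @ y) ** 2 / ((gt @ gt) * s2)
            want = stats.chi2.sf(chi, 1)
            got = score_test(nf, g).p
            assert got == pytest.approx(want, rel=1e-6)

    def test_invariant_to_affine_trait_rescaling(self, related_fit, small_cohort):
        y, X = related_fit["y"], related_fit["X"]
        g = related_fit["G"].dosages[:, 0]
        nf1 = related_fit["nf"]
        nf2 = null_model(3.5 * y + 11.0, X, small_cohort["K"],
                         sample_ids=small_cohort["ids"])
        p1 = score_test(nf1, g).p
        p2 = score_test(nf2, g).p
        assert p2 == pytest.approx(p1, rel=1e-4)

    def test_monomorphic_not_testable(self, related_fit):
        nf = related_fit["nf"]
        res = score_test(nf, np.zeros(nf.n))
        assert not res.testable and np.isnan(res.p)

    def test_missing_dosages_mean_imputed(self, related_fit):
        nf = related_fit["nf"]
        g = related_fit["G"].dosages[:, 1].copy()
        g[:5] = np.nan
        res = score_test(nf, g)
        assert res.testable and res.n == nf.n - 5

    def test_causal_variant_detected(self, small_cohort):
        """A strong simulated QTL reaches small p through the mixed model."""
        from metaboqtl.phenosim import QtlEffect

        ped, K_full = small_cohort["ped"], small_cohort["K_full"]
        G = simulate_genotypes(ped, [(0.3, "c")], seed=60)
        cfg = SimulationConfig(
            h2=0.3, c2=0.0, qtls=(QtlEffect("snp00001", 0.6),), seed=61
        )
        ph = simulate_phenotype(ped, K_full, G, cfg, ids=small_cohort["ids"])
        n = len(ph)
        nf = null_model(
            ph["metabolite"].to_numpy(), np.ones((n, 1)), small_cohort["K"],
            sample_ids=small_cohort["ids"],
        )
        g = G.subset_samples(list(small_cohort["ids"])).dosages[:, 0]
        res = score_test(nf, g)
        assert res.p < 1e-6
        assert res.beta == pytest.approx(0.6, abs=0.25)

    def test_scan_agrees_with_single_tests(self, related_fit):
        nf, G = related_fit["nf"], related_fit["G"]
        scan = score_scan(nf, G.dosages, variant_ids=G.variants["id"])
        for j in [0, 3, 7]:
            single = score_test(nf, G.dosages[:, j])
            assert scan["p"].iloc[j] == pytest.approx(single.p, rel=1e-10)
            assert scan["beta"].iloc[j] == pytest.approx(single.beta, rel=1e-10)


class TestGenotypeCodings:
    def test_overdominant_coding(self):
        np.testing.assert_array_equal(
            code_genotypes([0, 1, 2, 1], "overdominant"), [0, 1, 0, 1]
        )

    def test_dominant_recessive_codings(self):
        g = [0, 1, 2]
        np.testing.assert_array_equal(code_genotypes(g, "dominant"), [0, 1, 1])
        np.testing.assert_array_equal(code_genotypes(g, "recessive"), [0, 0, 1])

    def test_uncertain_dosages_set_missing(self):
        out = code_genotypes([0.0, 1.25, 2.0], "recessive")
        assert np.isnan(out[1])

    def test_additive_scan_equals_additive_branch(self, related_fit):
        nf = related_fit["nf"]
        g = related_fit["G"].dosages[:, 2]
        best, table = genotype_model_scan(nf, g)
        add_row = table[table["model"] == "additive"].iloc[0]
        direct = score_test(nf, g)
        assert add_row["p"] == pytest.approx(direct.p, rel=1e-12)

    def test_no_homozygotes_skips_recessive(self, related_fit):
        nf = related_fit["nf"]
        g = (related_fit["G"].dosages[:, 4] > 0).astype(float)  # only 0/1
        _, table = genotype_model_scan(nf, g)
        rec = table[table["model"] == "recessive"].iloc[0]
        assert rec["skipped_reason"] != ""


class TestExplainedVariance:
    def test_agrees_with_squared_correlation(self, related_fit):
        nf, G, y, X = (related_fit[k] for k in ("nf", "G", "y", "X"))
        g = G.dosages[:, 5]
        res = score_test(nf, g)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2_pct = 100 * np.corrcoef(g, resid)[0, 1] ** 2
        assert res.r2_pct == pytest.approx(r2_pct, abs=0.5)

    def test_zero_effect_zero_r2(self, related_fit):
        nf = related_fit["nf"]
        g = related_fit["G"].dosages[:, 6]
        assert explained_variance(nf, g, 0.0) == 0.0

    def test_sd_scale_arithmetic(self):
        """beta = 0.5 SD, MAF 0.3 -> 100 * 0.25 * 0.42 = 10.5 %."""
        assert 100 * 0.5**2 * 2 * 0.3 * 0.7 == pytest.approx(10.5)


class TestThresholdAndInflation:
    def test_metabolome_threshold_division(self):
        thr = metabolome_threshold(5e-8, 42)
        assert thr == pytest.approx(1.19e-9, rel=5e-3)
        assert f"{thr:.1e}" == "1.2e-09"

    def test_single_trait_passthrough(self):
        assert metabolome_threshold(5e-8, 1) == 5e-8

    def test_invalid_counts(self):
        with pytest.raises(InvalidArgumentError):
            metabolome_threshold(5e-8, 0)

    def test_lambda_on_uniform_pvalues(self):
        rng = np.random.default_rng(0)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_lambda_scales_with_chi2_inflation(self):
        rng = np.random.default_rng(1)
        chi = 1.2 * stats.chi2.rvs(1, size=50_000, random_state=2)
        lam = genomic_inflation(stats.chi2.sf(chi, 1))
        assert lam == pytest.approx(1.2, abs=0.03)

    def test_lambda_exact_at_median(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_too_few_pvalues(self):
        with pytest.raises(InsufficientDataError):
            genomic_inflation(np.full(99, 0.5))


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_additive(1000, 0.3, 0.0, 0.05) == pytest.approx(0.05)

    def test_monotone_in_effect_and_n(self):
        p1 = power_additive(1000, 0.3, 0.2, 5e-8)
        p2 = power_additive(1000, 0.3, 0.3, 5e-8)
        p3 = power_additive(2000, 0.3, 0.2, 5e-8)
        assert p1 < p2 and p1 < p3

    @pytest.mark.parametrize("bad", [dict(maf=0.0), dict(maf=0.7), dict(alpha=0.0), dict(n=0)])
    def test_invalid_arguments(self, bad):
        kw = dict(n=100, maf=0.3, beta=0.2, alpha=0.05)
        kw.update(bad)
        with pytest.raises(InvalidArgumentError):
            power_additive(**kw)

    def test_matches_simulation(self):
        """Analytic power vs direct Monte-Carlo of the 1-df Wald chi2."""
        n, maf, beta, alpha = 500, 0.3, 0.15, 0.01
        rng = np.random.default_rng(3)
        hits = 0
        reps = 2000
        for _ in range(reps):
            g = rng.binomial(2, maf, n).astype(float)
            y = beta * g + rng.standard_normal(n)
            r = stats.pearsonr(g, y)
            hits += r.pvalue < alpha
        mc = hits / reps
        ana = power_additive(n, maf, beta, alpha)
        assert ana == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / reps) + 0.01)
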