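# metaboqtl

Metabolite quantitative trait locus (mQTL) analysis for family-based
cohorts, from raw 1D NMR spectra to fine-mapped genetic signals — with a
synthetic-data layer that makes every stage testable without access to
individual-level cohort data.

The package is aimed at statistical geneticists and metabolomics
analysts who want a transparent, fully tested reference implementation
of the classic serum-NMR mQTL pipeline:

1. **NMR quantification** (`metaboqtl.nmr`): peaks in the well-resolved
   J-resolved (JRES) projection are deconvoluted into mixed
   Gauss–Lorentz (pseudo-Voigt) lineshapes
   A·[η·L(x; x₀, w) + (1−η)·G(x; x₀, w)] by windowed Nelder–Mead
   simplex; metabolite intensities are then obtained from the convoluted
   but high-SNR CPMG spectrum by a linear model over the re-broadened
   fitted shapes, and peaks are grouped into metabolites by
   across-sample correlation.
2. **Trait preparation** (`metaboqtl.prep`): ±4 SD outlier removal,
   rank transformation (average ties, missing-aware), sample exclusion,
   partial correlations with risk factors.
3. **Heritability** (`metaboqtl.varcomp`): REML fit of
   y ~ N(Xβ, σ²g·2Φ + σ²c·H + σ²e·I) with pedigree kinship Φ and a
   sibship household matrix H; h² = σ²g/σ²total, c² = σ²c/σ²total.
4. **GWAS** (`metaboqtl.assoc`): family-based score test
   χ²₁ = (g̃ᵀV̂⁻¹r)²/(g̃ᵀV̂⁻¹g̃) against a polygenic null (the
   FASTA/mmscore construction), mode-of-inheritance scanning
   (additive/dominant/recessive/over-dominant), metabolome-wide
   Bonferroni threshold, genomic inflation λ, analytic noncentral-χ²
   power.
5. **Fine-mapping** (`metaboqtl.finemap`): carrier-count filtering,
   dosage LD r², reciprocal conditional score tests, and classification
   of each variant as `explains_lead`, `independent`, `tagged_by_lead`
   or `indistinguishable`.
6. **Synthetic cohorts** (`metaboqtl.pedigree`, `genotypes`, `phenosim`,
   `spectra`): isolate-style pedigrees with households, gene-dropped
   genotypes with block LD, traits with a chosen variance budget, and
   paired CPMG/JRES spectra.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate a small cohort, quantify its spectra, and run a GWAS:

```bash
cat > config.yaml <<EOF
seed: 3
pedigree: {n_founder_couples: 4, n_generations: 2, mean_children: 2.5}
variants: [{maf: 0.3, block: a}, {maf: 0.2, block: b}]
qtls: [{variant: snp00001, beta: 0.4}]
h2: 0.3
c2: 0.05
spectra: {n_metabolites: 3, n_samples: 6}
EOF
metaboqtl simulate config.yaml --out data
metaboqtl quantify --spectra-dir data/spectra --out quant
metaboqtl gwas --phenotypes data/phenotypes.tsv --dosages data/dosages.tsv \
    --variants data/variants.tsv --kinship data/kinship.tsv \
    --out gwas.tsv --threshold-metabolites 42
metaboqtl power --n 2482 --maf 0.15 --beta 0.4
```

The quantify step prints

```
fitted 22 peaks in 9 windows (width scale 2.50); 10 groups; 6/6 spectra passed QC
```

— it recovered the generating CPMG broadening factor (2.5) from the data
and grouped the fitted peaks into candidate metabolites.  The gwas step
prints a JSON line with the cohort bookkeeping and the metabolome-wide
threshold 5×10⁻⁸/42 ≈ 1.19×10⁻⁹, and writes per-variant beta/SE/p/MAF/R²
to `gwas.tsv`.  The power call prints `power = 1.0000 (100.0%)`: at
n = 2,482, MAF 0.15 and a 0.4 SD-per-allele effect, the additive test at
the metabolome-wide level is essentially certain to detect the variant.

The same machinery is available as a library; for instance the
fine-mapping classifier:

```python
from metaboqtl.assoc import null_model
from metaboqtl.finemap import conditional_pair
nf = null_model(y, X, kinship, sample_ids=ids)
res = conditional_pair(nf, g_variant, g_lead)
print(res.p_variant_adj, res.p_lead_adj, res.r2, res.classification)
```

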