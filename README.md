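# gsfix

Genomic selection for biparental crop populations, with two enhancements that
matter in practice: fitting large-effect SNPs as fixed effects, and modelling
genotype-by-environment (G×E) interaction.

The package targets the setting of a maize BC₁F₃:₄ population — an F₁ between
a donor line (Zheng58) and a recurrent line (PH4CV), backcrossed once to the
recurrent parent, bulk-intermated and selfed — phenotyped for a quantitative
trait (days to anthesis) in multiple environments and genotyped with
genome-wide biallelic SNPs coded −1/0/+1.  It provides everything needed to
run and stress-test the full analysis without external data:

- **`synthetic_data`** — meiosis-level simulation of the breeding scheme
  (Haldane model, bulk-pollen random mating) and a multi-environment additive
  trait with configurable QTL, G×E deviations and entry-mean heritability.
- **`pheno_mixed`** — the phenotype mixed model
  `y_ijm = μ + g_i + e_j + ge_ij + δ_(j)m + ε_ijm`, solved by REML through
  Henderson's mixed-model equations: family BLUEs, variance components, and
  entry-mean broad-sense heritability
  `H² = σ²_g / (σ²_g + σ²_ge/Ne + σ²_ε/(r·Ne))`.
- **`kinship_gwas`** — marker QC (parent-missing / non-polymorphic / missing
  rate > 0.05), expected-value imputation, the VanRaden relationship matrix
  `K = WW′ / (2Σ p_j q_j)` with `W = M − P`, a P3D mixed-model GWAS on the
  BLUEs, top-SNP selection by −log₁₀ p, and phenotypic variance explained
  (PVE) from sequential sums of squares of one multiple regression.
- **`gs_engines`** — GBLUP via a deterministic spectral REML solver, a block
  Gibbs sampler (Bayesian ridge / RKHS form), and the three environment
  models: single-environment (SE), across-environment with a common marker
  effect (A-E), and G×E with a shared effect plus environment-specific
  deviations.  Selected large-effect SNPs enter the fixed design and are
  removed from the marker set behind K.
- **`cv_engine`** — repeated 5-fold cross-validation, the CV1 (untested
  lines) and CV2 (untested line×environment cells) schemes, prediction
  accuracy as the Pearson correlation between predicted and observed values,
  sequential t-tests choosing how many top SNPs to fix, a random-SNP null
  distribution, and a marker-assisted-selection (MAS) baseline.
- **`io_cli`** — readers/writers for the study's file dialects (long-format
  phenotype CSV; genotype TSV; VCF import/export), a YAML-configured
  pipeline, and the `gsfix` command line.

## Worked example

Simulate a population, estimate heritability, scan for large-effect SNPs, and
compare prediction accuracy with and without the top SNP fitted as a fixed
effect:

```bash
gsfix simulate --out demo --seed 7 --families 200 --markers-per-chrom 60 --n-envs 4
# wrote 200 families x 600 markers to demo
# mean composition: recurrent hom 0.645, het 0.195, donor hom 0.161

gsfix blue --phenotypes demo/phenotypes.csv --out demo/blue
# H2 = 0.586; BLUEs for 200 families -> demo/blue

gsfix gwas --phenotypes demo/phenotypes.csv --genotypes demo/genotypes.tsv \
      --out demo/gwas --top 20
# top marker chr1_169491525 PVE 63.27% -> demo/gwas

gsfix cv --phenotypes demo/phenotypes.csv --genotypes demo/genotypes.tsv \
      --scheme single --repeats 10 --seed 1 --out demo/cv0
# mean PA: 0.5994
gsfix cv --phenotypes demo/phenotypes.csv --genotypes demo/genotypes.tsv \
      --scheme single --fixed-snps auto:1 --repeats 10 --seed 1 --out demo/cv
# mean PA: 0.7888
```

Reading the output: the simulated BC₁F₃ genomes are on average 64.5%
homozygous for the recurrent parent, 19.5% heterozygous and 16.1% homozygous
for the donor — the single-locus pedigree expectation is 65.6/18.8/15.6%.
The planted major QTL at `chr1_169491525` explains 63% of the variance of
the family BLUEs, and fixing it as a covariate lifts five-fold
cross-validated prediction accuracy from 0.60 to 0.79.  A full pipeline run
(`gsfix run --config config.yaml`) chains all stages and writes per-stage
artifacts plus a JSON summary.

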