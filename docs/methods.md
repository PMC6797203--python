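# Methods

This note documents the models, algorithms and numerical choices behind
`gsfix`, and what the synthetic-data generator does and does not emulate.

## Breeding-scheme simulation

The simulated pedigree follows the construction of the target population:
an F₁ between the donor (Zheng58) and the recurrent parent (PH4CV) is
backcrossed to the recurrent parent to give BC₁F₁ plants; each BC₁F₁ is
pollinated with bulked pollen from the other BC₁F₁ plants (the pollen parent
of every seed is drawn uniformly from the non-self plants, which is the
expectation of a ≥10-plant pollen bulk); a fixed number of plants per
bulk-BC₁F₂ family is selfed once; BC₁F₃ plants are assigned round-robin
across the selfed ears so family sizes stay balanced.  Defaults are 43
BC₁F₂ families × 3 selfed plants and 481 BC₁F₃ plants.

Meiosis uses the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the genetic length in Morgans and breakpoints are
uniform, i.e. no interference.  No genetic map is published for the study's
chip, so the default map is 10 chromosomes of 1.8 M and 200 Mb with markers
placed evenly and genetic position obtained by linear bp↔cM interpolation.
Genotypes are coded +1 = homozygous recurrent, 0 = heterozygous,
−1 = homozygous donor; missing is NaN in memory and `NA` on disk.

Exact single-locus algebra for this pedigree (donor-allele frequency ¼ in
the BC₁F₁ gamete pool, random union, one selfing halving heterozygosity)
gives BC₁F₃ genotype-class probabilities 21/32 : 6/32 : 5/32
(recurrent hom : het : donor hom) = 65.625 / 18.75 / 15.625%.  Because only
43 BC₁F₁ founders and ~18 M of genome are involved, the mean composition of
a 481-plant population has an inherent sampling spread of roughly ±1
percentage point between runs; this is a property of the breeding design,
not of the simulator.

### Trait model

Phenotypes are generated as
`y_ijm = μ_j + Σ_q a_q g_iq + Σ_q d_qj g_iq + δ_(j)m + ε_ijm`, with QTL
additive effects `a_q` acting on the −1/0/+1 codes (heterozygotes contribute
zero additive value), per-(QTL, environment) deviations
`d_qj ~ N(0, σ²_gxe)` shared across replicates (a variance-component reading
of G×E), replicate-within-environment effects and i.i.d. residuals.  The
phenotyped unit of the real study is the selfed family of a genotyped BC₁F₃
plant; the generator uses the family-mean approximation — the BC₁F₃ parent
genotype determines the family's genetic value and within-family segregation
variance is folded into the residual.

When a target entry-mean heritability is requested, the residual sd is
solved from `H² = s_g/(s_g + s_ge/Ne + s_ε/(r·Ne))` using the *realized*
genetic and interaction variances of the simulated population, so the
calibration is exact up to estimation noise.  The default target is
H² = 0.64 with four environments and two replicates, matching the
population the package models.

What the generator does not emulate: dominance and epistasis, selection
during pedigree propagation, sequence-level variation, heterogeneous
per-environment error variances, and spatial field structure.  Tests passing
on synthetic data therefore validate the estimators under the stated model,
not robustness to these departures.

## Phenotype mixed model

BLUEs treat the family effect as fixed (full-rank reference-level contrasts;
reported as μ̂ + ĝ_i, which is contrast-invariant) with environment, G×E and
replicate-within-environment random; variance components re-fit the same
model with the family effect random.  Both are REML solutions.

The solver maximizes the restricted log-likelihood profiled over σ²_ε as a
function of the log variance ratios γ_k = σ²_k/σ²_ε.  Each evaluation
factorizes Henderson's mixed-model equations; the largest random block
(G×E, with ~families × environments levels) is absorbed first by a Schur
complement — a factor's Z′Z is diagonal — which reduces the factorization
from O((p+q)³) to O((p+rest)³) and makes the 481-family fit take seconds.
Two numerical details matter:

- the quadratic form y′Py is computed as ‖y − Wθ̂‖² + Σ_k û_k′û_k/γ_k (two
  positive terms) rather than y′y − θ̂′W′y, whose cancellation noise exceeds
  the curvature of the profile likelihood near its optimum;
- optimization runs L-BFGS-B from two starts (a moment-based start using
  level-mean variances of the OLS residuals, and γ = 1), followed by a
  bounded Nelder-Mead polish started just inside the box so that
  coordinates parked at the zero boundary are re-tested.  Components whose
  log-ratio ends at the lower bound (e^−23) are reported as zero.

On balanced data this REML solution coincides with the ANOVA
expected-mean-squares method of moments; the tests verify agreement to
1e-6.  Convergence is to ~1e-9 in the log-ratios; the returned optimum is
also tested against 100 random parameter draws.

## Kinship, GWAS and PVE

Allele frequencies for the VanRaden matrix are taken from the imputed
sample, not the pedigree expectation.  Missing genotypes are imputed with
the marker's observed mean (the expected code under the observed genotype
frequencies), so imputed values may be fractional.  The QC order is: drop
markers missing in a parent, non-polymorphic between parents, then missing
rate strictly above 0.05.

The association scan fits y* = 1μ + g + wτ + ε with g ~ N(0, Kσ²_u).  The
null-model variance ratio is estimated once by spectral REML on the
eigendecomposition of K and reused for every marker (P3D); each marker is
then a generalized-least-squares fixed effect in the rotated space with a
Wald t-test (df = n − 2, with the residual scale re-estimated per marker so
the K = I, σ²_u = 0 limit reproduces ordinary regression t-tests exactly).
An exact mode re-estimating the variance ratio per marker is available
behind a flag; the tested marker is not removed from K during its own test.
No multiple-testing correction is applied — the procedure ranks markers, it
does not threshold them.

PVE uses one multiple regression of the BLUEs on the top-50 markers (ranked
by −log₁₀ p, ties broken by chromosome and position), decomposed into
sequential Type-I sums of squares in rank order via Gram–Schmidt; aliased
columns are dropped with a warning.  The denominator is the total corrected
sum of squares of the response by default — "phenotypic variance explained"
— with the model sum of squares available as an option, since the two
readings differ and the total-SS convention is the one under which the
reported percentages are variance fractions.

## GS engines

GBLUP is solved deterministically: the restricted likelihood is profiled to
the single ratio γ = σ²_u/σ²_ε on the eigendecomposition of K and optimized
by bounded scalar search (absolute tolerance 1e-11 on log γ); fixed effects
are GLS, genetic values are BLUPs, and out-of-sample lines are predicted
through the kernel cross-covariance K_new,train V⁻¹(y − Xβ̂).  The identity
with marker-effect ridge regression at the matched penalty
λ = (σ²_ε/σ²_u)·2Σp_jq_j is tested to 1e-8.

The Bayesian solver is a block Gibbs sampler for
y = X_f β + Σ_k Z_k u_k + ε with u_k ~ N(0, K_k σ²_k): flat prior on β,
scaled-inverse-χ² priors (df = 5) on all variances with scales set so the
prior mode splits the response variance half to the genetic side (divided
across kernels, normalized by each kernel's mean diagonal) and half to the
residual.  Each kernel's effects are drawn jointly and exactly per sweep:
writing u = E√d·δ from K = E diag(d) E′ and diagonalizing T′T (T = Z E√d)
once as F Λ F′, the conditional posterior of δ in the F-basis has diagonal
precision Λ/σ²_ε + I/σ²_k, so a sweep costs a handful of matrix-vector
products regardless of how records map to lines.  Chains are reproducible
given the seed; default length 20,000 with 5,000 burn-in and thinning 5,
reducible for cross-validation.  With weak data (small n) the df = 5 prior
visibly shrinks the variance split; comparisons against REML are therefore
made at n where the prior weight is a few percent.

The environment models share one code path: per-environment intercepts (the
μ_j vector), fixed-SNP columns common across environments, a shared genetic
kernel (A-E), and for G×E additionally one kernel per environment built
from the same K restricted to that environment's records.  This kernel form
is algebraically identical to decomposing marker effects into a common β₀
plus environment-specific β_i, while avoiding m-dimensional sampling.
Full-data variance decompositions standardize the stacked response to mean
0, variance 1 first; cross-validation works on the original scale, which is
immaterial for Pearson-correlation accuracies.  Fitting large-effect SNPs
as fixed effects removes them from the marker set behind K.

## Cross-validation

One master seed derives every per-repeat fold partition and per-fold chain
seed through `SeedSequence([master, salt, index])`, so any repeat is
re-runnable in isolation and results are bit-reproducible.  K is built once
from all genotypes — genotypes are known for every line; only phenotypes
are masked.  Prediction accuracy pools the validation predictions of all
folds within a repeat before correlating (stabler than per-fold r at n/5
points), then averages over repeats.

CV1 masks a fold's lines in every environment; CV2 masks line×environment
cells, alternating the masked environment within each fold so masked-cell
counts stay balanced.  Multi-environment CV restricts to families
phenotyped in both environments of a pair.

The number of fixed SNPs is chosen by comparing the repeat-level accuracy
vectors of top-n against top-(n−1) markers with a two-tailed Welch t-test
at α = 0.05 (fold partitions shared across n, pairing the repeats; a step
counts only if the mean accuracy increases).  n* is the largest n with an
unbroken chain of significant steps.  Because the same data are reused
across the sequence, the test is anti-conservative: on a marker-free trait
it occasionally selects one spurious marker, which the tests acknowledge
rather than hide.  The random-SNP null repeats the full CV with (default)
200 uniformly drawn marker quadruples; the MAS baseline is plain OLS on the
selected markers within the same fold structure.

## Problem sizes used in the tests

Simulation-based tests run at 120–200 lines with 200–1,200 markers and
Gibbs chains of 1,200–6,000 iterations; the heritability-calibration check
runs at the full 481 families, and the replicate-counting accuracy
comparison uses 100 independently simulated traits.  These sizes were
chosen so the whole suite completes in a few minutes while keeping every
statistical check comfortably powered; all estimator code paths are
identical at larger sizes.

## Known limitations

- REML for the multi-kernel (G×E) model is not implemented; that model is
  fit only by the Gibbs sampler, per the solver split above.
- The sequential t-test inherits the data-reuse anti-conservatism of the
  underlying procedure (see above).
- With two environments the shared and environment-specific kernel
  variances are only weakly separable at a few hundred lines: estimates
  track the realized draw's variance and cross-covariance rather than the
  generating parameters, and recovery tests are framed accordingly.
- VCF import assumes the REF allele is the recurrent parent's; export
  requires hard −1/0/+1 calls.
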