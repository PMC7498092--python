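# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `kineqtl`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Association model

For each gene-SNP pair the linear model is

    y = C a + g b + e,    e ~ N(0, s^2 K)

with *y* log2-CPM expression, *g* minor-allele dosage in {0,1,2}, *C* the
covariate design (intercept; breed 2 levels and batch 5 levels as
reference-coded indicators; RIN and age in days as numeric columns) and
*K* the pedigree numerator relationship matrix used **verbatim** as the
error covariance — no variance-component estimation is performed, which
mirrors the fixed-covariance design this pipeline reproduces and keeps
the scan a single pass of matrix products. All statistics are invariant
to a global rescaling of *K* (tested), so the choice of A versus A/2
versus a correlation-form kinship is immaterial.

Computation: Cholesky L L' = K (with ridge, below); whiten y, g and C by
L^-1; project out the whitened C via its QR factor; the partial
correlation r of the residualized vectors gives t = r sqrt(df/(1-r^2)),
df = n - k - 1 (k = columns of C). The reported effect is the GLS slope
on the original scale. The ANOVA variant encodes the observed genotype
classes as indicators (df_num = classes - 1, adaptive: 1 when only two
classes segregate) and F-tests the nested models. With K = I and C =
intercept the linear test reduces exactly to the Pearson-correlation
t-test (tested).

Batching: genes are processed in chunks (`ScanConfig.chunk_size`, default
512); results are bitwise identical across chunkings (tested). Degenerate
pairs — dosage collinear with covariates after whitening, zero residual
expression variance, a single genotype class — keep their record with a
reason code and NaN statistics so the count contract (genes x SNPs per
model) always holds.

Cis/trans: a pair is *cis* iff same chromosome and the SNP position lies
in [gene start - d, gene end + d], d = 1 Mb, 1-based and boundary
inclusive; the window anchors on the gene interval, not the TSS.
BH-FDR is applied per (model x cis/trans) partition by default
(`fdr_partition="model"` pools cis+trans instead); partition-wise
adjustment mirrors how such scans report per-analysis FDR columns.

## Genotype QC

Dosages are first re-oriented per SNP so 2 = homozygote minor. The MAF
filter keeps MAF >= 0.3 **inclusive** (a threshold meant to remove
underpowered SNPs naturally keeps its boundary), computed on all samples
jointly. Missing genotypes are not supported: the loader rejects anything
outside {0,1,2} with a clear message (mean imputation is noted as future
work). The LD pass is a single left-to-right walk per chromosome; the
current block absorbs the next SNP iff its dosage R^2 with **every**
current member is >= 0.9 — an all-pairwise rule, deliberately not
transitive (tested with a constructed chain). The tag is the first member
by position: deterministic and order-stable. Blocks restart at chromosome
boundaries only, not at large physical gaps.

## Expression preparation

TMM follows the published recipe: reference = sample whose
upper-quartile/library-size fraction is closest to the mean of those
fractions; M and A values over genes positive in both sample and
reference; two-sided trims of 30% (M) and 5% (A) by ranks; factor =
2^(weighted mean of surviving M) with delta-method inverse-variance
weights; factors centered to geometric mean 1. The implementation is
cross-checked in the tests against a loop-based reimplementation and
against Bioconductor edgeR's `calcNormFactors` (agreement to 1e-6).
Expression values are log2((count + 0.5)/effective library size x 1e6).

Filters, in pipeline order: (1) count filter on **raw** counts (>= 5
reads in >= 11 samples, both bounds inclusive; 11 being the smaller breed
group so a group-specific gene can survive); (2) single-observation
outlier filter on **normalized** expression: a gene is removed iff any
|z| > 3 where z is computed per gene across samples. The z-rule is
two-sided — "a single extreme observation" is read as distance from the
mean in either direction — and applied on log-CPM because the log scale
stabilizes variance; constant genes (sd = 0) are kept with z defined 0.
The analysis set is (DEG list ∪ mitochondrial list) ∩ filter survivors;
both lists are plain input files, their derivation is out of scope.

## Kinship

The tabular method on a pedigree truncated to 4 ancestral generations:
a(i,i) = 1 + a(sire,dam)/2, a(i,j) = (a(j,sire) + a(j,dam))/2, unknown
parents contribute 0. Truncation counts parent steps per focal animal
(not calendar generations); ancestors at the horizon become founders.
Output is symmetric PSD with diagonal >= 1 (tested, including against a
gene-dropping Monte-Carlo oracle at 1e5 drops).

## Permutation ("bootstrap") validation

The null shuffles each SNP's dosage vector independently across samples —
expression, covariates and kinship untouched — and re-runs the full scan;
default 1000 iterations (configurable; reduced sizes are used in tests
and the acceptance script, see below). Note two properties of this
scheme, by design: it is permutation *without* replacement despite the
"bootstrap" name, and per-SNP shuffling also destroys LD between SNPs in
the null. Per iteration and partition the count of p < 0.01 and the
1st/10th/100th smallest p-values are recorded. The observed count is
scored one-sided: z against the permutation counts' mean/sd and the
upper-tail normal probability (probabilities below 2.2e-16 are printed
as "< 2.2e-16"); order-statistic exceedance uses strict inequality.
Iteration i draws from seed (base seed + i + 1), so any iteration can be
reproduced in isolation and results do not depend on execution order.

## Enrichment and QTL overlap

The top trans set is sized by the surplus of low p-values:
max(0, round(#{p < 0.01} - 0.01 N)); an explicit k may be given instead.
Ties at the selection boundary break by (snp_id, gene_id). The Fisher 2x2
deliberately mixes **pair counts with gene multiplicity** in the top set
against a plain gene **set** background (the analysis set, or all
expressed genes): a gene hit by many eQTLs counts once per pair. This
asymmetric construction is what the reported fold changes rest on; a
deduplicated variant (`dedupe=True`) is available. The test is two-sided
(depletion is as reportable as enrichment). When a category is absent
from the background the fold is undefined (reported with a reason) but
the exact test still runs. QTL overlap: SNP loci are ±100 kb flanks,
gene loci the unextended interval; all interval ends inclusive, BED input
converted from 0-based half-open on read.

## Synthetic data generator

The generator reproduces the statistical structure the scan assumes, at
the study's dimensions: 11 + 27 samples in two breed groups by default.

- **Pedigree**: separate founder pools per breed (confounding breed with
  relatedness clusters, as in a real two-breed design), 4 simulated
  generations, litters of 1-2 so full sibs occur; `unrelated=True` makes
  every sample a founder (A = identity), letting the whitening step be
  tested as a no-op.
- **Genotypes**: founder allele frequencies uniform on
  [MAF_min + 0.05, 0.5] so the MAF filter is achievable; gene dropping
  through the pedigree guarantees Mendelian consistency at every SNP.
  LD blocks are built at the *founder haplotype* level: each member
  copies the block seed's founder alleles with flip probability 0.01 and
  shares the block's transmission draws (complete within-block linkage).
  A copy whose realized dosage R^2 against any member falls below 0.9 is
  degraded to an exact copy, so the block guarantee holds by
  construction. (Flipping dosages post hoc, the obvious simpler scheme,
  would break Mendelian inheritance; the haplotype-level formulation
  keeps both properties.)
- **Covariates**: breed from group membership; 5 batch levels assigned by
  random permutation of a balanced pool; RIN ~ N(8, 0.5); age ~
  N(160, 10) days.
- **Expression**: negative-binomial counts, log link. log-mean = gene
  baseline (log N(log 200, 0.7) — typical for count-filtered bulk
  RNA-seq genes) + library offset (log sd 0.3) + covariate effects drawn
  per gene on standardized design columns + planted genotype effects +
  optional polygenic term with covariance polygenic_var x sigma_g^2 x A.
  Dispersion alpha = 0.1 (var = mu + alpha mu^2), a realistic biological
  CV of ~0.3 for bulk tissue. The real study's dispersion and covariate
  magnitudes are unknown; these defaults are config-exposed, not
  asserted.
- **Planted effects**: |beta| = m x sigma_g with sigma_g =
  sqrt(1/mu_g + alpha) the gene's approximate log-scale noise sd, so the
  config's effect size m is directly "effect in noise-sd units". Additive
  effects act on centered dosage; optional non-additive effects shift
  heterozygotes only (detectable by ANOVA, not the linear model). At most
  **one effect is planted per gene**: stacking several strong effects on
  one gene inflates its residual variance and silently shrinks every
  planted effect below its nominal noise-sd multiple, which would make
  the truth ledger's effect sizes uninterpretable. Cis pairs are drawn
  from SNPs within 1 Mb of the gene (relocating the gene next to a SNP if
  none exists); trans pairs from other chromosomes.

### What the generator does not emulate

No realistic haplotype structure or recombination maps (blocks are
exact-copy families, between-block transmission is independent); no
sequence-level artifacts (GC bias, mapping error); no expression
networks — genes are conditionally independent given genotype, covariates
and the polygenic term. Passing tests therefore demonstrate correctness
of the *inference machinery* under the model's assumptions, not
robustness to real-data pathologies beyond NB noise.

### A finite-sample property worth knowing

At n = 38, tests of a gene carrying a strong (2 noise-sd) planted effect
against *unrelated* null SNPs reject at roughly twice the nominal 0.01
rate, because the null SNP's chance sample correlation with the causal
SNP leaks signal; tests on genes with no planted effect are exactly
calibrated (measured 0.0100 in the suite's diagnostics). The
surplus-sized top set consequently contains such contamination pairs;
they are concentrated on the planted genes and so carry the same category
composition, which is why the enrichment analysis remains valid. This is
a property of small-n mass-univariate scans generally, not of this
implementation.

## Numerical choices

- Whitening uses Cholesky of K + 1e-8 x mean(diag K) x I; the ridge is
  configurable and the non-PSD error names the offending eigenvalue.
- Collinearity threshold for "untestable": residual norm below 1e-8
  relative to the whitened norm.
- Correlations are clipped to [-1, 1] before the t transform; RSS
  differences are floored at 0 before the F transform.
- BH-FDR delegates to statsmodels (`fdr_bh`), verified against the
  step-up formula; Fisher exact delegates to scipy, verified against
  exhaustive hypergeometric enumeration.
- All randomness flows through numpy Generators seeded from named
  substreams of a single config seed; identical configs give
  byte-identical serialized outputs (tested end to end).

## Problem sizes used in tests and the acceptance script

The full design (1425 genes x 19179 tag SNPs x 1000 permutations) is a
cluster-scale computation; the package's correctness does not depend on
size, so the suite exercises reduced dimensions chosen for statistical
power of each check: oracle equivalence on 20 fixtures of 5 x 20 pairs;
null calibration on 200 genes x 500 SNPs (~1e5 tests, 3-binomial-sd
band); permutation validation on 20 genes x 100 SNPs with 200 rescans
(20 planted effects give observed counts ~10 null sd above the
permutation mean, so exceedance 0 is expected, while the null branch sits
inside the central 95%); recovery on 20 replicates of 30 genes x 150
SNPs; enrichment on 400 genes x 120 SNPs with 150 planted trans effects
drawn 3x preferentially from a 130-gene category — sized so the Fisher
test resolves the induced fold (~1.4) at p < 0.01 per replicate. The
count contract for the full design is verified arithmetically.

## Known limitations

- No variance-component (mixed-model) estimation: K is taken as given.
  If the true polygenic fraction varies by gene, calibration depends on
  the supplied K being adequate.
- No missing-genotype support; no X-chromosome dosage compensation.
- The ANOVA model at n = 38 with a thin genotype class is fragile; such
  pairs are reported, with small df_num, rather than suppressed — screen
  by class counts when interpreting.
- Permutation preserves neither LD nor relatedness structure in the
  null; alternatives (residual rotation, restricted permutation) are out
  of scope.
- The t-test on NB log-CPM is ~2% relatively anti-conservative at the
  0.01 level for n = 38 (visible only at >1e5-test resolution).
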