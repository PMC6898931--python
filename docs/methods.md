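# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## RFI derivation

RFI is the residual of an ordinary least-squares regression of daily
feed intake (kg/day) on an intercept, average daily gain (kg/day),
metabolic mid-weight and test-group indicators. Metabolic mid-weight
is the pre-exponent mid-test weight (kg) raised to 0.73 inside the fit;
0.75 is the other convention in the literature and is available through
`mmwt_exponent`. Test groups are treatment-coded against the
first-observed level; because only residuals are consumed downstream,
the contrast choice is immaterial. Residuals are exactly zero-mean
within every group (an OLS identity, asserted to 1e-10 in the tests).
Rank-deficient designs — constant covariates, groups that alias other
columns — are rejected with the offending column names rather than
silently dropped.

## Genotype QC

Filter order: sample call rate (≥ 0.95, computed on the full SNP set),
then per-SNP call rate (≥ 0.95), MAF (≥ 0.01) and Hardy-Weinberg
equilibrium (p ≥ 1e-6), all recomputed on surviving samples. The HWE
test is the 1-df chi-square goodness-of-fit against expected
proportions at the estimated allele frequency; monomorphic sites pass
trivially (p = 1). An exact test would differ at very low minor-allele
counts, but such SNPs are removed by the MAF filter first; the
chi-square is deterministic and directly testable (50/0/50 gives
statistic 100 exactly). Imputation accuracy offers two conventions
because published "accuracy" is ambiguous: mean per-SNP Pearson
correlation over SNPs polymorphic in both matrices, and overall
genotype concordance.

## Mixed-model GWAS

* **GRM** — VanRaden method 1: `G = ZZ'/(2Σ p_j q_j)` with `Z` the
  dosage matrix centered at twice the allele frequency; missing
  dosages are mean-imputed before centering and monomorphic SNPs are
  skipped. Under Hardy-Weinberg-consistent simulation the mean
  diagonal sits near 1 (asserted within [0.95, 1.05]).
* **REML** — the restricted likelihood is profiled over the total
  variance and maximized over h² on [1e-6, 1−1e-6] by bounded scalar
  search (xatol 1e-9), after one eigendecomposition of the
  ridge-adjusted GRM (ridge 1e-6 on the diagonal, a PSD safeguard far
  below test tolerances). Flat profiles (e.g. an identity-like GRM,
  where σ²_a and σ²_e are unidentifiable) and optima at a bound are
  flagged, not errors.
* **Per-SNP tests** — variance components are estimated once and the
  variance *ratio* is fixed for every SNP test; each SNP is a weighted
  regression in the GRM eigenbasis with weights `1/(h²·d_i + 1 − h²)`.
  The residual scale is re-estimated per SNP from the weighted residual
  sum of squares, which makes the scan collapse exactly to ordinary
  least squares when h² = 0 and keeps it identical to the dense
  `V⁻¹`-based GLS oracle (asserted to 1e-8). Wald p-values use the
  standard normal reference — appropriate for the cohort sizes this
  targets (hundreds to thousands); at very small n this is
  anti-conservative and a t reference would be preferable.
* **Thresholds and regions** — Bonferroni 0.05/m and suggestive
  p < 5e-5 (−log10 = 4.301), both configurable. QTL regions merge
  suggestive SNPs on a chromosome whose ±1 Mb flanks overlap; the top
  SNP is the member with the largest −log10 p, ties broken by smaller
  position so reports are deterministic.
* **Additive/dominance decomposition** — genotype re-fitted as a
  3-level class (all classes ≥ 2 animals required) in the same rotated
  GLS; `a = (AA−BB)/2`, `d = AB − (AA+BB)/2`, with a normal Wald test
  on the dominance contrast.
* The candidate SNP is not removed from the GRM (no
  leave-one-chromosome-out); with dense panels this causes mild
  proximal contamination, accepted here for fidelity to the one-GRM
  design.

## Expression association

Genes with zero counts in every sample are removed — literally "no
expression", so a single read keeps a gene. TMM factors follow the
published recipe: reference sample chosen by upper-quartile count
fraction closest to the mean; genes zero in either sample excluded;
M values double-trimmed (30% on M, 5% on A, rank-based with average
ties); factor = 2^(precision-weighted mean of surviving M values) with
inverse asymptotic binomial variances as weights; factors rescaled to
geometric mean 1. The implementation matches both a brute-force
reimplementation and the Bioconductor reference to ≤ 1e-6 on a
negative-binomial fixture. log₂ CPM uses a prior count of 0.5 with a
doubled prior in the denominator:
`lcpm = log2((count + 0.5)/(eff_lib + 1) · 1e6)`; the offset is stated
bit-exactly because published analyses rarely specify it and results
near zero counts depend on it.

Per gene, RFI is regressed on lcpm — trait as response, matching the
convention that a positive effect means up-regulation in inefficient
animals. The slope's two-sided t-test uses n−2 df. Datasets
(tissue × sex cohorts) are processed independently; no cross-dataset
batch model is attempted, and opposite-signed effects for the same gene
across tissues are reported as-is. GSA p-values are raw (no
multiple-testing correction), mirroring the genome-wide p < 0.001 /
in-window p < 0.05 two-threshold scheme this pipeline supports.

## Integration

Windows are parameterized by half-width: a "2 Mb window" around a SNP
at 4.88 Mb means ±1 Mb, i.e. 3.88–5.88 Mb. Candidate-gene and GSA
windows default to 1 Mb half-width each. Gene–window overlap is
any-overlap on 0-based half-open intervals (recall over precision);
distance is 0 when the SNP lies inside the gene (no intron/exon
resolution) and otherwise the bp gap to the nearer edge. Nearest-gene
ties go to the smaller start coordinate. Regions on gene-free stretches
produce empty-but-present records; a complete chromosome-naming
mismatch between inputs is an error listing both name sets.

## Synthetic data

The generator exists to give every stage a parameter-recovery surface,
not to be a population-genetic simulator.

* **Genotypes** — within fixed-size LD blocks (default 20 SNPs) each
  sample chromosome copies one of 16 founder haplotypes; founder
  alleles follow a persistent Markov chain (stay probability 0.9) along
  the block so adjacent-SNP dosage correlation is positive, as
  region-merging tests require. Allele frequencies are uniform on
  [0.05, 0.5] by default; missingness is completely at random (no
  mechanism is described for the real data). No coalescent realism, no
  recombination gradient, no population structure beyond family-free
  exchangeability.
* **Phenotypes** — the trait is polygenic value + QTL contributions +
  Gaussian noise. Polygenic effects are i.i.d. normal per SNP with
  total variance σ²_a/(2Σpq), exactly the model the GRM-REML machinery
  assumes — so heritability-recovery tests validate the estimator, not
  robustness to model misspecification. The heterozygote receives the
  dominance deviation on top of the additive dose. Feed intake is
  assembled from the RFI regression's own coefficients (defaults
  β0 = 1, β1 = 1.5, β2 = 0.09, ADG ~ N(1.5, 0.2²) kg/day,
  MWT ~ N(400, 40²) kg — plausible feedlot-steer values chosen once;
  the source cohort's distributions are not published). Contemporary
  group equals test group in simulated data.
* **Expression** — expected log₂ CPM is baseline + slope × standardized
  RFI for designated genes; CPMs are rescaled to sum to 1e6, library
  sizes vary uniformly ±30% around the target, counts are negative
  binomial (`var = μ + φμ²`, default φ = 0.1). Because the pipeline
  regresses the trait on lcpm (the inverse of the planted direction),
  fitted slopes are not numerically the planted ones — only sign and
  significance recovery are asserted.

## Problem sizes and calibration checks

Heritability recovery uses 20 replicates at n = 500, 2000 SNPs with
σ²_a = 0.827 and σ²_e = 1.929 (true h² = 0.30); the replicate mean is
asserted within ±0.05. Null calibration runs one scan at n = 500 with
5000 SNPs simulated *without* LD: the inflation factor measures test
calibration, and LD between tests only widens the sampling noise of the
median without moving its expectation (with 20-SNP blocks the 5000
tests collapse to ~250 effective ones and λ's seed-to-seed sd grows to
≈ 0.06). The end-to-end recovery check plants one strong QTL and one
adjacent high-signal expression gene at n = 400 and requires joint
recovery in ≥ 19 of 20 seeds. These sizes keep the whole suite in the
low minutes on a single core while leaving each assertion's sampling
band comfortably wide.

## Known limitations

Single-trait, single-GRM models only; no leave-one-chromosome-out, no
dominance GRM, no epistasis, no fine-mapping. VCF support is GT-only
biallelic; no phasing, no INFO parsing, no bgzip/tabix. Genotype
imputation and read-level RNA-seq processing are upstream of this
package's scope. The chi-square HWE test (not exact) and the normal
Wald reference are documented approximations.
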