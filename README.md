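# rfi-integrate

A tested, reusable pipeline for a classic question in beef-cattle
genetics: which genomic regions and which expressed genes underlie
variation in **residual feed intake (RFI)**, the standard measure of
feed efficiency? Lower RFI means an animal eats less than predicted
from its growth and size — an economically and environmentally
important trait. The package is aimed at quantitative geneticists and
animal scientists who want the full chain — phenotype derivation,
genotype QC, mixed-model GWAS, expression association, and signal
integration — as composable, unit-tested Python, exercised end-to-end
on synthetic data with known ground truth.

## The models

**RFI derivation.** Daily feed intake is regressed on growth and
metabolic size,

    Y_i = β0 + β1·ADG_i + β2·MWT_i^0.73 + TestGroup_i + e_i

and the residual `e_i` *is* the RFI phenotype (ADG: average daily gain,
kg/day; MWT: mid-test weight, kg, raised to the metabolic exponent
0.73, overridable to 0.75).

**Mixed-model association.** Each SNP `j` is tested in

    y = μ + cg + g_j·α + a + e,   var(a) = G·σ²_a,   var(e) = I·σ²_e

with `cg` the contemporary groups, `g_j` the dosage of the counted
allele, `α` the allele-substitution effect, and `G` the VanRaden
genomic relationship matrix `ZZ'/(2Σp_jq_j)`. Variance components are
estimated once by REML and held fixed for every SNP (EMMAX-style); a
single eigendecomposition of `G` turns each SNP test into one weighted
regression. The scan reports Wald p-values, the genomic inflation
factor `λ = median(χ²)/0.455`, the percent of additive variance each
SNP explains (`100·2pqα²/σ²_a`), and QTL regions built by merging
suggestive SNPs (−log10 p ≥ 4.3) whose ±1 Mb flanks overlap. Top SNPs
can be re-fitted with genotype as a 3-level class to decompose
`a = (AA−BB)/2` and dominance `d = AB − (AA+BB)/2`.

**Expression association.** Per tissue/sex dataset, gene counts are
TMM-normalized, converted to log₂ CPM, and RFI is regressed on each
gene's lcpm (trait as response — the slope sign says whether expression
rises with inefficiency). Significant genes are intersected with
windows around the QTL top SNPs.

## Worked example

Simulate a 400-animal, 400-SNP cohort with one planted QTL (α = 1) and
one gene whose expression tracks RFI, then run the whole chain:

```python
import numpy as np, pandas as pd
from rfi_integrate import synthetic_data as syn
from rfi_integrate.rfi_derivation import fit_rfi
from rfi_integrate.genotype_qc import apply_qc
from rfi_integrate.mlm_gwas import (compute_grm, fit_variance_components,
    run_scan, define_qtl_regions)
from rfi_integrate.expression_assoc import (filter_unexpressed,
    tmm_factors, log_cpm, gene_rfi_association)
from rfi_integrate.integration import integrate

chrom_lengths = {"1": 10_000_000}
g = syn.simulate_genotypes(400, 400, seed=11, chrom_lengths=chrom_lengths)
qtl_pos = int(g.snp_map.loc[200, "pos"])
models = syn.simulate_gene_models(chrom_lengths, 150, seed=12)
target = models.data.loc[(models.data["start"] - qtl_pos).abs().idxmin(),
                         "gene_id"]
truth = syn.SimulationTruth(qtl_snps=[(200, 1.0, 0.0)], sigma_a2=0.3,
    sigma_e2=0.5, gsa_genes=[(target, 1.5)], seed=13)
table, _ = syn.simulate_feedlot_phenotypes(g, truth, n_groups=5)

fit = fit_rfi(table)                      # residuals define RFI
g_qc, report = apply_qc(g)                # MAF/HWE/call-rate filters
y = fit.residuals.to_numpy()
X = np.column_stack([np.ones(len(table)),
    pd.get_dummies(table.data["cg"]).to_numpy(float)[:, 1:]])
grm = compute_grm(g_qc)
vc = fit_variance_components(y, X, grm)
scan = run_scan(y, X, g_qc, vc, grm=grm)
regions = define_qtl_regions(scan)

expr_rfi = pd.Series(y[:50], index=g.sample_ids[:50])
cm = filter_unexpressed(syn.simulate_expression(expr_rfi.to_numpy(),
    models, truth, dispersion=0.05, seed=14,
    sample_ids=list(expr_rfi.index)))
norm = log_cpm(cm, tmm_factors(cm))
gsa = gene_rfi_association(norm.lcpm, expr_rfi, "synthetic_liver")
print(integrate(regions, [gsa], models).to_json())
```

Output (abridged):

```
feed-intake fit: beta1=1.268 beta2=0.0927 r2=0.269
QC: 400 -> 391 SNPs, 400 -> 400 samples
REML: h2=0.49 sigma_a2=0.494 sigma_e2=0.513
QTL region chr1:5090516-5341102 top=snp000201 (pos 5090516, -log10p=7.4, n_sig=4)
window 4090516-6090516: 31 genes, nearest=gene00083,
  GSA hits=[('gene00081', -0.934, 0.0206), ('gene00083', 0.59, 0.0), ...]
planted: 5090516 gene00083
```

The planted SNP (index 200, position 5,090,516) is the scan's top hit,
its ±1 Mb candidate window recovers the planted expression gene
`gene00083` as both the nearest gene and a GSA hit with p ≈ 0. The
REML h² (0.49) exceeds the polygenic 0.3/0.8 = 0.375 because the
planted QTL's variance is itself tagged by the GRM, and λ on only 400
LD-correlated SNPs is noisy — both expected at this toy size.

A `rfi-integrate` CLI mirrors the library
(`convert`, `rfi`, `qc`, `gwas`, `expr`, `integrate`); run
`rfi-integrate --help`.

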