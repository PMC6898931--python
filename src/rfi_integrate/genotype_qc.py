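"""SNP and sample quality control plus imputation-accuracy metrics.

Filter order: sample call rate first (on the full SNP set), then SNP
call rate, minor allele frequency and Hardy-Weinberg equilibrium, all
recomputed on the surviving samples.  Defaults mirror common GWAS
practice: samples with < 95% valid genotypes are dropped, as are SNPs
with > 5% missingness, MAF < 0.01 or an HWE chi-square p below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix


@dataclass
class QCReport:
    snp: pd.DataFrame        # snp_id, call_rate, maf, hwe_p, kept, reasons
    sample: pd.DataFrame     # sample_id, call_rate, kept
    n_samples_before: int
    n_samples_after: int
    n_snps_before: int
    n_snps_after: int


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """One-df chi-square goodness-of-fit p-value against HWE proportions.

    Expected genotype counts come from the allele frequency estimated on
    the same counts; a monomorphic site fits HWE trivially (p = 1).
    """
    counts = np.array([n_AA, n_AB, n_BB], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one genotype required")
    p = (2 * n_AA + n_AB) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP counts of the three dosage classes (2, 1, 0)."""
    return np.stack([np.nansum(dosages == v, axis=0) for v in (2.0, 1.0, 0.0)],
                    axis=1)


def snp_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF and HWE p-value.

    MAF is the folded frequency of allele1 over non-missing calls; an
    all-missing SNP gets call_rate 0 and NaN MAF/HWE.
    """
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    D = g.dosages
    n_obs = (~np.isnan(D)).sum(axis=0)
    call_rate = n_obs / g.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.nansum(D, axis=0) / (2.0 * n_obs)
    freq1 = np.where(n_obs > 0, freq1, np.nan)
    maf = np.minimum(freq1, 1.0 - freq1)
    counts = _genotype_counts(D)
    hwe_p = np.array([
        hwe_test(*counts[j]) if n_obs[j] > 0 else np.nan
        for j in range(g.n_snps)])
    return pd.DataFrame({
        "snp_id": g.snp_map["snp_id"],
        "call_rate": call_rate,
        "maf": maf,
        "hwe_p": hwe_p,
    })


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    snp_callrate_min: float = 0.95,
    sample_callrate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples then SNPs; report every exclusion with its reason."""
    for name, v in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                    ("snp_callrate_min", snp_callrate_min),
                    ("sample_callrate_min", sample_callrate_min)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1]")

    sample_cr = (~np.isnan(g.dosages)).mean(axis=1)
    sample_kept = sample_cr >= sample_callrate_min
    sample_df = pd.DataFrame({"sample_id": g.sample_ids,
                              "call_rate": sample_cr,
                              "kept": sample_kept})
    if not sample_kept.any():
        raise ValueError("empty after QC: no sample passes the call-rate "
                         "threshold")

    surv = g.subset(sample_idx=np.nonzero(sample_kept)[0])
    stats_df = snp_stats(surv)
    reasons = []
    for row in stats_df.itertuples(index=False):
        r = []
        if row.call_rate < snp_callrate_min:
            r.append(f"call_rate<{snp_callrate_min}")
        if np.isnan(row.maf) or row.maf < maf_min:
            r.append(f"maf<{maf_min}")
        if np.isnan(row.hwe_p) or row.hwe_p < hwe_p_min:
            r.append(f"hwe_p<{hwe_p_min}")
        reasons.append(";".join(r))
    snp_df = stats_df.assign(kept=[not r for r in reasons], reasons=reasons)
    if not snp_df["kept"].any():
        raise ValueError("empty after QC: no SNP passes all filters")

    kept = surv.subset(snp_idx=np.nonzero(snp_df["kept"].to_numpy())[0])
    report = QCReport(
        snp=snp_df,
        sample=sample_df,
        n_samples_before=g.n_samples,
        n_samples_after=kept.n_samples,
        n_snps_before=g.n_snps,
        n_snps_after=kept.n_snps,
    )
    return kept, report


def imputation_accuracy(
    true_g: GenotypeMatrix, imputed_g: GenotypeMatrix
) -> tuple[float, float]:
    """Per-SNP dosage correlation (averaged) and overall concordance.

    Correlation averages Pearson r over SNPs polymorphic in both
    matrices, computed on jointly non-missing entries; concordance is
    the fraction of exactly matching dosages over those entries.
    """
    if true_g.dosages.shape != imputed_g.dosages.shape:
        raise ValueError("genotype matrices differ in shape")
    if not true_g.snp_map["snp_id"].equals(imputed_g.snp_map["snp_id"]):
        raise ValueError("SNP maps differ")
    T, I = true_g.dosages, imputed_g.dosages
    joint = ~np.isnan(T) & ~np.isnan(I)
    if not joint.any():
        raise ValueError("no jointly observed genotypes")
    concordance = float((T[joint] == I[joint]).mean())
    rs = []
    for j in range(T.shape[1]):
        mask = joint[:, j]
        if mask.sum() < 2:
            continue
        t, i = T[mask, j], I[mask, j]
        if t.std() == 0 or i.std() == 0:
            continue
        rs.append(np.corrcoef(t, i)[0, 1])
    correlation = float(np.mean(rs)) if rs else float("nan")
    return correlation, concordance
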