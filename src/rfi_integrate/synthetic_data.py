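"""Synthetic genotypes, feedlot phenotypes, gene models and RNA-seq counts.

Every generator is seeded and deterministic, and the planted ground
truth travels alongside the data in a :class:`SimulationTruth` record so
each downstream stage has a parameter-recovery surface:

* genotypes — diploid dosages drawn from a small pool of block
  haplotypes, giving positive short-range linkage disequilibrium;
* feedlot phenotypes — daily feed intake built from the classical RFI
  regression (intercept + ADG + metabolic mid-weight + test group) with
  the residual being a trait composed of a polygenic value, optional
  per-SNP additive/dominance QTL effects and i.i.d. noise;
* gene models — non-overlapping intervals on the simulated chromosomes;
* expression — negative-binomial counts whose expected log2 CPM depends
  linearly on standardized RFI for designated genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    GenotypeMatrix,
    FeedlotTable,
    GeneModelSet,
    CountMatrix,
    GENE_MODEL_COLUMNS,
    SNP_MAP_COLUMNS,
)


@dataclass
class SimulationTruth:
    """Planted parameters behind one simulated dataset.

    ``qtl_snps`` holds ``(snp_index, additive, dominance)`` triples; the
    heterozygote receives the dominance deviation on top of the additive
    dose.  ``eq1_coeffs`` are the intercept and partial regressions of
    feed intake on ADG and metabolic mid-weight.  ``gsa_genes`` are
    ``(gene_id, slope)`` pairs: genes whose expected log2 CPM shifts by
    ``slope`` per standard deviation of RFI.
    """

    qtl_snps: list[tuple[int, float, float]] = field(default_factory=list)
    sigma_a2: float = 0.0
    sigma_e2: float = 1.0
    group_effects: dict[str, float] = field(default_factory=dict)
    eq1_coeffs: tuple[float, float, float] = (1.0, 1.5, 0.09)
    gsa_genes: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0:
            raise ValueError("sigma_a2 must be >= 0")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be >= 0")
        if len(self.eq1_coeffs) != 3:
            raise ValueError("eq1_coeffs must be (beta0, beta1, beta2)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["qtl_snps"] = [tuple(t) for t in d["qtl_snps"]]
        d["gsa_genes"] = [tuple(t) for t in d["gsa_genes"]]
        d["eq1_coeffs"] = tuple(d["eq1_coeffs"])
        return cls(**d)


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range=(0.05, 0.5),
    ld_block_size: int = 20,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    n_founder_haplotypes: int = 16,
) -> GenotypeMatrix:
    """Simulate diploid dosage genotypes with block-wise LD.

    Within each block of ``ld_block_size`` consecutive SNPs, every
    sample chromosome copies one of ``n_founder_haplotypes`` founder
    haplotypes whose alleles are Bernoulli draws at a frequency sampled
    uniformly from ``maf_range``; adjacent SNPs therefore share the
    copying pattern and are positively correlated.  Blocks never span a
    chromosome boundary.  Missingness is completely at random.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")

    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {"1": max(1_000_000, n_snps * 5_000)}

    # distribute SNPs across chromosomes proportional to length
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(n_snps * lengths / lengths.sum() - alloc)):
        if alloc.sum() >= n_snps:
            break
        alloc[i] += 1
    alloc[np.argmax(lengths)] += n_snps - alloc.sum()

    dosages = np.empty((n_samples, n_snps))
    map_rows = []
    col = 0
    for chrom, m_c in zip(chroms, alloc):
        if m_c == 0:
            continue
        length = chrom_lengths[chrom]
        mean_gap = max(1, length // (m_c + 1))
        gaps = rng.integers(1, 2 * mean_gap + 1, size=m_c)
        pos = np.cumsum(gaps)
        for start in range(0, m_c, ld_block_size):
            bs = min(ld_block_size, m_c - start)
            freqs = rng.uniform(lo, hi, size=bs)
            # founder haplotypes follow a persistent Markov chain along
            # the block so neighbouring SNPs are positively correlated
            founders = np.empty((n_founder_haplotypes, bs), dtype=np.int8)
            founders[:, 0] = rng.random(n_founder_haplotypes) < freqs[0]
            for j in range(1, bs):
                fresh = (rng.random(n_founder_haplotypes)
                         < freqs[j]).astype(np.int8)
                stay = rng.random(n_founder_haplotypes) < 0.9
                founders[:, j] = np.where(stay, founders[:, j - 1], fresh)
            picks = rng.integers(n_founder_haplotypes, size=(2, n_samples))
            block = founders[picks[0]] + founders[picks[1]]
            dosages[:, col + start:col + start + bs] = block
        for k in range(m_c):
            map_rows.append((f"snp{col + k + 1:06d}", str(chrom),
                             int(pos[k]), "A", "B"))
        col += m_c

    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan

    snp_map = pd.DataFrame(map_rows, columns=SNP_MAP_COLUMNS)
    return GenotypeMatrix(dosages, [f"s{i + 1:05d}" for i in range(n_samples)],
                          snp_map)


def simulate_feedlot_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    n_groups: int = 10,
    mmwt_exponent: float = 0.73,
    adg_mean: float = 1.5,
    adg_sd: float = 0.2,
    mwt_mean: float = 400.0,
    mwt_sd: float = 40.0,
) -> tuple[FeedlotTable, np.ndarray]:
    """Simulate feedlot records whose feed-intake residual is a known trait.

    The true trait (``rfi_true``) is polygenic value + QTL contributions
    + noise.  The polygenic value is ``Z w`` with ``Z`` the centered
    dosage matrix and per-SNP effects ``w ~ N(0, sigma_a2 / (2 Σ p q))``,
    so its expected variance is ``sigma_a2`` and its covariance follows
    the VanRaden genomic relationship matrix.  Daily feed intake is then
    assembled from ``eq1_coeffs`` so that re-fitting the feed-intake
    regression recovers ``rfi_true`` up to estimation error.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    n, m = genotypes.n_samples, genotypes.n_snps
    for idx, _, _ in truth.qtl_snps:
        if not (0 <= idx < m):
            raise ValueError(f"QTL snp index {idx} out of range for {m} SNPs")

    rng = np.random.default_rng(truth.seed)
    D = genotypes.dosages.copy()
    col_mean = np.nanmean(D, axis=0)
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.take(col_mean, np.nonzero(miss)[1])

    # polygenic value under the GRM model
    u = np.zeros(n)
    if truth.sigma_a2 > 0:
        p = col_mean / 2.0
        pq = p * (1 - p)
        denom = 2.0 * pq.sum()
        if denom <= 0:
            raise ValueError("all SNPs monomorphic; cannot draw a "
                             "polygenic value with sigma_a2 > 0")
        w = rng.normal(0.0, np.sqrt(truth.sigma_a2 / denom), size=m)
        u = (D - 2.0 * p) @ w

    q = np.zeros(n)
    for idx, add, dom in truth.qtl_snps:
        d_col = D[:, idx]
        q += add * (d_col - d_col.mean()) + dom * (d_col == 1.0)

    e = (rng.normal(0.0, np.sqrt(truth.sigma_e2), size=n)
         if truth.sigma_e2 > 0 else np.zeros(n))
    rfi_true = u + q + e

    groups = rng.integers(n_groups, size=n)
    labels = np.array([f"G{g + 1}" for g in groups])
    g_eff = np.array([truth.group_effects.get(lab, 0.0) for lab in labels])

    adg = np.clip(rng.normal(adg_mean, adg_sd, size=n), 0.05, None)
    mwt = np.clip(rng.normal(mwt_mean, mwt_sd, size=n), 50.0, None)
    b0, b1, b2 = truth.eq1_coeffs
    dfi = b0 + b1 * adg + b2 * mwt ** mmwt_exponent + g_eff + rfi_true

    table = FeedlotTable(pd.DataFrame({
        "animal_id": genotypes.sample_ids,
        "dfi": dfi,
        "adg": adg,
        "mwt": mwt,
        "test_group": labels,
        "cg": labels,
    }))
    return table, rfi_true


def simulate_gene_models(
    chrom_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    length_range=(5_000, 50_000),
    allow_overlap: bool = False,
) -> GeneModelSet:
    """Place gene intervals on the given chromosomes.

    Genes are allocated to chromosomes proportionally to length.  With
    ``allow_overlap=False`` (default) genes are laid out disjointly by
    splitting the leftover space into random gaps; if the requested
    genes cannot fit, the call is rejected.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(n_genes * lengths / lengths.sum() - alloc)):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += 1
    alloc[np.argmax(lengths)] += n_genes - alloc.sum()

    rows = []
    gene_no = 0
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        L = int(chrom_lengths[chrom])
        lens = rng.integers(length_range[0], length_range[1] + 1, size=k)
        if allow_overlap:
            starts = rng.integers(0, np.maximum(1, L - lens))
            order = np.argsort(starts)
            starts, lens = starts[order], lens[order]
        else:
            total = int(lens.sum())
            if total > L:
                raise ValueError(
                    f"{k} genes of total length {total} do not fit on "
                    f"chromosome {chrom!r} of length {L} without overlap")
            free = L - total
            cuts = np.sort(rng.integers(0, free + 1, size=k))
            starts = cuts + np.concatenate(([0], np.cumsum(lens[:-1])))
        for s, l in zip(starts, lens):
            gene_no += 1
            rows.append((f"gene{gene_no:05d}", str(chrom), int(s),
                         int(s + l), rng.choice(["+", "-"])))
    return GeneModelSet(pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS))


def simulate_expression(
    rfi: np.ndarray,
    gene_models: GeneModelSet,
    truth: SimulationTruth,
    mean_libsize: int = 5_000_000,
    dispersion: float = 0.1,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    baseline_lcpm_range=(1.0, 9.0),
) -> CountMatrix:
    """Simulate negative-binomial gene counts linked to RFI.

    For each ``(gene, slope)`` in ``truth.gsa_genes`` the expected log2
    CPM is ``baseline + slope * z`` where ``z`` is standardized RFI; all
    other genes are independent of the trait.  Expected CPMs are scaled
    to sum to 1e6, library sizes vary uniformly within +/-30% of
    ``mean_libsize``, and counts are NB with ``var = mu + phi mu^2``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rfi = np.asarray(rfi, dtype=float)
    n = rfi.size
    if sample_ids is not None and len(sample_ids) != n:
        raise ValueError(f"rfi has {n} values but {len(sample_ids)} "
                         "sample ids were supplied")
    if sample_ids is None:
        sample_ids = [f"s{i + 1:05d}" for i in range(n)]
    gene_ids = list(gene_models.data["gene_id"])
    slope = dict(truth.gsa_genes)
    unknown = set(slope) - set(gene_ids)
    if unknown:
        raise ValueError(f"gsa genes not in gene models: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sd = rfi.std()
    z = (rfi - rfi.mean()) / sd if sd > 0 else np.zeros(n)

    base = rng.uniform(*baseline_lcpm_range, size=len(gene_ids))
    slopes = np.array([slope.get(g, 0.0) for g in gene_ids])
    lcpm = base[:, None] + slopes[:, None] * z[None, :]
    cpm = 2.0 ** lcpm
    cpm *= 1e6 / cpm.sum(axis=0).mean()

    libsizes = rng.uniform(0.7, 1.3, size=n) * mean_libsize
    mu = cpm * (libsizes[None, :] / 1e6)
    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                    columns=sample_ids))
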