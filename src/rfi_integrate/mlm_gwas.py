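"""Mixed-model association scan with a genomic relationship matrix.

The trait model is

    y = X b + g alpha + a + e,     var(a) = G sigma_a^2,  var(e) = I sigma_e^2

with ``X`` the fixed covariates (intercept + contemporary groups), ``g``
the SNP dosage and ``G`` the VanRaden genomic relationship matrix.
Variance components are estimated once by REML on the no-SNP model and
then held fixed for every per-SNP test (the EMMAX strategy): a single
eigendecomposition ``G = U D U'`` rotates the model into independent
coordinates, after which each SNP costs one weighted least-squares
solve.  The scan reports the allele-substitution effect, its Wald test,
the fraction of additive variance the SNP explains, the genomic
inflation factor, and merged QTL regions around suggestive hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...
SUGGESTIVE_NEGLOG10P = 4.301        # -log10(5e-5), suggestive threshold
P_FLOOR = 1e-300


@dataclass
class GRM:
    values: np.ndarray
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class AssocScan:
    table: pd.DataFrame          # snp_id chrom pos maf effect se p ...
    lambda_gc: float
    vc: VarianceComponents
    thresholds: dict = field(default_factory=dict)


@dataclass
class QTLRegion:
    chrom: str
    start: int                   # span of significant SNPs (bp, 1-based)
    end: int
    flank_start: int             # span extended by the flank, clipped at 0
    flank_end: int
    snp_ids: list[str]
    top_snp: str
    top_pos: int
    top_neglog10p: float

    @property
    def n_sig(self) -> int:
        return len(self.snp_ids)


@dataclass
class GenotypeClassEffects:
    """Genotype fitted as a 3-level class; additive/dominance decomposition.

    ``a = (AA - BB) / 2`` and ``d = AB - (AA + BB) / 2`` where AA is the
    allele1 homozygote (dosage 2), AB the heterozygote and BB the
    allele2 homozygote.
    """

    est_AA: float
    est_AB: float
    est_BB: float
    a: float
    d: float
    d_se: float
    d_p: float


def compute_grm(g: GenotypeMatrix, return_freqs: bool = False):
    """VanRaden (method 1) genomic relationship matrix.

    ``G = Z Z' / (2 Σ p q)`` with ``Z`` the dosage matrix centered at
    ``2p``; missing dosages are mean-imputed before centering and
    monomorphic SNPs are skipped.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    D = g.dosages.copy()
    p = np.nanmean(D, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    D, p = D[:, poly], p[poly]
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.take(2.0 * p, np.nonzero(miss)[1])
    Z = D - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    grm = GRM(Z @ Z.T / denom, list(g.sample_ids))
    return (grm, p, poly) if return_freqs else grm


def _eigen_grm(grm: GRM, ridge: float = 1e-6):
    d, U = np.linalg.eigh(grm.values + ridge * np.eye(grm.n))
    if d.min() < -1e-6:
        raise ValueError(f"GRM not positive semi-definite even after "
                         f"ridge {ridge} (min eigenvalue {d.min():.3g})")
    return np.clip(d, 0.0, None), U


def _as_design(covariates, n: int) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows for {n} samples")
    return X


def fit_variance_components(
    y: np.ndarray,
    covariates,
    grm: GRM,
    ridge: float = 1e-6,
    h2_bounds: tuple[float, float] = (1e-6, 1 - 1e-6),
) -> VarianceComponents:
    """REML estimation of additive and residual variance.

    The restricted log-likelihood is profiled over the total variance
    and maximized over ``h2 = sigma_a2 / (sigma_a2 + sigma_e2)`` on a
    one-dimensional bounded search, using a single eigendecomposition of
    the ridge-adjusted GRM.  Deterministic.  An optimum within 1e-4 of a
    bound is flagged with ``at_bound`` (not an error).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != grm.n:
        raise ValueError("trait length does not match GRM")
    X = _as_design(covariates, n)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate design is rank deficient")
    d, U = _eigen_grm(grm, ridge)
    yr, Xr = U.T @ y, U.T @ X

    def profile(h2: float):
        w = h2 * d + (1.0 - h2)
        Wi = 1.0 / w
        XtWX = Xr.T @ (Xr * Wi[:, None])
        XtWy = Xr.T @ (yr * Wi)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yr - Xr @ beta
        rss = float(np.sum(r * r * Wi))
        sig2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(sig2) + np.sum(np.log(w))
                     + logdet + (n - p))
        return ll, sig2

    res = optimize.minimize_scalar(
        lambda h: -profile(h)[0], bounds=h2_bounds, method="bounded",
        options={"xatol": 1e-9})
    h2 = float(res.x)
    ll, sig2 = profile(h2)
    # flag optima parked on a bound and flat (unidentifiable) profiles,
    # e.g. a GRM indistinguishable from the identity
    flat = abs(ll - profile(h2_bounds[0])[0]) < 1e-6 \
        and abs(ll - profile(h2_bounds[1])[0]) < 1e-6
    at_bound = flat or (h2 - h2_bounds[0] < 1e-4) \
        or (h2_bounds[1] - h2 < 1e-4)
    return VarianceComponents(
        sigma_a2=h2 * sig2, sigma_e2=(1.0 - h2) * sig2, h2=h2,
        reml_loglik=float(ll), at_bound=at_bound)


def run_scan(
    y: np.ndarray,
    covariates,
    g: GenotypeMatrix,
    vc: VarianceComponents,
    grm: GRM | None = None,
    ridge: float = 1e-6,
    bonferroni_alpha: float = 0.05,
    suggestive_p: float = 5e-5,
) -> AssocScan:
    """Per-SNP generalized least squares with fixed variance components.

    The model is rotated once into the GRM eigenbasis; each SNP is then
    a weighted regression with weights ``1 / (h2 d_i + 1 - h2)``.  The
    residual scale is re-estimated per SNP, so with ``sigma_a2 = 0`` the
    scan reduces exactly to ordinary least squares.  Wald p-values use
    the standard normal reference.  Missing dosages are mean-imputed;
    zero-variance SNPs yield NA rows.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = _as_design(covariates, n)
    p_cov = X.shape[1]
    if g.n_samples != n:
        raise ValueError("genotypes do not match trait length")
    if grm is None:
        grm = compute_grm(g)
    d, U = _eigen_grm(grm, ridge)
    w = vc.h2 * d + (1.0 - vc.h2)
    Wi = 1.0 / w
    yr, Xr = U.T @ y, U.T @ X

    D = g.dosages.copy()
    freq1 = np.nanmean(D, axis=0) / 2.0
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.take(2.0 * freq1, np.nonzero(miss)[1])
    snp_var = D.var(axis=0)
    maf = np.minimum(freq1, 1.0 - freq1)

    Gr = U.T @ D
    XtWX = Xr.T @ (Xr * Wi[:, None])
    C = np.linalg.solve(XtWX, Xr.T * Wi[None, :])   # p x n projector
    Gs = Gr - Xr @ (C @ Gr)                          # residualized dosages
    ys = yr - Xr @ (C @ yr)

    sg = np.einsum("ij,ij->j", Gs * Wi[:, None], Gs)
    gy = Gs.T @ (ys * Wi)
    yy = float(np.sum(ys * ys * Wi))
    df = n - p_cov - 1

    ok = (snp_var > 0) & (sg > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(ok, gy / sg, np.nan)
        rss = yy - np.where(ok, alpha**2 * sg, 0.0)
        sigma2 = rss / df
        se = np.where(ok, np.sqrt(sigma2 / sg), np.nan)
        z = alpha / se
    pvals = np.where(ok, np.clip(2.0 * stats.norm.sf(np.abs(z)),
                                 P_FLOOR, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        neglog10p = -np.log10(pvals)
        var_exp = (100.0 * 2.0 * freq1 * (1.0 - freq1) * alpha**2
                   / vc.sigma_a2 if vc.sigma_a2 > 0
                   else np.full(g.n_snps, np.nan))

    table = pd.DataFrame({
        "snp_id": g.snp_map["snp_id"],
        "chrom": g.snp_map["chrom"].astype(str),
        "pos": g.snp_map["pos"].astype(int),
        "maf": maf,
        "effect": alpha,
        "se": se,
        "p": pvals,
        "neglog10p": neglog10p,
        "var_explained_pct": var_exp,
    })
    m_scanned = int(ok.sum())
    lam = genomic_inflation(pvals[ok]) if m_scanned else float("nan")
    thresholds = {
        "bonferroni_p": bonferroni_alpha / max(m_scanned, 1),
        "bonferroni_neglog10p": float(
            -np.log10(bonferroni_alpha / max(m_scanned, 1))),
        "suggestive_p": suggestive_p,
        "suggestive_neglog10p": float(-np.log10(suggestive_p)),
    }
    return AssocScan(table=table, lambda_gc=lam, vc=vc,
                     thresholds=thresholds)


def genomic_inflation(p_values) -> float:
    """Median association chi-square over the null 1-df median (~0.455)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def variance_explained(p, alpha, sigma_a2) -> float:
    """Percent of additive variance explained: ``100 * 2 p q alpha^2 / sigma_a2``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must be in (0, 1)")
    sigma_a2 = float(sigma_a2)
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be > 0")
    out = 100.0 * 2.0 * p * (1.0 - p) * np.asarray(alpha, dtype=float) ** 2 \
        / sigma_a2
    return float(out) if out.ndim == 0 else out


def define_qtl_regions(
    scan: AssocScan,
    sig_neglog10p: float = SUGGESTIVE_NEGLOG10P,
    flank_bp: int = 1_000_000,
) -> list[QTLRegion]:
    """Merge significant SNPs whose +/-flank intervals overlap into regions.

    Reports both the significant-SNP span and the flanked span (clipped
    at 0); the top SNP is the member with the largest -log10 p, ties
    broken by smaller position.
    """
    df = scan.table
    if df.empty:
        raise ValueError("empty scan")
    sig = df[df["neglog10p"] >= sig_neglog10p].copy()
    regions: list[QTLRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        cluster: list = []
        for row in grp.itertuples(index=False):
            if cluster and row.pos - cluster[-1].pos > 2 * flank_bp:
                regions.append(_make_region(str(chrom), cluster, flank_bp))
                cluster = []
            cluster.append(row)
        if cluster:
            regions.append(_make_region(str(chrom), cluster, flank_bp))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _make_region(chrom: str, rows: list, flank_bp: int) -> QTLRegion:
    top = max(rows, key=lambda r: (r.neglog10p, -r.pos))
    start, end = rows[0].pos, rows[-1].pos
    return QTLRegion(
        chrom=chrom, start=int(start), end=int(end),
        flank_start=int(max(0, start - flank_bp)),
        flank_end=int(end + flank_bp),
        snp_ids=[r.snp_id for r in rows],
        top_snp=top.snp_id, top_pos=int(top.pos),
        top_neglog10p=float(top.neglog10p),
    )


def estimate_genotype_class_effects(
    y: np.ndarray,
    covariates,
    snp_dosages: np.ndarray,
    vc: VarianceComponents,
    grm: GRM,
    ridge: float = 1e-6,
) -> GenotypeClassEffects:
    """Fit a SNP as a 3-level genotype class in the rotated GLS model.

    Requires all three genotype classes with at least two animals each
    and complete dosages.  The dominance contrast
    ``AB - (AA + BB) / 2`` carries a Wald test on its standard error.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    dose = np.asarray(snp_dosages, dtype=float)
    if dose.size != n:
        raise ValueError("dosage length does not match trait")
    if np.isnan(dose).any():
        raise ValueError("missing dosages not supported in the class model")
    classes = [(dose == 2.0), (dose == 1.0), (dose == 0.0)]
    for name, mask in zip(("AA", "AB", "BB"), classes):
        if mask.sum() < 2:
            raise ValueError(f"genotype class {name} not estimable "
                             f"({int(mask.sum())} animals)")

    X = _as_design(covariates, n)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    design = np.column_stack([c.astype(float) for c in classes]
                             + [X[:, j] for j in keep])
    q = design.shape[1]
    if np.linalg.matrix_rank(design) < q:
        raise ValueError("class-model design is rank deficient")

    d, U = _eigen_grm(grm, ridge)
    w = vc.h2 * d + (1.0 - vc.h2)
    Wi = 1.0 / w
    yr, Dr = U.T @ y, U.T @ design
    XtWX = Dr.T @ (Dr * Wi[:, None])
    beta = np.linalg.solve(XtWX, Dr.T @ (yr * Wi))
    r = yr - Dr @ beta
    sigma2 = float(np.sum(r * r * Wi)) / (n - q)
    cov = sigma2 * np.linalg.inv(XtWX)

    est_AA, est_AB, est_BB = beta[:3]
    contrast = np.zeros(q)
    contrast[:3] = (-0.5, 1.0, -0.5)
    d_val = float(contrast @ beta)
    d_se = float(np.sqrt(contrast @ cov @ contrast))
    d_p = float(np.clip(2.0 * stats.norm.sf(abs(d_val / d_se)),
                        P_FLOOR, 1.0)) if d_se > 0 else float("nan")
    return GenotypeClassEffects(
        est_AA=float(est_AA), est_AB=float(est_AB), est_BB=float(est_BB),
        a=float((est_AA - est_BB) / 2.0), d=d_val, d_se=d_se, d_p=d_p)
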