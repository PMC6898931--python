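"""TMM normalization, log2 CPM and per-gene expression-trait regression.

Each tissue/sex dataset is processed independently: genes with no
expression in any sample are dropped, counts are scaled by trimmed mean
of M-values (TMM) factors, converted to log2 counts-per-million, and the
trait (RFI) is regressed on each gene's lcpm.  Note the orientation: the
trait is the response and expression the predictor, so a positive effect
means higher expression accompanies higher (less efficient) RFI.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, GeneModelSet

logger = logging.getLogger(__name__)

GSA_COLUMNS = ["gene_id", "dataset", "effect", "p"]


@dataclass
class NormalizedExpression:
    tmm_factors: pd.Series
    effective_libsizes: pd.Series
    lcpm: pd.DataFrame


def filter_unexpressed(cm: CountMatrix) -> CountMatrix:
    """Drop genes whose count is zero in every sample; nothing else."""
    keep = (cm.counts > 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes unexpressed")
    return CountMatrix(cm.counts.loc[keep])


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction
    is closest to the mean upper-quartile.  For each sample, genes with
    a zero count in either the sample or the reference are excluded;
    M (log ratio) and A (log abundance) values are double-trimmed
    (``trim_m`` on M, ``trim_a`` on A) and the factor is 2 to the
    precision-weighted mean of the surviving M values, with inverse
    asymptotic binomial variances as weights.
    """
    counts = cm.counts.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [cm.sample_ids[i] for i in np.nonzero(lib <= 0)[0]]
        raise ValueError(f"samples with zero library size: {bad}")

    uq = np.quantile(counts, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    refc, Nr = counts[:, ref], lib[ref]

    factors = np.ones(n_samples)
    for s in range(n_samples):
        obs, N = counts[:, s], lib[s]
        both = (obs > 0) & (refc > 0)
        if not both.any():
            raise ValueError(
                f"sample {cm.sample_ids[s]!r} shares no expressed genes "
                f"with the reference {cm.sample_ids[ref]!r}")
        o, r = obs[both], refc[both]
        logR = np.log2((o / N) / (r / Nr))
        absE = 0.5 * np.log2((o / N) * (r / Nr))
        v = (N - o) / (N * o) + (Nr - r) / (Nr * r)
        if np.max(np.abs(logR)) < 1e-6:
            continue
        n = logR.size
        loL = np.floor(n * trim_m) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * trim_a) + 1
        hiS = n + 1 - loS
        rR = stats.rankdata(logR)
        rA = stats.rankdata(absE)
        keep = (rR >= loL) & (rR <= hiL) & (rA >= loS) & (rA <= hiS)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
        factors[s] = 2.0 ** (0.0 if np.isnan(f) else f)

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def log_cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> NormalizedExpression:
    """log2 counts-per-million on TMM-effective library sizes.

    ``lcpm = log2((count + prior) / (eff_lib + 2 * prior) * 1e6)`` with
    ``eff_lib = raw library size * factor``; the doubled prior in the
    denominator keeps lcpm finite and bounded for zero counts.
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.sample_ids)
    factors = factors.reindex(cm.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every sample")
    lib = cm.counts.sum(axis=0).astype(float)
    eff = lib * factors
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    lcpm = np.log2((cm.counts + prior_count)
                   / (eff + 2.0 * prior_count) * 1e6)
    return NormalizedExpression(tmm_factors=factors,
                                effective_libsizes=eff,
                                lcpm=lcpm)


def gene_rfi_association(
    lcpm: pd.DataFrame,
    rfi: pd.Series,
    dataset_label: str,
) -> pd.DataFrame:
    """Per-gene simple regression of the trait on lcpm.

    Returns one row per gene with columns ``gene_id, dataset, effect,
    p``; the effect is the slope of RFI on lcpm and p the two-sided
    t-test with n-2 degrees of freedom.  Genes with zero lcpm variance
    are emitted with NA and logged.
    """
    if not isinstance(rfi, pd.Series):
        rfi = pd.Series(np.asarray(rfi, dtype=float), index=lcpm.columns)
    if set(rfi.index) != set(lcpm.columns):
        raise ValueError("trait sample ids do not match expression columns")
    rfi = rfi.reindex(lcpm.columns).astype(float)
    n = lcpm.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")

    X = lcpm.to_numpy(dtype=float)
    y = rfi.to_numpy()
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = xc @ yc
    syy = float(yc @ yc)
    ok = sxx > 0
    if (~ok).any():
        logger.warning("%d gene(s) with constant lcpm emitted as NA",
                       int((~ok).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, sxy / sxx, np.nan)
        rss = syy - np.where(ok, slope * sxy, 0.0)
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        t = slope / se
    with np.errstate(invalid="ignore"):
        p = np.where(ok & (se > 0),
                     2.0 * stats.t.sf(np.abs(t), df=n - 2), np.nan)
    p = np.where(ok & (se == 0), np.finfo(float).tiny, p)
    return pd.DataFrame({
        "gene_id": lcpm.index,
        "dataset": dataset_label,
        "effect": slope,
        "p": p,
    }).reset_index(drop=True)


def select_gsa(
    gsa: pd.DataFrame,
    p_threshold: float,
    regions: list[tuple[str, int, int]] | None = None,
    models: GeneModelSet | None = None,
) -> pd.DataFrame:
    """Rows below the p threshold, optionally restricted to windows.

    ``regions`` is a list of ``(chrom, start, end)`` half-open windows;
    a gene is retained when its interval overlaps any window.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    out = gsa[gsa["p"] < p_threshold]
    if regions is not None:
        if models is None:
            raise ValueError("gene models required for windowed selection")
        loc = models.data.set_index("gene_id")
        keep = []
        for gid in out["gene_id"]:
            if gid not in loc.index:
                keep.append(False)
                continue
            row = loc.loc[gid]
            keep.append(any(
                str(row["chrom"]) == str(c) and row["start"] < e
                and row["end"] > s
                for c, s, e in regions))
        out = out[np.array(keep, dtype=bool)]
    return out.reset_index(drop=True)
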