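"""Overlay QTL regions with gene models and expression-trait signals.

Around each region's top SNP two windows are drawn: a candidate-gene
window (default half-width 1 Mb, so a 4.88 Mb SNP yields the 3.88-5.88
Mb span) and a window for expression hits of the same default width.
Gene-window overlap is any-overlap on half-open intervals; distances
are in bp, zero when the SNP falls inside the gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import GeneModelSet
from .mlm_gwas import QTLRegion

logger = logging.getLogger(__name__)


@dataclass
class RegionReport:
    chrom: str
    top_snp: str
    top_pos: int
    window_start: int
    window_end: int
    genes: list[tuple[str, int]]            # (gene_id, distance), sorted
    nearest_gene: str | None
    gsa_genes: list[tuple[str, str, float, float]]  # (gene, dataset, effect, p)


@dataclass
class IntegrationReport:
    regions: list[RegionReport] = field(default_factory=list)

    def to_json(self, path=None):
        payload = [asdict(r) for r in self.regions]
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            for gid, dist in r.genes:
                rows.append((r.chrom, r.top_snp, r.window_start,
                             r.window_end, gid, "candidate", "", np.nan,
                             np.nan))
            if r.nearest_gene is not None:
                rows.append((r.chrom, r.top_snp, r.window_start,
                             r.window_end, r.nearest_gene, "nearest", "",
                             np.nan, np.nan))
            for gid, ds, eff, p in r.gsa_genes:
                rows.append((r.chrom, r.top_snp, r.window_start,
                             r.window_end, gid, "gsa", ds, eff, p))
        return pd.DataFrame(rows, columns=[
            "chrom", "top_snp", "window_start", "window_end", "gene",
            "role", "dataset", "effect", "p"])


def _distance(start: int, end: int, pos: int) -> int:
    """bp gap from ``pos`` to the half-open gene interval (0 if inside)."""
    if start <= pos < end:
        return 0
    if pos < start:
        return start - pos
    return pos - (end - 1)


def genes_in_window(
    models: GeneModelSet,
    chrom: str,
    center_bp: int,
    half_width_bp: int,
) -> list[tuple[str, int]]:
    """Genes overlapping ``[center - hw, center + hw)`` with distances.

    Sorted by distance then start position.  An unknown chromosome
    yields an empty list with a logged warning.
    """
    if half_width_bp <= 0:
        raise ValueError("half_width_bp must be > 0")
    sub = models.on_chrom(chrom)
    if sub.empty:
        if str(chrom) not in models.chroms:
            logger.warning("chromosome %s has no gene models", chrom)
        return []
    w0 = max(0, center_bp - half_width_bp)
    w1 = center_bp + half_width_bp
    hit = sub[(sub["start"] < w1) & (sub["end"] > w0)]
    out = [(row.gene_id, _distance(row.start, row.end, center_bp))
           for row in hit.itertuples(index=False)]
    starts = {row.gene_id: row.start for row in hit.itertuples(index=False)}
    out.sort(key=lambda t: (t[1], starts[t[0]]))
    return out


def nearest_gene(models: GeneModelSet, chrom: str, pos: int) -> str | None:
    """Gene minimizing distance to ``pos``; ties go to the smaller start."""
    sub = models.on_chrom(chrom)
    if sub.empty:
        return None
    best = min(sub.itertuples(index=False),
               key=lambda r: (_distance(r.start, r.end, pos), r.start))
    return best.gene_id


def integrate(
    regions: list[QTLRegion],
    gsa_tables: list[pd.DataFrame],
    models: GeneModelSet,
    candidate_hw_bp: int = 1_000_000,
    gsa_hw_bp: int = 1_000_000,
    gsa_p_threshold: float = 0.05,
) -> IntegrationReport:
    """Per-region candidate genes, nearest gene and in-window GSA hits.

    A region on a chromosome without genes yields an empty-but-present
    record.  A complete chromosome-naming mismatch between regions and
    gene models is an error.
    """
    region_chroms = {str(r.chrom) for r in regions}
    if regions and len(models) and not (region_chroms & models.chroms):
        raise ValueError(
            "chromosome naming mismatch: regions use "
            f"{sorted(region_chroms)} but gene models use "
            f"{sorted(models.chroms)}")

    gsa = (pd.concat(gsa_tables, ignore_index=True) if gsa_tables
           else pd.DataFrame(columns=["gene_id", "dataset", "effect", "p"]))
    gene_loc = models.data.set_index("gene_id")

    out = IntegrationReport()
    for region in sorted(regions, key=lambda r: (str(r.chrom), r.start)):
        chrom, pos = str(region.chrom), region.top_pos
        genes = genes_in_window(models, chrom, pos, candidate_hw_bp)
        near = nearest_gene(models, chrom, pos)
        if near is not None and genes and near not in {g for g, _ in genes}:
            near = genes[0][0]

        g0, g1 = max(0, pos - gsa_hw_bp), pos + gsa_hw_bp
        sub = models.on_chrom(chrom)
        in_win = set(sub[(sub["start"] < g1) & (sub["end"] > g0)]["gene_id"])
        hits = gsa[(gsa["p"] < gsa_p_threshold)
                   & gsa["gene_id"].isin(in_win)]
        gsa_rows = sorted(
            (str(r.gene_id), str(r.dataset), float(r.effect), float(r.p))
            for r in hits.itertuples(index=False))

        out.regions.append(RegionReport(
            chrom=chrom,
            top_snp=region.top_snp,
            top_pos=pos,
            window_start=max(0, pos - candidate_hw_bp),
            window_end=pos + candidate_hw_bp,
            genes=genes,
            nearest_gene=near if genes else None,
            gsa_genes=gsa_rows,
        ))
    return out
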