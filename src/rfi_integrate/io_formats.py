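"""Containers and on-disk formats for the pipeline.

All genomic intervals are held internally as 0-based half-open
``[start, end)``; 1-based coordinates appear only at I/O edges (VCF and
GFF3).  SNP dosage counts copies of ``allele1`` — for VCF input that is
the REF allele — so the sign of every downstream effect estimate is tied
to this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]
FEEDLOT_COLUMNS = ["animal_id", "dfi", "adg", "mwt", "test_group", "cg"]
GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
SCAN_COLUMNS = [
    "snp_id", "chrom", "pos", "maf", "effect", "se", "p",
    "neglog10p", "var_explained_pct",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class GenotypeMatrix:
    """Diploid dosages for ``n_samples`` x ``n_snps``.

    ``dosages`` is a float array with values in {0, 1, 2} and ``nan`` for
    missing genotypes.  ``snp_map`` carries one row per SNP with columns
    ``snp_id, chrom, pos (1-based), allele1, allele2``.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        if list(self.snp_map.columns) != SNP_MAP_COLUMNS:
            raise ValueError(f"snp_map must have columns {SNP_MAP_COLUMNS}")
        if len(self.snp_map) != m:
            raise ValueError(f"{len(self.snp_map)} map rows for {m} SNPs")
        if self.snp_map["snp_id"].duplicated().any():
            dup = self.snp_map["snp_id"][self.snp_map["snp_id"].duplicated()]
            raise ValueError(f"duplicated SNP ids: {sorted(set(dup))[:5]}")
        if (self.snp_map["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = (np.arange(self.n_samples) if sample_idx is None
                      else np.asarray(sample_idx))
        snp_idx = (np.arange(self.n_snps) if snp_idx is None
                   else np.asarray(snp_idx))
        return GenotypeMatrix(
            self.dosages[np.ix_(sample_idx, snp_idx)],
            [self.sample_ids[i] for i in sample_idx],
            self.snp_map.iloc[snp_idx].reset_index(drop=True),
        )


@dataclass
class FeedlotTable:
    """Per-animal feedlot records feeding the RFI regression.

    Columns: ``animal_id``, ``dfi`` (daily feed intake, kg/day), ``adg``
    (average daily gain, kg/day), ``mwt`` (mid-test weight, kg, before
    metabolic exponentiation), ``test_group`` and ``cg`` (contemporary
    group), both categorical labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEEDLOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feedlot table missing columns {missing}")
        if self.data["animal_id"].duplicated().any():
            raise ValueError("duplicated animal_id")
        for col in ("dfi", "adg", "mwt"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite values in column {col!r}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneModelSet:
    """Gene intervals, 0-based half-open, sorted by (chrom, start)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = [c for c in GENE_MODEL_COLUMNS if c != "strand"]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"gene models missing columns {missing}")
        if "strand" not in self.data.columns:
            self.data = self.data.assign(strand=".")
        if self.data["gene_id"].duplicated().any():
            raise ValueError("duplicated gene_id")
        if len(self.data) and (self.data["start"] >= self.data["end"]).any():
            bad = self.data.loc[self.data["start"] >= self.data["end"],
                                "gene_id"].tolist()
            raise ValueError(f"gene interval with start >= end: {bad[:5]}")
        if len(self.data) and (self.data["start"] < 0).any():
            raise ValueError("negative gene start")
        self.data = (self.data[GENE_MODEL_COLUMNS]
                     .sort_values(["chrom", "start"], kind="mergesort")
                     .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chroms(self) -> set[str]:
        return set(self.data["chrom"].astype(str))

    def on_chrom(self, chrom) -> pd.DataFrame:
        return self.data[self.data["chrom"].astype(str) == str(chrom)]


@dataclass
class CountMatrix:
    """Gene-level RNA-seq counts, genes x samples, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT field) or PLINK-style text.

    Multi-allelic VCF records are skipped with a warning; missing GT
    calls become masked entries.  Dosage counts REF (allele1) copies.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    rows, map_rows = [], []
    last = {}
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            logger.warning("%s: record %d (%s:%d) is not biallelic, skipped",
                           path, i, var.CHROM, var.POS)
            continue
        if var.CHROM in last and var.POS < last[var.CHROM]:
            raise FormatError(
                f"{path}: record {i}: position {var.POS} on {var.CHROM} "
                f"not sorted (previous {last[var.CHROM]})")
        last[var.CHROM] = var.POS
        dose = np.full(len(samples), np.nan)
        for k, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            dose[k] = sum(1 for a in alleles if a == 0)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append(dose)
        map_rows.append((snp_id, str(var.CHROM), var.POS, var.REF, var.ALT[0]))
    snp_map = pd.DataFrame(map_rows, columns=SNP_MAP_COLUMNS)
    if snp_map["snp_id"].duplicated().any():
        dup = snp_map["snp_id"][snp_map["snp_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated SNP id {dup!r}")
    dosages = (np.array(rows).T if rows
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(dosages, samples, snp_map)


def write_genotypes(g: GenotypeMatrix, path, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "plink_text":
        _write_plink_text(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_CODE = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}


def _write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snp_map["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, row in g.snp_map.iterrows():
            gts = "\t".join(
                _GT_CODE.get(g.dosages[i, j], "./.")
                for i in range(g.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.allele1}\t"
                     f"{row.allele2}\t.\t.\t.\tGT\t{gts}\n")


def _write_plink_text(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tallele1\tallele2\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, row in g.snp_map.iterrows():
            vals = "\t".join(
                "NA" if np.isnan(d) else str(int(d)) for d in g.dosages[:, j])
            fh.write(f"{row.snp_id}\t{row.chrom}\t{row.pos}\t{row.allele1}\t"
                     f"{row.allele2}\t{vals}\n")


def _read_plink_text(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = SNP_MAP_COLUMNS
    if list(df.columns[:5]) != fixed:
        raise FormatError(
            f"{path}: expected leading columns {fixed}, got "
            f"{list(df.columns[:5])}")
    samples = list(df.columns[5:])
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, samples, df[fixed].copy())


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, format: str = "bed") -> GeneModelSet:
    """Read gene intervals from BED6 (0-based half-open) or GFF3.

    GFF3 ``gene`` features (1-based closed) are shifted to the internal
    0-based half-open convention: start-1, end unchanged.
    """
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_bed(path) -> GeneModelSet:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {i}: fewer than 4 BED fields")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer "
                                  f"coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}: line {i}: start >= end")
            rows.append((name, chrom, start, end, strand))
    return GeneModelSet(pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS))


def _read_gff3(path) -> GeneModelSet:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start, end = feat.start - 1, feat.end  # 1-based closed -> half-open
        if start >= end:
            raise FormatError(f"{path}: gene {gene_id}: empty interval "
                              f"after conversion")
        rows.append((gene_id, feat.seqid, start, end, feat.strand or "."))
    return GeneModelSet(pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS))


def write_gene_models(models: GeneModelSet, path) -> None:
    """Write gene models as BED6 (score column constant)."""
    with open(path, "w") as fh:
        for row in models.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t"
                     f".\t{row.strand}\n")


# ---------------------------------------------------------------------------
# tables


def read_feedlot_table(path) -> FeedlotTable:
    df = pd.read_csv(path, sep="\t",
                     dtype={"animal_id": str, "test_group": str, "cg": str})
    return FeedlotTable(df)


def write_feedlot_table(table: FeedlotTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_scan_results(scan, path) -> None:
    """Write a per-SNP association table, sorted by (chrom, pos).

    Columns: snp_id, chrom, pos, maf, effect, se, p, neglog10p,
    var_explained_pct; fixed numeric formats so output is deterministic
    and directly Manhattan/QQ-plot ready.
    """
    df = scan.table if hasattr(scan, "table") else scan
    df = df[SCAN_COLUMNS].sort_values(["chrom", "pos"], kind="mergesort")
    out = df.copy()
    out["maf"] = out["maf"].map(lambda v: f"{v:.4f}")
    for col in ("effect", "se"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out["p"] = out["p"].map(lambda v: f"{v:.4e}")
    out["neglog10p"] = out["neglog10p"].map(lambda v: f"{v:.2f}")
    out["var_explained_pct"] = out["var_explained_pct"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str},
                       na_values=["NA"])
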