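import numpy as np
import pandas as pd
import pytest

from rfi_integrate.io_formats import (
    CountMatrix,
    GeneModelSet,
    GenotypeMatrix,
    SNP_MAP_COLUMNS,
)


def make_genotypes(dosages, chrom="1", positions=None, sample_ids=None):
    """Hand-build a GenotypeMatrix from a list of per-sample dosage rows."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    snp_map = pd.DataFrame(
        [(f"snp{j + 1}", chrom, positions[j], "A", "B") for j in range(m)],
        columns=SNP_MAP_COLUMNS)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(d, sample_ids, snp_map)


def make_gene_models(rows):
    """rows: iterable of (gene_id, chrom, start, end[, strand])."""
    recs = [(r + (".",))[:5] for r in rows]
    return GeneModelSet(pd.DataFrame(
        recs, columns=["gene_id", "chrom", "start", "end", "strand"]))


@pytest.fixture
def small_genotypes():
    return make_genotypes([
        [0, 1, 2, 0, 1],
        [1, 1, 2, 0, 0],
        [2, 0, 1, 1, 2],
    ])


@pytest.fixture
def nb_counts():
    rng = np.random.default_rng(42)
    mu = rng.gamma(2, 200, size=(300, 8)) * rng.uniform(0.5, 2.0, size=(1, 8))
    counts = rng.negative_binomial(5, 5 / (5 + mu))
    return CountMatrix(pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(300)],
        columns=[f"s{j}" for j in range(8)]))
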