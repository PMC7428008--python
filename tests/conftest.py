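import numpy as np
import pandas as pd
import pytest

from trcscan.annotation import GeneModel


def build_toy_genes():
    """Three hand-built genes on a 100 kb chromosome (plus/minus/non-coding)."""
    return [
        GeneModel(gene_id="gA", chrom="chr1", strand="+",
                  tx_start=10_000, tx_end=20_000,
                  exons=((10_000, 11_000), (14_000, 15_000), (19_000, 20_000)),
                  cds_start=10_500, cds_end=19_500),
        GeneModel(gene_id="gB", chrom="chr1", strand="-",
                  tx_start=40_000, tx_end=52_000,
                  exons=((40_000, 41_000), (45_000, 46_500), (51_000, 52_000)),
                  cds_start=40_600, cds_end=51_400),
        GeneModel(gene_id="gC", chrom="chr1", strand="+",
                  tx_start=70_000, tx_end=75_000,
                  exons=((70_000, 71_500), (73_000, 75_000))),  # non-coding
    ]


@pytest.fixture
def toy_genes():
    return build_toy_genes()


@pytest.fixture
def toy_chrom_sizes():
    return {"chr1": 100_000}


def make_reads(rows):
    """Read table from (chrom, start, end, strand) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
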