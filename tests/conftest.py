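import numpy as np
import pandas as pd
import pytest

from chlororibo import GeneModel, SimConfig, build_toy_plastome
from chlororibo.io_formats import FOOTPRINT_COLUMNS


@pytest.fixture(scope="session")
def base_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def plastome(base_config):
    return build_toy_plastome(base_config)


@pytest.fixture(scope="session")
def cheap_config():
    """Reduced-depth conditions for unit tests that only need structure."""
    return SimConfig(seed=11, nuclear_read_count=50_000)


@pytest.fixture(scope="session")
def cheap_plastome(cheap_config):
    return build_toy_plastome(cheap_config)


@pytest.fixture
def toy_genes():
    """Tiny hand-built annotation: plus, minus, and intron genes."""
    return [
        GeneModel("gA", "chloro", "+", [(100, 1000)]),
        GeneModel("gB", "chloro", "-", [(1200, 1800)]),
        GeneModel("gC", "chloro", "+", [(2000, 2300), (2500, 3100)],
                  (2500, 3100)),
    ]


def make_footprints(rows, sample_id="s1"):
    """rows: (seqid, start, end, length, strand) tuples -> footprint frame."""
    df = pd.DataFrame(rows, columns=["seqid", "start", "end", "length",
                                     "strand"])
    df["sample_id"] = sample_id
    return df[FOOTPRINT_COLUMNS]


def footprint_for_psite(gene, tpos, length=28, d3=15, seqid=None):
    """Build one footprint whose P-site sits at transcript position
    ``tpos`` of ``gene``, using the fixed P-site-to-3'-end geometry."""
    gpos = int(gene.transcript_to_genomic(int(tpos)))
    if gene.strand == "+":
        end = gpos + d3 + 1
        start = end - length
    else:
        start = gpos - d3
        end = start + length
    return (seqid or gene.seqid, start, end, length, gene.strand)
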