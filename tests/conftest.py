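import numpy as np
import pandas as pd
import pytest

from acetylscope.models import GeneModel, TagLibrary


def make_library(positions, chrom="chr1", strand="+", condition="SS", role="IP",
                 sample_id="test"):
    """Build a TagLibrary from a flat list of (chrom, pos) or bare positions."""
    rows = []
    for p in positions:
        if isinstance(p, tuple):
            rows.append((p[0], int(p[1]), strand))
        else:
            rows.append((chrom, int(p), strand))
    tags = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    return TagLibrary(sample_id=sample_id, condition=condition, role=role, tags=tags)


def brute_force_nearest(genes, chrom, pos):
    """O(genes) argmin over all genes for one tag: smallest distance, ties to
    smaller TSS then lexicographic gene_id. Returns gene_id or None."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        key = (abs(pos - g.tss), g.tss, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    return None if best is None else best[1]


@pytest.fixture
def three_genes():
    return [
        GeneModel(gene_id="g1", chrom="chr1", start=1000, end=3000, strand="+"),
        GeneModel(gene_id="g2", chrom="chr1", start=5000, end=7000, strand="+"),
        GeneModel(gene_id="g3", chrom="chr1", start=9000, end=11000, strand="+"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
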