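import numpy as np
import pytest

from enrange.tables_io import EnhancerGeneLink, GenomicInterval


def make_link(
    distance_bp: int,
    score: float,
    gene_id: str = "ENSG00000000001",
    tss: int = 1_000_000,
    width: int = 500,
    features: dict | None = None,
    ubiquitous: bool | None = None,
) -> EnhancerGeneLink:
    """An element placed ``distance_bp`` downstream of the TSS."""
    start = tss + distance_bp
    return EnhancerGeneLink(
        element=GenomicInterval("chr1", start, start + width),
        gene_id=gene_id,
        gene_symbol="GENE",
        tss=tss,
        e2g_score=score,
        distance_bp=distance_bp,
        features=features or {},
        ubiquitous_flag=ubiquitous,
    )


def random_gene_links(rng: np.random.Generator, gene_id: str = "ENSG00000000001"):
    """0-6 links with distances U[0, 600 kb] and scores U[0, 1]."""
    n = int(rng.integers(0, 7))
    return [
        make_link(int(rng.uniform(0, 600_000)), float(rng.uniform()), gene_id=gene_id)
        for _ in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
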