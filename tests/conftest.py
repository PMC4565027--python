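import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from s2p.annotation_io import GeneModel, GenomeAnnotation, TranscriptModel
from s2p.fixtures import ToyGenomeSpec, make_toy_genome


def _gene(gene_id, chrom, strand, exons, cds=(), symbol=None, up=2000, down=0):
    span = (min(s for s, _ in exons), max(e for _, e in exons))
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        gene_symbol=symbol or gene_id.upper(),
        chrom=chrom,
        strand=strand,
        span=span,
        exons=list(exons),
        cds=list(cds),
    )
    g = GeneModel(
        gene_id=gene_id,
        gene_symbol=symbol or gene_id.upper(),
        chrom=chrom,
        strand=strand,
        span=span,
        transcripts=[tx],
    )
    g.set_promoter(up, down)
    return g


@pytest.fixture
def two_gene_annotation():
    """Hand-built two-gene fixture: a coding '+' gene with an intron and a
    non-coding '-' gene overlapping its 3' end."""
    gene_a = _gene(
        "geneA", "chr1", "+",
        exons=[(1000, 1500), (2000, 2500)],
        cds=[(1100, 1400)],
    )
    gene_b = _gene("geneB", "chr1", "-", exons=[(2400, 3000)])
    return GenomeAnnotation(
        genes={"geneA": gene_a, "geneB": gene_b},
        provenance={"promoter_up": 2000, "promoter_down": 0},
    )


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Generated 30-gene / 2-chromosome toy genome plus its GTF on disk."""
    gtf = tmp_path_factory.mktemp("genome") / "toy.gtf"
    spec = ToyGenomeSpec(n_genes=30, n_chroms=2, seed=11)
    _, annotation = make_toy_genome(spec, gtf_path=str(gtf))
    return spec, str(gtf), annotation


def make_gene(*args, **kwargs):
    return _gene(*args, **kwargs)
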