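"""Deterministic synthetic data: toy genomes, null loci, score matrices.

The generators emulate the input shapes the toolkit targets — peak calls and
SNP lists on a small annotated genome — with controlled statistical
structure.  Gene lengths are log-normal (heavy-tailed, as in real genomes),
which is exactly what drives gene-length bias: under a uniform-genome null,
locus hit counts are proportional to gene length.  Every generator takes an
explicit seed; with the seed fixed, outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation_io import (
    DEFAULT_PROMOTER_DOWN,
    DEFAULT_PROMOTER_UP,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    write_gtf,
)
from .gene2pathway import GeneSet, GeneSetCollection
from .genescore import GeneScoreMatrix
from .seq2gene import Locus, LocusTable

SCORE_FAMILIES = ("normal", "uniform", "constant")


@dataclass
class ToyGenomeSpec:
    """Parameters of the toy genome generator.

    Lengths are in bp.  ``gene_length_log_mean/sd`` parameterize a log-normal
    (defaults give a ~10 kb median with a heavy right tail, a caricature of
    mammalian gene lengths); intergenic gaps are log-normal too.  A fraction
    of transcripts is non-coding (no CDS).  ``chrom_length``, when set, caps
    each chromosome and packing beyond it is an error.
    """

    n_chroms: int = 1
    n_genes: int = 30
    gene_length_log_mean: float = 9.2
    gene_length_log_sd: float = 0.8
    gap_log_mean: float = 8.7
    gap_log_sd: float = 0.7
    promoter_up: int = DEFAULT_PROMOTER_UP
    promoter_down: int = DEFAULT_PROMOTER_DOWN
    fraction_noncoding: float = 0.2
    chrom_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("need at least one gene and one chromosome")
        if not 0 <= self.fraction_noncoding <= 1:
            raise ValueError("fraction_noncoding must be in [0, 1]")


def _partition_length(rng: np.random.Generator, total: int, parts: int, floor: int) -> List[int]:
    """Split ``total`` into ``parts`` segments, each >= floor."""
    spare = total - floor * parts
    extra = rng.multinomial(spare, np.full(parts, 1.0 / parts))
    return [floor + int(e) for e in extra]


def _make_gene(
    rng: np.random.Generator,
    serial: int,
    chrom: str,
    start: int,
    length: int,
    coding: bool,
    promoter_up: int,
    promoter_down: int,
) -> GeneModel:
    gid = f"G{serial:04d}"
    symbol = f"SYM{serial:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    while length < 30 * (2 * n_exons - 1) and n_exons > 1:
        n_exons -= 1
    segs = _partition_length(rng, length, 2 * n_exons - 1, 30)
    exons: List[Tuple[int, int]] = []
    pos = start
    for i, seg in enumerate(segs):
        if i % 2 == 0:
            exons.append((pos, pos + seg))
        pos += seg
    cds: List[Tuple[int, int]] = []
    if coding:
        first_len = exons[0][1] - exons[0][0]
        last_len = exons[-1][1] - exons[-1][0]
        u = int(rng.integers(1, max(2, first_len // 2)))
        v = int(rng.integers(1, max(2, last_len // 2)))
        cstart, cend = exons[0][0] + u, exons[-1][1] - v
        if cend > cstart:
            for s, e in exons:
                lo, hi = max(s, cstart), min(e, cend)
                if hi > lo:
                    cds.append((lo, hi))
    transcripts = []
    n_tx = int(rng.integers(1, 4))
    for j in range(n_tx):
        tx_exons = list(exons)
        if j > 0 and len(exons) >= 3:
            drop = int(rng.integers(1, len(exons) - 1))  # internal exon skipping
            tx_exons = exons[:drop] + exons[drop + 1:]
        tx_cds = []
        for cs, ce in cds:
            for s, e in tx_exons:
                lo, hi = max(s, cs), min(e, ce)
                if hi > lo:
                    tx_cds.append((lo, hi))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t{j + 1}",
                gene_id=gid,
                gene_symbol=symbol,
                chrom=chrom,
                strand=strand,
                span=(start, start + length),
                exons=tx_exons,
                cds=tx_cds,
            )
        )
    gene = GeneModel(
        gene_id=gid,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        span=(start, start + length),
        transcripts=transcripts,
    )
    gene.set_promoter(promoter_up, promoter_down)
    return gene


def make_toy_genome(
    spec: ToyGenomeSpec, gtf_path: Optional[str] = None
) -> Tuple[Optional[str], GenomeAnnotation]:
    """Generate a toy genome; optionally write it as GTF.

    Genes are packed left to right with log-normal lengths and gaps, never
    overlapping within a chromosome.  The returned annotation is identical to
    what ``read_gtf`` recovers from the written file.
    """
    rng = np.random.default_rng(spec.seed)
    genes: Dict[str, GeneModel] = {}
    chrom_lengths: Dict[str, int] = {}
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    serial = 0
    for ci, n_here in enumerate(per_chrom, start=1):
        chrom = f"chr{ci}"
        cursor = int(rng.lognormal(spec.gap_log_mean, spec.gap_log_sd))
        for _ in range(n_here):
            serial += 1
            length = int(
                np.clip(
                    rng.lognormal(spec.gene_length_log_mean, spec.gene_length_log_sd),
                    300,
                    500_000,
                )
            )
            coding = rng.random() >= spec.fraction_noncoding
            gene = _make_gene(
                rng, serial, chrom, cursor, length, coding,
                spec.promoter_up, spec.promoter_down,
            )
            genes[gene.gene_id] = gene
            cursor += length + int(rng.lognormal(spec.gap_log_mean, spec.gap_log_sd))
            if spec.chrom_length is not None and cursor > spec.chrom_length:
                raise ValueError(
                    f"infeasible packing: genes exceed chromosome length "
                    f"{spec.chrom_length} on {chrom}"
                )
        chrom_lengths[chrom] = (
            spec.chrom_length if spec.chrom_length is not None else cursor
        )
    annotation = GenomeAnnotation(
        genes=genes,
        provenance={
            "source": "fixtures.make_toy_genome",
            "promoter_up": spec.promoter_up,
            "promoter_down": spec.promoter_down,
            "chrom_lengths": chrom_lengths,
            "spec": asdict(spec),
        },
    )
    if gtf_path is not None:
        write_gtf(annotation, gtf_path)
    return gtf_path, annotation


def _chrom_lengths(annotation: GenomeAnnotation) -> Dict[str, int]:
    lengths = annotation.provenance.get("chrom_lengths")
    if isinstance(lengths, dict) and lengths:
        return {str(c): int(v) for c, v in lengths.items()}
    out: Dict[str, int] = {}
    for g in annotation.genes.values():
        out[g.chrom] = max(out.get(g.chrom, 0), g.span[1] + 10_000)
    return out


def _draw_scores(
    rng: np.random.Generator, n: int, score_dist: Tuple[str, Tuple]
) -> np.ndarray:
    family, params = score_dist
    if family == "normal":
        mu, sd = params
        return rng.normal(mu, sd, size=n)
    if family == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    if family == "constant":
        (value,) = params if isinstance(params, (tuple, list)) else (params,)
        return np.full(n, float(value))
    raise ValueError(
        f"unknown score distribution family {family!r}; "
        f"choices: {', '.join(SCORE_FAMILIES)}"
    )


def sample_null_loci(
    annotation: GenomeAnnotation,
    n_loci: int,
    mode: str = "uniform_genome",
    score_dist: Tuple[str, Tuple] = ("normal", (0.0, 1.0)),
    snp: bool = False,
    seed: int = 0,
    locus_length: int = 200,
    bed_path: Optional[str] = None,
) -> Tuple[Optional[str], LocusTable]:
    """Null loci with i.i.d. scores and no relation to gene-set structure.

    ``uniform_genome`` drops loci uniformly over the total genome length, so
    longer genes collect proportionally more hits — the configuration that
    exposes gene-length bias.  ``per_gene_poisson`` instead picks a gene
    uniformly and places the locus inside it (length-neutral counts).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    length = 1 if snp else int(locus_length)
    lengths = _chrom_lengths(annotation)
    chroms = sorted(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    scores = _draw_scores(rng, n_loci, score_dist)
    loci: List[Locus] = []
    gene_list = [annotation.genes[g] for g in annotation.gene_ids()]
    for i in range(n_loci):
        if mode == "uniform_genome":
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            start = int(rng.integers(0, max(1, lengths[chrom] - length)))
        elif mode == "per_gene_poisson":
            g = gene_list[int(rng.integers(0, len(gene_list)))]
            chrom = g.chrom
            span_len = g.span[1] - g.span[0]
            offset = int(rng.integers(0, max(1, span_len - length + 1)))
            start = g.span[0] + offset
        else:
            raise ValueError(f"unknown mode {mode!r}")
        loci.append(
            Locus(
                locus_id=f"locus_{i + 1:05d}",
                chrom=chrom,
                interval=(start, start + length),
                score=float(scores[i]),
                is_snp=snp,
            )
        )
    table = LocusTable(loci=loci, source=bed_path)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for l in loci:
                fh.write(
                    f"{l.chrom}\t{l.interval[0]}\t{l.interval[1]}"
                    f"\t{l.locus_id}\t{l.score!r}\n"
                )
    return bed_path, table


def spike_signal(
    matrix: GeneScoreMatrix,
    target_set: Sequence[str],
    effect: float,
    seed: Optional[int] = None,
) -> GeneScoreMatrix:
    """Shift the scores of ``target_set`` genes by ``effect`` in every sample.

    ``seed`` is accepted for generator-API symmetry; the shift itself is
    deterministic.
    """
    missing = set(target_set) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"target genes not in matrix: {sorted(missing)}")
    values = matrix.values.copy()
    idx = [matrix.gene_ids.index(g) for g in target_set]
    values[idx, :] += effect
    return GeneScoreMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), values, matrix.n_loci.copy()
    )


def random_score_matrix(
    gene_ids: Sequence[str],
    n_samples: int = 1,
    seed: int = 0,
    score_dist: Tuple[str, Tuple] = ("normal", (0.0, 1.0)),
) -> GeneScoreMatrix:
    """Gene x sample matrix of i.i.d. scores (a pure null gene profile)."""
    rng = np.random.default_rng(seed)
    values = _draw_scores(rng, len(gene_ids) * n_samples, score_dist).reshape(
        len(gene_ids), n_samples
    )
    return GeneScoreMatrix(
        list(gene_ids), [f"S{j + 1}" for j in range(n_samples)], values
    )


def random_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int,
    size: int,
    seed: int = 0,
    weights: Optional[Sequence[float]] = None,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene-sets of a fixed size drawn from ``gene_ids``.

    ``weights`` biases the draw (e.g. proportional to gene length, to emulate
    the length structure of real pathway catalogs).
    """
    if size >= len(gene_ids):
        raise ValueError("set size must be smaller than the universe")
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    sets: Dict[str, GeneSet] = {}
    ids = list(gene_ids)
    for i in range(n_sets):
        members = rng.choice(ids, size=size, replace=False, p=p)
        sid = f"{prefix}{i + 1:04d}"
        sets[sid] = GeneSet(sid, f"random size-{size} set", [str(g) for g in members])
    return GeneSetCollection(sets=sets, source="fixtures.random_gene_sets")
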