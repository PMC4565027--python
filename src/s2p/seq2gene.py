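"""Many-to-many locus-to-gene mapping with typed relations.

Each locus (peak, SNP, scored interval) is linked to every gene whose body or
promoter it intersects, labelled by the most specific structural feature it
touches (priority cds > utr > exon > intron > promoter).  Loci that hit no
gene body additionally receive ``neighbor`` links to every gene whose TSS
lies within the search radius; in SNP mode neighbor links are emitted even
for intragenic loci, since a point variant may regulate a neighboring gene
rather than its host.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    intervals_overlap,
    query_overlaps,
    query_radius,
    tss_offset,
)
from .provenance import read_table, write_table

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 100_000

MAPPING_TYPES = ("cds", "utr", "exon", "intron", "promoter", "neighbor")
_STRUCTURAL_PRIORITY = ("cds", "utr", "exon", "intron")


@dataclass
class Locus:
    locus_id: str
    chrom: str
    interval: Interval
    score: float = 1.0
    is_snp: bool = False

    def __post_init__(self) -> None:
        s, e = self.interval
        if not s < e:
            raise ValueError(
                f"locus {self.locus_id}: start must be < end, got [{s}, {e})"
            )
        if not pd.notna(self.score) or self.score in (float("inf"), float("-inf")):
            raise ValueError(f"locus {self.locus_id}: score must be finite")


@dataclass
class LocusTable:
    loci: List[Locus]
    source: Optional[str] = None

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "chrom": [l.chrom for l in self.loci],
                "start": [l.interval[0] for l in self.loci],
                "end": [l.interval[1] for l in self.loci],
                "score": [l.score for l in self.loci],
                "is_snp": [l.is_snp for l in self.loci],
            }
        )


@dataclass
class MappingRecord:
    locus_id: str
    gene_id: str
    gene_symbol: str
    mapping_type: str
    signed_distance: int
    locus_score: float

    def __post_init__(self) -> None:
        if self.mapping_type not in MAPPING_TYPES:
            raise ValueError(f"unknown mapping type {self.mapping_type!r}")


@dataclass
class MappingTable:
    records: List[MappingRecord]
    parameters: Dict[str, object] = field(default_factory=dict)
    unmapped: List[str] = field(default_factory=list)
    locus_info: Dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            info = self.locus_info.get(r.locus_id, {})
            rows.append(
                {
                    "locus_id": r.locus_id,
                    "chrom": info.get("chrom", ""),
                    "start": info.get("start", -1),
                    "end": info.get("end", -1),
                    "score": r.locus_score,
                    "gene_id": r.gene_id,
                    "gene_symbol": r.gene_symbol,
                    "type": r.mapping_type,
                    "distance": r.signed_distance,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "locus_id", "chrom", "start", "end", "score",
                "gene_id", "gene_symbol", "type", "distance",
            ],
        )

    def write_tsv(self, path: str) -> None:
        write_table(self.to_dataframe(), path, params=self.parameters)


def read_mapping_tsv(path: str) -> MappingTable:
    """Read a mapping table previously written with :meth:`MappingTable.write_tsv`."""
    df, params = read_table(path)
    records = []
    info: Dict[str, dict] = {}
    for _, row in df.iterrows():
        records.append(
            MappingRecord(
                locus_id=str(row.locus_id),
                gene_id=str(row.gene_id),
                gene_symbol=str(row.gene_symbol),
                mapping_type=str(row.type),
                signed_distance=int(row.distance),
                locus_score=float(row.score),
            )
        )
        info[str(row.locus_id)] = {
            "chrom": str(row.chrom),
            "start": int(row.start),
            "end": int(row.end),
        }
    return MappingTable(records=records, parameters=params, locus_info=info)


# ---------------------------------------------------------------------------
# BED input
# ---------------------------------------------------------------------------

def read_loci_bed(path: str, score_column: Optional[int] = None) -> LocusTable:
    """Read loci from a BED3+ file (0-based half-open).

    ``score_column`` is a 1-based column index (BED5 score = column 5); when
    absent every locus scores 1.0 (pure count mode). The BED name column is
    used for locus ids when present and unique, otherwise sequential ids are
    assigned in file order.  1-bp intervals are flagged as SNPs.
    """
    rows: List[List[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: row {lineno}: fewer than 3 BED columns")
            rows.append([str(lineno)] + fields)
    if not rows:
        raise ValueError(f"{path}: no loci")

    names = []
    loci: List[Locus] = []
    for i, (lineno, *fields) in enumerate(rows):
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(
                f"{path}: row {lineno}: start >= end ({start} >= {end})"
            )
        score = 1.0
        if score_column is not None:
            if len(fields) < score_column:
                raise ValueError(
                    f"{path}: row {lineno}: no column {score_column}"
                )
            cell = fields[score_column - 1]
            try:
                score = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {lineno}: non-numeric score {cell!r} "
                    f"in column {score_column}"
                ) from exc
        name = fields[3] if len(fields) >= 4 else ""
        names.append(name)
        loci.append(
            Locus(
                locus_id=name,  # fixed below if unusable
                chrom=chrom,
                interval=(start, end),
                score=score,
                is_snp=(end - start == 1),
            )
        )
    usable = all(n and n != "." for n in names) and len(set(names)) == len(names)
    if not usable:
        for i, locus in enumerate(loci):
            locus.locus_id = f"locus_{i + 1:05d}"
    return LocusTable(loci=loci, source=path)


# ---------------------------------------------------------------------------
# classification and mapping
# ---------------------------------------------------------------------------

def classify_overlap(locus: Locus, gene: GeneModel) -> str:
    """Structural label for a locus intersecting a gene's body or promoter.

    The most specific feature touched across all transcripts wins
    (cds > utr > exon > intron); ``promoter`` only when the locus misses the
    gene body entirely.
    """
    iv = locus.interval
    s, e = iv
    body = s < gene.span[1] and gene.span[0] < e
    if body:
        hits = set()
        for t in gene.transcripts:
            if not (s < t.span[1] and t.span[0] < e):
                continue
            if t.is_coding:
                if intervals_overlap(iv, t.cds):
                    hits.add("cds")
                if intervals_overlap(iv, t.utrs):
                    hits.add("utr")
            elif intervals_overlap(iv, t.exons):
                hits.add("exon")
            if intervals_overlap(iv, t.introns):
                hits.add("intron")
        for label in _STRUCTURAL_PRIORITY:
            if label in hits:
                return label
        # body overlap outside any transcript span (gap between transcripts)
        return "intron"
    if s < gene.promoter[1] and gene.promoter[0] < e:
        return "promoter"
    raise ValueError(
        f"classify_overlap: locus {locus.locus_id} does not intersect "
        f"gene {gene.gene_id} body or promoter"
    )


def map_locus(
    locus: Locus,
    annotation: GenomeAnnotation,
    radius: int = DEFAULT_RADIUS,
    snp_mode: bool = False,
) -> List[MappingRecord]:
    """All mapping records for a single locus, sorted by (|distance|, gene_id)."""
    records: List[MappingRecord] = []
    emitted = set()
    body_hit = False
    for gid, kind in query_overlaps(annotation, locus.chrom, locus.interval):
        gene = annotation.genes[gid]
        label = classify_overlap(locus, gene)
        if label != "promoter":
            body_hit = True
            dist = 0
        else:
            dist = tss_offset(locus.interval, gene.tss, gene.strand)
        records.append(
            MappingRecord(
                locus_id=locus.locus_id,
                gene_id=gid,
                gene_symbol=gene.gene_symbol,
                mapping_type=label,
                signed_distance=dist,
                locus_score=locus.score,
            )
        )
        emitted.add(gid)
    if not body_hit or snp_mode:
        for gid, dist in query_radius(annotation, locus.chrom, locus.interval, radius):
            if gid in emitted or dist == 0:
                continue
            gene = annotation.genes[gid]
            records.append(
                MappingRecord(
                    locus_id=locus.locus_id,
                    gene_id=gid,
                    gene_symbol=gene.gene_symbol,
                    mapping_type="neighbor",
                    signed_distance=dist,
                    locus_score=locus.score,
                )
            )
    records.sort(key=lambda r: (abs(r.signed_distance), r.gene_id))
    return records


def _check_chrom_dialect(loci: LocusTable, annotation: GenomeAnnotation) -> None:
    if not len(loci):
        return
    known = set(annotation.index)
    miss = [l.chrom for l in loci if l.chrom not in known]
    if len(miss) / len(loci) > 0.9:
        alt = {c[3:] if c.startswith("chr") else "chr" + c for c in miss}
        hint = ""
        if alt & known:
            hint = (
                " — loci and annotation appear to use different chromosome "
                'naming dialects ("chr1" vs "1"); rename one side'
            )
        raise ValueError(
            f"{len(miss)}/{len(loci)} loci lie on chromosomes absent from "
            f"the annotation{hint}"
        )


def seq2gene(
    loci: LocusTable,
    annotation: GenomeAnnotation,
    radius: int = DEFAULT_RADIUS,
    snp_mode: bool = False,
) -> MappingTable:
    """Map every locus to its candidate target genes (many-to-many)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    _check_chrom_dialect(loci, annotation)
    records: List[MappingRecord] = []
    unmapped: List[str] = []
    info: Dict[str, dict] = {}
    for locus in loci:
        recs = map_locus(locus, annotation, radius=radius, snp_mode=snp_mode)
        info[locus.locus_id] = {
            "chrom": locus.chrom,
            "start": locus.interval[0],
            "end": locus.interval[1],
        }
        if recs:
            records.extend(recs)
        else:
            unmapped.append(locus.locus_id)
    if unmapped:
        logger.info("%d/%d loci unmapped", len(unmapped), len(loci))
    return MappingTable(
        records=records,
        parameters={
            "radius": radius,
            "snp_mode": snp_mode,
            "promoter_up": annotation.provenance.get("promoter_up"),
            "promoter_down": annotation.provenance.get("promoter_down"),
        },
        unmapped=unmapped,
        locus_info=info,
    )
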