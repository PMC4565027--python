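"""Gene-model annotation: GTF parsing, feature geometry, interval queries.

Internal coordinates are 0-based half-open throughout. GTF input is 1-based
inclusive and is converted at the boundary (``pyranges.read_gtf`` performs the
conversion); BED input is already 0-based half-open.

A gene's span is the union-span of its transcripts; the TSS is the
strand-aware 5' end of that span.  The promoter is a configurable window
around the TSS (default 2000 bp upstream, 0 bp downstream, strand-aware,
clamped at position 0).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pyranges

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

DEFAULT_PROMOTER_UP = 2000
DEFAULT_PROMOTER_DOWN = 0


# ---------------------------------------------------------------------------
# interval arithmetic (all half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: Sequence[Interval], minus: Sequence[Interval]) -> List[Interval]:
    """Set difference base \\ minus on merged half-open intervals."""
    base = merge_intervals(base)
    minus = merge_intervals(minus)
    out: List[Interval] = []
    for s, e in base:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intervals_overlap(a: Interval, ivs: Sequence[Interval]) -> bool:
    s, e = a
    return any(s < ie and ie_s < e for ie_s, ie in ivs)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One transcript: exon/CDS geometry with derived UTRs and introns.

    ``exons`` and ``cds`` are sorted non-overlapping half-open intervals;
    ``cds`` is empty for non-coding transcripts. UTRs are the exonic
    complement of the CDS, introns the span complement of the exons.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    span: Interval
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        self.cds = merge_intervals(self.cds)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        self.span = (min(self.span[0], lo), max(self.span[1], hi))
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if subtract_intervals(self.cds, self.exons):
            raise ValueError(
                f"transcript {self.transcript_id}: CDS extends outside exons"
            )

    @property
    def utrs(self) -> List[Interval]:
        if not self.cds:
            return []
        return subtract_intervals(self.exons, self.cds)

    @property
    def introns(self) -> List[Interval]:
        return subtract_intervals([self.span], self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class GeneModel:
    """A gene: union-span of its transcripts plus promoter geometry."""

    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    span: Interval
    transcripts: List[TranscriptModel]
    promoter: Interval = (0, 0)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end of the gene span (0-based position)."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    def set_promoter(self, up: int, down: int) -> None:
        """Promoter = [tss-up, tss+down) on '+', mirrored on '-', clamped at 0."""
        t = self.tss
        if self.strand == "+":
            lo, hi = t - up, t + down
        else:
            lo, hi = t + 1 - down, t + 1 + up
        self.promoter = (max(0, lo), max(0, hi))


@dataclass
class GenomeAnnotation:
    """Collection of gene models plus a per-chromosome interval index."""

    genes: Dict[str, GeneModel]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._build_index()
        self._warned_chroms: set = set()

    def _build_index(self) -> None:
        by_chrom: Dict[str, List[GeneModel]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        self.index: Dict[str, Dict[str, np.ndarray]] = {}
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: g.gene_id)
            self.index[chrom] = {
                "gene_id": np.array([g.gene_id for g in gs], dtype=object),
                "body_start": np.array([g.span[0] for g in gs]),
                "body_end": np.array([g.span[1] for g in gs]),
                "prom_start": np.array([g.promoter[0] for g in gs]),
                "prom_end": np.array([g.promoter[1] for g in gs]),
                "tss": np.array([g.tss for g in gs]),
                "strand_plus": np.array([g.strand == "+" for g in gs]),
            }

    @property
    def chroms(self) -> List[str]:
        return sorted(self.index)

    def gene_ids(self) -> List[str]:
        return sorted(self.genes)

    def _chrom_index(self, chrom: str):
        idx = self.index.get(chrom)
        if idx is None and chrom not in self._warned_chroms:
            self._warned_chroms.add(chrom)
            logger.warning("chromosome %r not present in annotation", chrom)
        return idx


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def query_overlaps(
    annotation: GenomeAnnotation, chrom: str, interval: Interval
) -> List[Tuple[str, str]]:
    """Genes whose body or promoter intersects ``interval``.

    Returns ``(gene_id, kind)`` pairs sorted by gene_id, ``kind`` being
    ``"body"`` when the gene body intersects (body wins when both do) and
    ``"promoter"`` otherwise.  An unknown chromosome yields an empty list.
    """
    s, e = interval
    if e <= s:
        raise ValueError(f"empty interval {interval}")
    idx = annotation._chrom_index(chrom)
    if idx is None:
        return []
    body = (idx["body_start"] < e) & (idx["body_end"] > s)
    prom = (idx["prom_start"] < e) & (idx["prom_end"] > s)
    out = [(gid, "body") for gid in idx["gene_id"][body]]
    out += [(gid, "promoter") for gid in idx["gene_id"][prom & ~body]]
    return sorted(out)


def tss_offset(interval: Interval, tss: int, strand: str) -> int:
    """Signed genomic offset of the locus relative to the TSS.

    0 when the locus covers the TSS; otherwise the distance from the nearest
    covered position to the TSS, negative when the locus lies upstream of the
    TSS in the gene's strand orientation.
    """
    s, e = interval
    if s <= tss < e:
        return 0
    off = (e - 1) - tss if tss >= e else s - tss
    return off if strand == "+" else -off


def query_radius(
    annotation: GenomeAnnotation, chrom: str, interval: Interval, radius: int
) -> List[Tuple[str, int]]:
    """Genes whose TSS lies within ``radius`` bp of the locus' nearest edge.

    Inclusion is closed (``|distance| <= radius``). Returns
    ``(gene_id, signed_distance)`` sorted by (|distance|, gene_id).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    s, e = interval
    if e <= s:
        raise ValueError(f"empty interval {interval}")
    idx = annotation._chrom_index(chrom)
    if idx is None:
        return []
    tss = idx["tss"]
    gap = np.where(
        (tss >= s) & (tss < e),
        0,
        np.where(tss >= e, tss - (e - 1), s - tss),
    )
    keep = gap <= radius
    out = []
    for gid, t, plus in zip(
        idx["gene_id"][keep], tss[keep], idx["strand_plus"][keep]
    ):
        out.append((gid, tss_offset(interval, int(t), "+" if plus else "-")))
    out.sort(key=lambda r: (abs(r[1]), r[0]))
    return out


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: bad interval "
                    f"[{start}, {end}]"
                )
            if fields[6] not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand symbol {fields[6]!r}"
                )


def read_gtf(
    path: str,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Needs ``exon`` rows carrying ``gene_id`` (and ideally ``transcript_id``);
    ``CDS`` rows are used when present; explicit gene/transcript rows are
    optional (spans are derived from exon unions). ``gene_name`` supplies the
    symbol, falling back to the gene_id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            raise ValueError(f"{path}: no gene records")
    df = pyranges.read_gtf(path).df  # 0-based half-open
    if df.empty:
        raise ValueError(f"{path}: no gene records")
    for col in ("gene_name", "transcript_id"):
        if col not in df.columns:
            df[col] = None
    exon_rows = df[df.Feature == "exon"]
    cds_rows = df[df.Feature == "CDS"]
    if exon_rows.empty:
        raise ValueError(f"{path}: no gene records (no exon rows)")

    symbols = {}
    for _, row in df.iterrows():
        gid = row.gene_id
        name = row.get("gene_name")
        if gid not in symbols or (isinstance(name, str) and name):
            if isinstance(name, str) and name:
                symbols[gid] = name
    transcripts: Dict[Tuple[str, str], dict] = {}

    def _tx_key(row) -> Tuple[str, str]:
        tid = row.transcript_id
        if not isinstance(tid, str) or not tid:
            tid = f"{row.gene_id}.t1"  # exon rows without transcript ids
        return (row.gene_id, tid)

    for _, row in exon_rows.iterrows():
        rec = transcripts.setdefault(
            _tx_key(row),
            {"chrom": row.Chromosome, "strand": row.Strand, "exons": [], "cds": []},
        )
        rec["exons"].append((int(row.Start), int(row.End)))
    for _, row in cds_rows.iterrows():
        key = _tx_key(row)
        if key in transcripts:
            transcripts[key]["cds"].append((int(row.Start), int(row.End)))

    genes: Dict[str, GeneModel] = {}
    for (gid, tid), rec in transcripts.items():
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_symbol=symbols.get(gid, gid),
            chrom=str(rec["chrom"]),
            strand=str(rec["strand"]),
            span=(min(s for s, _ in rec["exons"]), max(e for _, e in rec["exons"])),
            exons=rec["exons"],
            cds=rec["cds"],
        )
        g = genes.get(gid)
        if g is None:
            genes[gid] = GeneModel(
                gene_id=gid,
                gene_symbol=tm.gene_symbol,
                chrom=tm.chrom,
                strand=tm.strand,
                span=tm.span,
                transcripts=[tm],
            )
        else:
            g.transcripts.append(tm)
            g.span = (min(g.span[0], tm.span[0]), max(g.span[1], tm.span[1]))
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
        g.set_promoter(promoter_up, promoter_down)
    return GenomeAnnotation(
        genes=genes,
        provenance={
            "source": os.path.abspath(path),
            "promoter_up": promoter_up,
            "promoter_down": promoter_down,
        },
    )


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation back to GTF (1-based inclusive coordinates)."""
    rows = []

    def _fmt(chrom, feature, iv, strand, attrs):
        return (
            f"{chrom}\ts2p\t{feature}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t{attrs}"
        )

    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        gattr = f'gene_id "{g.gene_id}"; gene_name "{g.gene_symbol}";'
        rows.append(_fmt(g.chrom, "gene", g.span, g.strand, gattr))
        for t in g.transcripts:
            tattr = (
                f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{g.gene_symbol}";'
            )
            rows.append(_fmt(g.chrom, "transcript", t.span, g.strand, tattr))
            for iv in t.exons:
                rows.append(_fmt(g.chrom, "exon", iv, g.strand, tattr))
            for iv in t.cds:
                rows.append(_fmt(g.chrom, "CDS", iv, g.strand, tattr))
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
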