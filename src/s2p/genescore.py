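"""Collapse per-locus scores into one score per gene per sample.

When a gene is hit by several loci (e.g. SNPs in linkage disequilibrium, or
multiple peaks) their scores are collapsed into a single per-gene value; the
default statistic keeps the score of largest magnitude.  A locus mapping to
the same gene through several feature types contributes once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .provenance import read_table, write_table
from .seq2gene import MappingTable

COLLAPSE_METHODS = ("max_abs", "max", "min", "mean", "median", "count")


@dataclass
class GeneScoreMatrix:
    """Gene-by-sample score matrix with per-cell contributing-locus counts."""

    gene_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    n_loci: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.n_loci is None:
            self.n_loci = np.zeros(self.values.shape, dtype=int)
        self.n_loci = np.asarray(self.n_loci, dtype=int)
        if self.n_loci.shape != self.values.shape:
            raise ValueError("n_loci shape inconsistent with values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gene score matrix contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def sample_vector(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)

    def reindex(self, gene_ids: Sequence[str], fill: float = 0.0) -> "GeneScoreMatrix":
        """Expand/restrict to ``gene_ids``; absent genes take ``fill``."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        vals = np.full((len(gene_ids), len(self.sample_ids)), float(fill))
        nl = np.zeros((len(gene_ids), len(self.sample_ids)), dtype=int)
        for i, g in enumerate(gene_ids):
            j = pos.get(g)
            if j is not None:
                vals[i] = self.values[j]
                nl[i] = self.n_loci[j]
        return GeneScoreMatrix(list(gene_ids), list(self.sample_ids), vals, nl)


def _collapse_values(scores: np.ndarray, method: str) -> float:
    if method == "max_abs":
        return float(scores[int(np.argmax(np.abs(scores)))])
    if method == "max":
        return float(np.max(scores))
    if method == "min":
        return float(np.min(scores))
    if method == "mean":
        return float(np.mean(scores))
    if method == "median":
        return float(np.median(scores))
    if method == "count":
        return float(len(scores))
    raise ValueError(
        f"unknown collapse method {method!r}; choices: {', '.join(COLLAPSE_METHODS)}"
    )


def collapse_to_genes(
    mapping: MappingTable, sample_id: str, method: str = "max_abs"
) -> GeneScoreMatrix:
    """One score per gene from its contributing loci (single sample).

    Each distinct locus contributes once per gene even when it maps through
    several feature types.  ``max_abs`` (default) keeps the score of largest
    magnitude, preserving its sign; ``count`` ignores scores entirely.
    """
    if method not in COLLAPSE_METHODS:
        # surface the full choice list for typos
        _collapse_values(np.array([0.0]), method)
    if not len(mapping.records):
        raise ValueError("mapping table is empty; nothing to collapse")
    per_gene: Dict[str, Dict[str, float]] = {}
    for r in mapping.records:
        per_gene.setdefault(r.gene_id, {})[r.locus_id] = r.locus_score
    gene_ids = sorted(per_gene)
    values = np.empty((len(gene_ids), 1))
    n_loci = np.empty((len(gene_ids), 1), dtype=int)
    for i, g in enumerate(gene_ids):
        # canonical locus order: exact invariance to input record order
        scores = np.array(
            [per_gene[g][l] for l in sorted(per_gene[g])], dtype=float
        )
        values[i, 0] = _collapse_values(scores, method)
        n_loci[i, 0] = len(scores)
    return GeneScoreMatrix(gene_ids, [sample_id], values, n_loci)


def merge_samples(
    matrices: Sequence[GeneScoreMatrix], fill_missing: float = 0.0
) -> GeneScoreMatrix:
    """Merge single-sample matrices over the union of their genes."""
    if not matrices:
        raise ValueError("no matrices to merge")
    sample_ids: List[str] = []
    for m in matrices:
        for s in m.sample_ids:
            if s in sample_ids:
                raise ValueError(f"duplicate sample_id {s!r}")
            sample_ids.append(s)
    gene_ids = sorted(set().union(*[set(m.gene_ids) for m in matrices]))
    parts = [m.reindex(gene_ids, fill=fill_missing) for m in matrices]
    return GeneScoreMatrix(
        gene_ids,
        sample_ids,
        np.hstack([p.values for p in parts]),
        np.hstack([p.n_loci for p in parts]),
    )


def read_gene_matrix(path: str) -> GeneScoreMatrix:
    """Read a user-supplied gene x sample TSV (header row of sample ids)."""
    df, _ = read_table(path)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty gene matrix body")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    dup = pd.Series(genes)[pd.Series(genes).duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(map(str, dup))}")
    samples = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]
    for j, col in enumerate(body.columns):
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = body.index[coerced.isna() & body[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric cell at gene {genes[bad[0]]!r}, "
                f"sample {samples[j]!r}"
            )
        if coerced.isna().any():
            raise ValueError(f"{path}: missing value in column {samples[j]!r}")
    values = body.apply(pd.to_numeric).to_numpy(dtype=float)
    return GeneScoreMatrix(genes, samples, values)


def write_gene_matrix(
    matrix: GeneScoreMatrix, path: str, params: Optional[dict] = None
) -> None:
    df = matrix.to_dataframe().reset_index().rename(columns={"index": "gene_id"})
    write_table(df, path, params=params)
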