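"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (position loops, exact
rational arithmetic, exhaustive enumeration) and deliberately avoids the
package's own interval helpers, so agreement is a real cross-check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


# ---------------------------------------------------------------------------
# locus -> gene mapping oracle
# ---------------------------------------------------------------------------

def _iv_overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]


def classify_oracle(interval, gene):
    """Position-by-position structural label, or None if no intersection."""
    s, e = interval
    if _iv_overlap(interval, gene.span):
        flags = set()
        for p in range(max(s, gene.span[0]), min(e, gene.span[1])):
            for t in gene.transcripts:
                if not (t.span[0] <= p < t.span[1]):
                    continue
                in_exon = any(es <= p < ee for es, ee in t.exons)
                if in_exon:
                    if t.cds:
                        in_cds = any(cs <= p < ce for cs, ce in t.cds)
                        flags.add("cds" if in_cds else "utr")
                    else:
                        flags.add("exon")
                else:
                    flags.add("intron")
        if not flags:
            flags.add("intron")  # inside gene span but between transcript spans
        for label in ("cds", "utr", "exon", "intron"):
            if label in flags:
                return label
    if _iv_overlap(interval, gene.promoter):
        return "promoter"
    return None


def tss_distance_oracle(interval, gene):
    """(|gap|, signed) TSS distance of the locus' nearest covered position."""
    s, e = interval
    tss = gene.span[0] if gene.strand == "+" else gene.span[1] - 1
    if s <= tss < e:
        return 0, 0
    nearest = s if abs(s - tss) <= abs((e - 1) - tss) else e - 1
    gap = abs(nearest - tss)
    signed = nearest - tss
    if gene.strand == "-":
        signed = -signed
    return gap, signed


def map_all_pairs_oracle(loci, annotation, radius, snp_mode):
    """Set of (locus_id, gene_id, type, distance) from an all-pairs scan."""
    out = set()
    genes = list(annotation.genes.values())
    for locus in loci:
        structural = {}
        body_hit = False
        for g in genes:
            if g.chrom != locus.chrom:
                continue
            label = classify_oracle(locus.interval, g)
            if label is not None:
                if label == "promoter":
                    _, signed = tss_distance_oracle(locus.interval, g)
                    structural[g.gene_id] = ("promoter", signed)
                else:
                    body_hit = True
                    structural[g.gene_id] = (label, 0)
        for gid, (label, d) in structural.items():
            out.add((locus.locus_id, gid, label, d))
        if not body_hit or snp_mode:
            for g in genes:
                if g.chrom != locus.chrom or g.gene_id in structural:
                    continue
                gap, signed = tss_distance_oracle(locus.interval, g)
                if 0 < gap <= radius:
                    out.add((locus.locus_id, g.gene_id, "neighbor", signed))
    return out


# ---------------------------------------------------------------------------
# statistic oracles
# ---------------------------------------------------------------------------

def hypergeom_upper_tail_exact(a, n_total, k_in, n_sig):
    """P[X >= a], X ~ Hypergeom(N, K, n), as an exact Fraction."""
    denom = comb(n_total, n_sig)
    total = Fraction(0)
    for x in range(a, min(k_in, n_sig) + 1):
        if n_sig - x <= n_total - k_in:
            total += Fraction(comb(k_in, x) * comb(n_total - k_in, n_sig - x), denom)
    return total


def ks_d_bruteforce(xs, ys):
    """sup |ECDF_x - ECDF_y| evaluated at every sample point."""
    points = sorted(set(xs) | set(ys))
    d = 0.0
    for p in points:
        fx = sum(1 for v in xs if v <= p) / len(xs)
        fy = sum(1 for v in ys if v <= p) / len(ys)
        d = max(d, abs(fx - fy))
    return d


def rank_sum_enumeration(ranks, k, t_obs, tol=1e-9):
    """(p_lower, p_upper): exact tails of the in-set rank sum over C(N, k)."""
    sums = [sum(c) for c in combinations(ranks, k)]
    n = len(sums)
    p_low = sum(s <= t_obs + tol for s in sums) / n
    p_high = sum(s >= t_obs - tol for s in sums) / n
    return p_low, p_high
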