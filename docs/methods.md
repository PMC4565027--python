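# Methods

## Problem

Most gene-set (pathway) enrichment tools start from genes. Sequencing
experiments, however, produce *loci* — ChIP-seq peaks, trait-associated
SNPs, scored intervals — most of which are non-coding and act on genes in
cis, sometimes across tens of kilobases and sometimes on a neighbor rather
than the host gene. `s2p` bridges this gap in two stages:

1. **seq2gene** — a many-to-many mapping from loci to candidate target
   genes, each link typed by the structural feature it touches;
2. **gene2pathway** — condensation of the resulting gene-by-sample score
   matrix into gene-set-by-sample scores, with permutation-based empirical
   p-values and Benjamini-Hochberg FDR control.

## Locus-to-gene mapping

Coordinates are 0-based half-open internally; GTF (1-based inclusive) and
BED (already half-open) are converted only at the I/O boundary.

A gene model is the union-span of its transcripts; its TSS is the
strand-aware 5' end of that span, and its promoter a window around the TSS
(default 2000 bp upstream, 0 bp downstream, strand-aware, clamped at
position 0). Per-gene rather than per-transcript promoters keep the mapping
one record per (locus, gene); the window is configurable because no single
convention is universal.

For each locus:

* **Structural links.** Every gene whose body or promoter the locus
  intersects yields one record, labelled by the most specific feature
  touched across all transcripts, with priority
  `cds > utr > exon > intron > promoter`. Exonic overlap on a non-coding
  transcript (no CDS) is labelled `exon`, never `cds`/`utr`. A locus inside
  the gene span but between transcript spans counts as `intron`.
* **Neighbor links.** If the locus hits no gene body, every gene whose TSS
  lies within the search radius of the locus' nearest edge (closed
  inclusion, `|d| <= radius`) gets a `neighbor` record. Distances are
  signed: negative when the locus lies upstream of the TSS in the gene's
  strand orientation. The default radius is 100 kb; 5 kb is a common
  conservative choice for promoter-proximal work.
* **SNP mode.** A point variant inside one gene may regulate another, so
  with `snp_mode` neighbor records are emitted even for intragenic loci
  (host-gene structural records are kept; the neighbor set always contains
  the non-SNP output).

Locus strand is ignored (peaks and SNPs are unstranded). Equidistant TSSs
are all reported — the mapping is many-to-many by design — and output order
is deterministic (|distance|, then gene id).

## Gene profile

Scores of multiple loci hitting one gene are collapsed to a single value
per gene per sample. The default statistic `max_abs` keeps the score of
largest magnitude with its sign — the strongest single piece of evidence —
which also defuses pseudo-replication from linked loci (e.g. SNPs in LD).
`max`, `min`, `mean`, `median` and `count` are available; a locus mapping
to a gene through several feature types contributes exactly once.
Contributions are reduced in a canonical (locus-id) order so the result is
exactly invariant to input record order. For set scoring the profile is by
default extended to the full annotated universe, with 0 ("no evidence")
for genes without loci.

## FAIME set score

For one sample with scores `x_g` over the `N`-gene universe:

1. rank genes descending (rank 1 = highest score, ties averaged);
2. weight `w_g = x_g * exp(-alpha * r_g / N)`;
3. `f(m) = mean_{g in m} w_g - mean_{g not in m} w_g`.

The exponential term concentrates the score on top-ranked genes while the
raw `x_g` keeps the statistic quantitative; `alpha` (default 5, exposed so
other members of this statistic family can be matched by configuration)
sets how fast low ranks are discounted — at `alpha=5` the weight of the
median-ranked gene is `e^-2.5 ~ 8%` of the top gene's. Two identities are
exact and tested to 1e-12: `f = 0` when all scores are equal, and
`f(m) = -f(complement of m)`. Negative input scores are allowed; weights
inherit their sign.

## Empirical p-values

For each (set, sample), the gene-score vector is shuffled over gene labels
`n_perm` times (default 1000) and the statistic recomputed; the add-one
estimator `p = (1 + #extreme)/(n_perm + 1)` (two-sided on |f| by default)
is valid and strictly positive, with floor `1/(n_perm+1)`. Shuffling over
the *full* universe is the point: it detaches score magnitude from set
membership, so a score pattern that merely tracks gene length (long genes
collect more loci under any uniform null) is reproduced by the null and
not called significant. A naive count test that treats each locus as
equally likely to hit any gene has no such protection and is demonstrably
anti-conservative on the same data (tested). Stratified (length-matched)
permutation is out of scope.

Each (set, sample) pair gets its own sub-seed derived from the global seed
by hashing `(seed, set_id, sample_id)` (SHA-256, reduced below 2^31), so
results are reproducible bit-for-bit given the seed, independent of the
order sets are scored in — though they are tied to the gene-row order of
the matrix, since the permutation stream operates on vector positions.
With `exhaustive=True` all `N!` label permutations are enumerated (small N
only) and the plain fraction is exact, since the identity permutation is
included.

BH FDR (via `statsmodels`) is applied per sample across sets, matching the
per-sample framing of the score; q-values dominate p-values elementwise.

## Alternative tests

* **Fisher** — exact hypergeometric upper tail on the 2x2 table of set
  membership vs significance. Binarization is an explicit user rule
  (`score >= t` or top-k; top-k ties broken by gene id) with *no default*:
  a silent threshold would manufacture results. The odds ratio uses the
  Haldane +0.5 correction only when a cell is zero; the p-value is never
  corrected.
* **KS** — two-sample two-sided Kolmogorov-Smirnov, in-set vs out-of-set
  scores, asymptotic p (via `scipy`).
* **Cumulative rank** — `T = sum of in-set descending ranks`; enrichment
  makes T small, so "greater" (greater enrichment) is the lower tail of T.
  For `N <= 10` the p comes from exhaustive enumeration of all `C(N, k)`
  rank subsets (tail inclusive, `<=`/`>=` with a 1e-9 tie tolerance);
  otherwise from the normal approximation with `E[T] = k(N+1)/2`,
  `Var[T] = k(N-k)(N+1)/12` (no tie correction) and a 0.5 continuity
  correction toward the mean. Against the exact Mann-Whitney tail at
  N=50, k=10 the approximation agrees within 0.05.

Default sidedness is two-sided everywhere; one-sided alternatives are a
flag away.

## Synthetic data

The fixtures generator states a small but structurally honest world:
non-overlapping genes packed on 1-2 chromosomes, log-normal gene lengths
(log-mean 9.2, log-sd 0.8: ~10 kb median with a heavy right tail — the
length heterogeneity that *drives* the bias the permutation null corrects),
log-normal intergenic gaps, 1-4 exons per gene, 1-3 transcripts with
internal exon skipping, 20% non-coding transcripts. Null loci fall either
uniformly on the genome (hit counts proportional to gene length) or
uniformly per gene (length-neutral); scores are i.i.d. from a stated
family. Everything takes an explicit seed and regenerates byte-identically.

What the generator does **not** emulate: overlapping/nested genes, LD
structure among SNPs, non-uniform peak placement (e.g. promoter
enrichment), chromatin domains, and real GO-style nested set catalogs.
Green calibration tests therefore establish validity under exchangeable
nulls on clean gene models, not robustness to those real-data features.
Note also that no per-sample shuffling scheme can protect a set that
*genuinely* has systematically longer genes and count-valued scores; the
correction addresses the null calibration, not confounding by design.

## Numerical choices

* Extremity comparisons in the permutation tail use a 1e-12 absolute guard
  so a permutation reproducing the observed value counts as extreme.
* `max_abs` resolves sign ties by first occurrence in canonical locus
  order (numpy argmax semantics).
* Degenerate inputs fail loudly: empty GTF/BED/GMT, sets that are empty or
  equal to the universe, all-or-nothing significance rules, p outside
  [0, 1].
* A chromosome-naming mismatch ("chr1" vs "1") is detected when >90% of
  loci miss the annotation, and reported as such rather than as an empty
  result.

## Limitations

* Per-gene (not per-transcript) TSS and promoter; alternative promoters
  are invisible.
* GTF subset only (gene/transcript/exon/CDS attributes `gene_id`,
  `transcript_id`, `gene_name`); no GFF3 ID/Parent graphs, no bundled
  genome annotations — users supply a GTF.
* Fisher/KS/cumulative-rank p-values are analytic, not permutation-based;
  only FAIME gets the empirical null.
* The permutation scheme is exchangeable over the whole universe;
  length-stratified or LD-preserving schemes are not implemented.
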