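# Methods

## Motif model and occurrence calling

A motif of length L is a count matrix `c[i,b]` over A, C, G, T.
Frequencies are derived with a pseudocount distributed by the background:

    f[i,b] = (c[i,b] + α·p[b]) / (Σ_b' c[i,b'] + α)

with total pseudocount α = 1.0 by default (the common convention for
JASPAR count matrices) and a uniform background p = (0.25, 0.25, 0.25,
0.25). The same pseudocounted matrix is used everywhere — information
content, log-odds scoring, logos — so there is exactly one model per
motif. Columns with all-zero counts are rejected as uninformative.

The information content `IC = Σ_i Σ_b f[i,b]·log2(f[i,b]/p[b])` (bits,
with 0·log 0 = 0) sets the per-motif occurrence threshold `P = 2^(−IC)`:
a motif carrying IC bits of specificity is called at the P-value a random
background sequence would reach with probability 2^(−IC). The threshold
is inclusive (window score ≥ threshold score), so a fully deterministic
motif's consensus — whose null probability is exactly 4^(−L) = 2^(−2L) —
passes its own dynamic threshold.

Scoring is standard log-odds, `s[i,b] = log2(f[i,b]/p[b])`; zero
frequencies (possible only with zero pseudocount, i.e. exact-sequence
motifs) are floored at 1e-4 before the log, deep enough that a single
mismatch can never reach an exact-sequence motif's threshold.

### Exact score-distribution P-values

P-values are exact under the i.i.d. background, not sampled: each column's
four scores are rounded to a grid of width `granularity` (default 1e-3
bits) and the column distributions are convolved position by position,
giving the pmf of the total window score. The survival function of that
pmf answers both `P(score ≥ s)` and the inverse threshold query
`score_of_pvalue(p)` = the smallest *attained* score whose tail
probability is ≤ p. Only attained grid points are kept in the support, so
inverse queries always return a score some k-mer actually achieves.

Accuracy: per-cell rounding can shift a k-mer's summed score by at most
L·granularity/2, so a query P-value can differ from the exact enumeration
value by at most the null mass lying that close to the query score. The
test suite checks this bound against exhaustive enumeration of all 4^L
k-mers for L ≤ 6. At the default granularity the bound is negligible for
every realistic matrix; granularity is configurable where tighter grids
are wanted.

### Scanning

The genome is integer-encoded once per chromosome; forward-strand window
scores are numpy gathers summed across columns, and the minus strand is
scored with the reverse-complemented score matrix on the same encoding
(mathematically identical to scoring the reverse-complement sequence).
Windows containing N are skipped; soft-masked (lowercase) bases are
scanned normally unless `exclude_softmasked` is set — the pipeline
filters composition artifacts through mappability/blacklist masks, not
repeat masking. A window passing on both strands (palindromes) yields two
occurrence records; region-level presence is boolean, so enrichment
counts are unaffected. Results are independent of chromosome chunking and
sorted by (chrom, start, strand).

## Controls

**Local controls** flank each region with half its size on each side
(left flank takes the extra base for odd sizes; flanks are clipped at
chromosome bounds), so the total flanking length equals the region
length.

**Global controls** are sampled from a pool of 500 bp windows sliding by
100 bp, stratified into the 11 G+C bins (per 100 bp)
0–19 / 20–29 / 30–34 / 35–39 / 40–44 / 45–49 / 50–54 / 55–59 / 60–69 /
70–79 / 80–100, treated half-open on the continuous scale ([80, 100]
closed). Windows must lie entirely inside the mappability mask when one
is given, overlap no blacklist interval, and contain ≤ 10% N (assembly
gaps). For each input region one window (configurable) is drawn uniformly
without replacement from the region's bin, rejected if it overlaps any
input region, then recentred and trimmed to the region's exact length —
so the bin histogram of the controls matches the input by construction
and enrichment percentages compare regions of identical lengths. The
sampler is a deterministic function of the seed.

When a region's exact bin holds no remaining window the default is an
error naming the bin and its deficit. The pipeline instead substitutes
the nearest non-empty bin (`on_exhausted="nearest"`): regions shorter
than the 500 bp windows have a wider G+C spread than the windows
themselves, so an extreme-composition region can lack an exact-bin window
even on a genome whose composition matches the regions perfectly —
substitution by the adjacent bin is the least-distorting completion and
is logged.

A QC warning fires when user-provided controls differ from the input by
more than 5 G+C per 100 bp in median — the regime where fold changes
start reflecting base composition rather than biology.

## Enrichment statistics

The counting unit is the region: k = number of regions with ≥ 1
occurrence. Significance of k_in out of n_in input regions against k_ctrl
out of n_ctrl controls is the upper-tail hypergeometric probability
including the observed count,

    p = P(X ≥ k_in),  X ~ Hypergeom(N = n_in + n_ctrl,
                                    K = k_in + k_ctrl, draws = n_in)

equivalent to `phyper(k_in − 1, K, N − K, n_in, lower.tail = FALSE)`.
Fold change is the ratio of percentages (robust to unequal control
multiplicity); 0-control cases render as `Inf`, 0/0 as `NA`. P-values
display down to 1e-300, below which "0" is printed. No multiple-testing
correction is applied — raw P-values are reported along with the motif
count so users can correct as they see fit. The table ranks by global
P-value, ties broken by descending global fold change, then motif id.

## Positional summaries

The metaplot value for motif m at offset d is the percent of regions in
which some occurrence of m covers the single base `center + d`, with
center = floor((start+end)/2). Coverage (not occurrence start) is used:
it matches the visual reading of a summit-centered peak and is stable
under motif length changes. Bases outside a short region never count for
its numerator, but the region always counts in the denominator, so
curves from region sets of mixed sizes taper honestly. The default
half-width is half the maximum region length. Optional moving-average
smoothing affects display only; TSV output is always raw.

The genomic view shows only regions containing ≥ 1 occurrence, one row
per region, bars scaled to the longest displayed region, paginated at 25
rows/page and capped at 10 pages (the overflow count is reported).
Sequence logos in legends draw letter heights proportional to
frequency × column IC (the standard logo convention).

All figures are SVG emitted by a small deterministic string writer:
identical inputs yield byte-identical files, which makes reproducibility
checkable with a plain byte comparison.

## Motif clustering

Similarity between two matrices is the maximum Pearson correlation of
flattened frequency columns over all ungapped offsets and both
orientations, requiring ≥ min(5, min(L1, L2)) overlapping columns.
Clustering is average-linkage hierarchical on d = 1 − similarity, cut at
0.2 (correlation ≥ 0.8), both configurable; the representative is the
member with the highest IC (ties: lexicographic id). Motifs are processed
in id order so results are independent of input order. This collapses
database redundancy for the "no motifs selected" default; it is not a
statistically calibrated motif comparison.

## Synthetic data

The generator emulates exactly the structure the pipeline consumes: an
i.i.d. genome with a single G+C parameter, non-overlapping equal-length
regions, and a consensus written (overwritten in place, coordinates
stable) into a fraction of regions at center + truncated-Gaussian jitter
on a random strand, with a truth table of every planted instance. The
canonical benchmark is a 500 kb chromosome at 41% G+C (mammalian-like),
200 regions of 200 bp, a 10 bp consensus planted in 80% of regions with
5 bp jitter — large enough for stable percentages and tail P-values,
small enough to run in seconds.

What the generator does *not* emulate: repeats, CpG islands, chromatin
structure, dinucleotide composition, read-level noise. Passing tests
therefore demonstrate correctness of the statistics and bookkeeping under
the stated null, not robustness to the composition artifacts of real
genomes — that is what the G+C matching and masks are for on real data.

The null-calibration experiment scans an unplanted fixture (200 replicates
of 100 input + 100 control regions) with a sharp 6-mer matrix motif
(IC ≈ 7.7 bits) whose dynamic threshold yields ~60% region presence —
mid-range presence maximises the resolution of the discrete
hypergeometric test; the observed fraction of P < 0.05 stays within
binomial 3σ of 0.05 and fold changes center at 1.

## Numerical and edge-case choices

- Coordinates are 0-based half-open everywhere; 1-based conversion
  happens only in browser-facing rendering.
- Track scores are round(−10·log10 p) capped at 1000 (UCSC convention).
- Region-count guard: runs outside 100–100 000 regions require an
  explicit force flag (warning, not hard error — single-region views are
  legitimate); region sizes over 1 kb log a hint that the genomic view is
  optimized below that.
- Exact-sequence motifs accept strictly A/C/G/T, lengths 6–12; no IUPAC
  ambiguity codes.
- Empty inputs error early with the offending file and line number for
  BED/GTF/JASPAR parsing.

## Known limitations

- The i.i.d. background ignores dinucleotide structure; exact P-values
  are exact only under that model.
- Nearest-bin substitution under pool exhaustion trades a little G+C
  fidelity for a complete control set; the manifest and logs record when
  it happened.
- Motif similarity is correlation-based redundancy collapsing, not a
  calibrated statistical comparison of matrices.
- SVG output is deliberately minimal (no interactivity, no embedded
  fonts); convert externally for PDF.
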