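# Methods

This note documents the models, parameter choices and numerical
conventions behind `crescan`, and what its synthetic-data tests do and do
not establish about real data.

## Coordinate model

All intervals are held internally as 0-based, half-open pairs. Published
coordinates for the same loci are printed under more than one convention —
element coordinates are consistent with end-exclusive arithmetic
(698 = 23,806,978 − 23,806,280) while deletion coordinates are consistent
with 1-based fully-closed arithmetic (993 = 23,807,226 − 23,806,234 + 1) —
so parsers and formatters take an explicit convention tag
(`zero_based_half_open`, `one_based_fully_closed`,
`one_based_end_exclusive`) rather than guessing. Conversion is lossless
both ways. Interval arithmetic uses half-open semantics throughout:
intervals that share a boundary base abut but do not overlap.

The intergenic complement is computed against whole transcript footprints
plus standalone pseudogene fragments, not exon unions: introns and UTRs
count as genic, because candidate enhancers are required to sit outside
known coding sequence, UTRs and pseudogene fragments alike.

## Conservation

Two sources of conservation evidence are supported and deliberately kept
as inputs, not recomputed:

- an external per-base score track (phyloP-style), read from bedGraph or
  wiggle; uncovered bases are NaN, never 0;
- a percent-identity profile computed from a pairwise alignment in the
  spirit of classic percent-identity plots: for each reference base, the
  percent of identical columns in a `window` bp window (default CLI
  window 50 bp). Columns gapped in the reference carry no score; a gap in
  the other row counts as a mismatch. Windows near the ends are clamped
  (shifted inward) rather than shrunk, so every position is averaged over
  the same number of reference bases.

**Segment calling.** Maximal runs of bases at or above a threshold are
merged across sub-threshold gaps of at most `merge_gap` bp (default 20)
and discarded below `min_len` bp (default 50). The defaults are an order
of magnitude below the 345–698 bp elements the pipeline is designed to
find, so true elements are never length-filtered away while isolated
noise spikes are.

**Thresholding.** The discovery pipeline smooths the track with a 25 bp
clamped rolling mean and then applies, by default, a robust threshold:
median + 6 scaled MADs (median absolute deviation × 1.4826) of the
smoothed track. The reasoning: under a neutral background the smoothed
score is approximately Gaussian around the background identity level, and
truly conserved elements occupy well under 1% of a cluster, so the median
and MAD estimate the noise distribution essentially uncontaminated; a 6σ
excursion sustained for ≥ 50 bp is vanishingly improbable under the null
while conserved elements sit far above it. A fixed-percentile rule was
rejected as the default because it marks a fixed fraction of bases by
construction — it over-calls on clusters with no conserved element and
splits elements when the conserved fraction exceeds the percentile's
complement. Percentile (`conservation_mode: percentile`) and absolute
(`conservation_absolute`) thresholds remain available in the
configuration; all three are recorded in the run report.

## Motif scanning

Scanning is exact IUPAC set-membership per position — no position weight
matrices. An `N` in the subject sequence is unknown and matches only a
fully degenerate pattern position, so ambiguous sequence cannot create
hits. Minus-strand hits are found by scanning the forward sequence with
the reverse-complement pattern; footprints are always reported in forward
coordinates, with the matched word read 5′→3′ on the matching strand. A
forward and a reverse hit with the same footprint are both reported;
`dedupe_footprints` collapses them, which matters for
self-reverse-complementary patterns such as `YCCCNNGGGR` where both-strand
counts are exactly double the forward counts. Overlapping hits are all
reported (no greedy masking).

Motif clusters ("*k* copies within *w* bp", e.g. a TAATGA triad within
206 bp) use first-footprint-start to last-footprint-end span ≤ *w* by
default; a pairwise-start-distance semantics is available. Reported
clusters are maximal: no further match can be added without violating the
window, and groups contained in a reported group are suppressed.

Because homeodomain-site counts are reported in the literature without a
stated strand convention, the candidate report carries forward-only and
both-strand counts side by side rather than committing to one.

## Cross-species motif conservation

Reference-coordinate positions are projected through the alignment to
columns (and back). For each reference motif hit, each species' aligned
window is the column slice under the footprint with gaps removed; the
species supports the instance only if that window has exactly the
pattern's length and satisfies it (optionally: is the identical word,
`exact_variant`). Support is binary — no partial credit — matching how
conserved sites are called from alignment figures. The support fraction is
computed over all species including the reference (which always supports
its own hit). The default support threshold is 0.8, exposed in
configuration, since "conserved across species" is used in the field
without a numeric rule; at 16 species this tolerates up to three divergent
species.

## Shared homology and database search

`find_shared_blocks` seeds on exact k-mers (default 8; both strands) and
extends each seed without gaps in both directions for as long as the
block's running identity stays at or above `min_identity` (default 0.9),
then trims flanking mismatches, deduplicates blocks contained in longer
blocks on the same diagonal, and ranks by identity × length. At
`min_identity = 1.0` this provably enumerates all maximal exact shared
substrings of at least `min_len` bp (every such block contains a seed),
and the test suite asserts equality with a brute-force all-substring-pairs
oracle there. For `min_identity < 1` the greedy prefix-identity extension
is a heuristic — it can stop one mismatch short of a longer valid block —
so its behavior is pinned by planted-truth and null simulations instead.

`scan_database_with_qvalues` replaces an external FIMO/BLAST step with an
exact, self-contained computation. In degenerate mode, the probability
that one background window satisfies an IUPAC pattern is the product over
positions of the summed frequencies of allowed bases under a 0-order
background (estimated from the database itself by default, mirroring the
common default of motif-scanning tools). In mismatch mode a fixed query
word is scored by its best window's number of matching positions, whose
exact tail probability is computed by Poisson-binomial dynamic
programming. Either way, the per-window p-value is Bonferroni-corrected by
the number of windows scanned in that target (both strands counted) and
Benjamini–Hochberg q-values are computed across targets — the structure
behind per-target "FDR q < 0.05" statements. Null simulations confirm the
min-q false-positive rate stays within the FDR band.

## Candidate calling

Candidate boundaries are conserved-segment boundaries clipped to the
intergenic, unmasked search space; clipped pieces shorter than `min_len`
are dropped. Element edges are therefore conservative excisions of the
conservation signal, not motif-defined. Motif content (HD counts both
ways, conserved-HD count when an alignment is supplied, O/E count,
cluster-rule hits) annotates and ranks candidates but does not gate them —
the discovery criteria are the three filters; a `require_hd` gate is
available. Ranking is lexicographic: conserved-HD count (descending), mean
conservation (descending), coordinate. Identical inputs and configuration
produce byte-identical machine-readable reports.

## qPCR analysis

ΔCt is computed per sample as Ct(gene) − mean Ct(housekeeping genes),
after averaging technical replicates per (sample, gene). Subtracting the
arithmetic mean of housekeeping Ct values is algebraically identical to
normalizing by the geometric mean of the housekeeping expression
quantities 2^−Ct (the standard multi-gene normalization construction);
the equivalence is unit-tested. ΔΔCt is the difference of genotype-group
mean ΔCt from the control-group mean, and fold = 2^−ΔΔCt, so the control
fold is 1 by construction. Hypothesis tests are one-way ANOVA across
genotypes on the per-sample ΔCt values (not on folds), with Dunn–Šidák
family-wise adjustment p_adj = 1 − (1 − p)^m; the family size defaults to
the number of genes tested. Degenerate inputs (zero within-group variance)
yield p = 1 when group means are equal and p = 0 otherwise. Effects are
classified abolished (fold ≤ 0.05 and p_adj < 0.05), reduced
(fold < 1 and significant), or spared; both thresholds are configuration,
since published analyses state significance but no fold rule. Primer
efficiency is assumed ≈ 100% (2-fold per cycle); efficiency modelling is
out of scope.

## Synthetic data: what it emulates, and what it does not

`simulate_cluster` builds a 200 kb cluster of 15 two-exon genes (1 kb
exons, 2 kb intron) plus a pseudogene fragment on an i.i.d. uniform
background, and plants two elements (700 and 350 bp, echoing the real
element sizes) in the intergenic gaps after the 1st and 6th genes. Element
1 carries four designated-conserved HD words (TAATAG, TAATGA, TAATTA,
TAATCA) and three random extras; element 2 a conserved TAATCC, a TAATGA
triad spanning 141 bp, and three random extras; both carry three O/E-like
sites and an identical 30 bp shared block containing the tandem words
TTGCATCA and TAAAGTTTTC. So that the recorded truth is exact, accidental
background copies of the triad word (both strands, cluster-wide) and
accidental forward TAATNN or O/E hits inside elements are scrubbed by
point mutation. Repeats are random intervals (200–2000 bp) filling 10% of
the cluster away from the elements.

`simulate_orthologs` evolves 15 non-reference species from the reference
on a star phylogeny: each site substitutes independently with probability
0.25 (uniform over the three alternatives, Jukes–Cantor style), reduced
×0.1 inside elements and to zero at designated-conserved motif cores. No
indels in this version, so the alignment is positional; gap handling in
consumers is exercised with hand-built gapped fixtures instead. The
conservation track is the per-base fraction of species matching the
reference — an identity proxy with the same shape as a phylogenetic
score, not the phyloP statistic.

`simulate_qpcr` draws Ct = baseline(gene) − log2(fold) + mouse offset +
N(0, σ) with 5 mice per genotype, 3 technical replicates, σ = 0.2 cycles
and a mouse-level RNA-quantity offset (SD 0.5 cycles) that housekeeping
normalization removes. Abolished expression is modelled as a finite fold
floor (2^−10), since the Ct of an absent transcript is censored in
practice.

Passing closed-loop tests on these simulations demonstrates that the
implementation is internally correct and that the procedure recovers the
structures it was designed for under its stated noise model. It does not
demonstrate performance on real genomes: real background is not i.i.d.
(repeat families, compositional heterogeneity), real phylogenies are not
stars, real alignments contain indels and missing species, and real
conservation scores are model-based. Problem sizes in the test suite and
acceptance script (50 simulated clusters of 200 kb × 16 species, 200 qPCR
replicates, 100 null sequence pairs) were chosen as the package's own
defaults for stable statistics at interactive runtimes.

## Known limitations

- No gapped local alignment and no genome-scale search index; uniqueness
  claims are exercised on synthetic or user-supplied sequence sets only.
- No liftover between genome builds; cluster bounds (e.g. between flanking
  conserved genes) must be supplied by the user or an annotation lookup.
- The greedy mismatch-tolerant block extension is not an exact local
  aligner (see above).
- Gene identifiers in Ct tables are opaque labels; assays that co-amplify
  several family members are represented however the input table encodes
  them.
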