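# Methods

`bwtsv` detects genomic rearrangement breakpoints from paired-end WGS data of
matched tumor/normal samples in three stages: region prediction from
discordant pairs, candidate collection from a lossless BWT dictionary of the
raw reads, and base-pair localisation via multivalued edit-distance
functions.  This note records the models, the tunable parameters, the
numerical choices, and what the synthetic benchmark does and does not show.

## Read dictionary

All reads of a sample, together with their reverse complements, are indexed
as `$`-terminated strings in one Burrows-Wheeler transform with occurrence
checkpoints every 64 positions.  Indexing both strands means a
junction-spanning fragment is found regardless of sequencing strand with a
single forward-pattern backward search.  Construction is a packed
prefix-doubling suffix sort over the concatenated text (16 symbols packed
into the first radix key, then ~3 doublings for 90-bp reads); equal `$`
symbols are ordered by the text that follows them, which fixes one canonical
BWT without affecting occurrence counts (patterns never contain `$`).  This
is a deliberate desk-scale choice: the construction is exact and `O(n log n)`
with small constants, and makes no attempt at the external-memory or
wavelet-tree engineering needed for 100-Gbp archives.

## Coordinates, MLU and anchor queries

Chromosomes are concatenated with `$` separators into one global coordinate
system; N bases are encoded like separators, so they never match reads and
never participate in unique anchors.  The MLU (minimum length for
uniqueness) at a position is the shortest substring starting there, in a
given direction, occurring exactly once across both strands; it is computed
for every position of the doubled text (genome + reverse complement) from
one suffix array and its LCP array: `MLU(i) = 1 + max(LCP with lexicographic
neighbours)`, undefined where that length runs past the chromosome end.
Storing the doubled text's table gives leftward MLUs for free (the reverse
complement's rightward MLU), which is what the swapped scan pass needs.
Anchor queries are MLU + `alpha` windows (`alpha` = 3 bp), so a matching
read fragment is unique in the reference by construction; anchors longer
than 60 bp are skipped as repeat-ambiguous.

## Discordant pairs and 2D clustering

Pairs are kept when both ends are mapped, primary, the proper-pair flag is
unset and min(MAPQ) >= 30.  A pair becomes the point `(x, y)`, `x < y`, of
the 5' base coordinates.  The strand pair fixes one of four orientation
classes: a forward read precedes its breakpoint, a reverse read follows it,
so `(+,-)` is deletion-like, `(-,+)` duplication-like and `(+,+)`/`(-,-)`
the two inversion geometries.  Clustering alternates sort-and-partition on
the two axes (gap threshold = one insert length) to a fixed point, per
orientation class, with tumor and normal points pooled; clusters need >= 3
pairs (suppresses stray mismapped singletons).  A cluster is somatic when
>= 90% of its pairs are tumor-derived.  The alternating fixed point equals
single-linkage connected components under "both axis gaps < L" adjacency on
all instances we generate; adversarial interleaved configurations where the
two disagree exist in principle and would be merged rather than split.

## Region prediction by the conjugate operator

With insert length ~ N(L, sigma) and no fragmentation bias, a junction at
`(x0, y0)` scatters its pairs by the operator `A = G_sigma U_L T_{L/2}`:
an isotropic 2D Gaussian (sd sigma), a uniform diffusion of per-axis extent
+-L/2 along the diagonal (anti-diagonal for inversion classes), and a
per-axis translation of L/2 whose sign per axis is the class's strand rule
('+' end: -L/2).  The prediction applies the conjugate to the empirical pair
counts, `z = A* y`, per cluster; breakpoint regions are the connected
components of `{z >= tau * max z}` (tau = 0.5, scale-free across coverages),
each with its two 1D projections.  The normal operator `A*A = G_{sqrt2
sigma} U_L^2` is symmetric and positive semi-definite; the implementation
realises its Gaussian factor as the exact composition of the two
sigma-truncated kernels so the identity with forward-then-conjugate holds to
machine precision.

Numerical choices: 1-bp bins on per-cluster grids; Gaussian kernels
truncated at +-4 sigma and renormalised (`scipy.ndimage`); the uniform
diagonal diffusion is a length-(L+1) centered kernel applied down sheared
columns, which is exactly self-adjoint; grids are padded so operator mass
cannot leave them (asymmetric padding on the conjugate path — the
translation moves mass only toward the junction).  The operator is an
approximation of the exact generative law: it smooths the insert-length
jitter isotropically, so the first moments of the pair scatter are exact
while the anti-diagonal width is modestly over-dispersed (per-axis sd sigma
instead of sigma/2).  This blurs `z` slightly but leaves its argmax
unbiased, which is all prediction uses.

## Breakpoint scan and calling

Each region is scanned twice (projection A, then B — the swapped pass), on
each sample.  A flank retained to the left of its breakpoint ('+' class
ends) is scanned on the reverse complement so its continuation becomes
rightward.  At each scan position the anchor query is looked up in the read
dictionary and all leftward extensions to 20 bp are enumerated (recursive
A/C/G/T probes).  Each supported extension contributes one value of the
multivalued profile: normalised distance to the local reference context and
to the partner region (both strands; Myers' bit-parallel semi-global
distance, pattern <= 64 symbols in one machine word, verified against the
classic DP).

A branch is junctional when its full extension does not align to the local
reference (normalised distance > 0.3) while its non-reference prefix (>= 10
bp after removing the maximal exact reference suffix) aligns to the partner
within 0.1.  Using full-extension alignment for the reference-band test is
essential: SNP and sequencing-error branches differ from the reference by
one edit (normalised 0.05) and must stay in the band, not become candidates
— this is what keeps the false-detection rate at zero.  The breakpoint on
the scanned side is the anchor position minus the matched reference suffix;
the partner coordinate is the end of the prefix's best partner alignment.
Support may be re-counted for a shorter prefix (flank suffix + 10-bp
partner anchor) via the dictionary, trading extension depth for read count;
>= 2 supporting reads are required.  Micro-homology at a junction makes the
reported coordinates ambiguous by the homology length (typically +-1 bp).

The two scan directions are merged (consistency within 2 x alpha); the
call's orientation class is derived from the evidence itself — scanned-flank
orientation plus partner strand — rather than inherited from the region, so
a junction picked up through a neighbouring cluster's region is still typed
and deduplicated correctly.  A call is somatic when the normal sample shows
no junctional branch within 5 bp of the same locus.  Short templated or
random insertions at a junction shift the partner prefix rather than
breaking it and are tolerated up to the alignment threshold (~2 bp at the
defaults); longer insertions suppress the partner match and the call.

## Internal mapper

The pipeline carries its own exact-seed mapper so simulations need no
external aligner: the first 30 bases of each read (both orientations) are
matched against a sorted table of the reference's 30-mers, with a
one-mismatch rescue for seeds hit by a sequencing error; placements are
verified by full-length mismatch counting (reject > 10), MAPQ is 60 for
unique placements and 0 otherwise, and the proper-pair flag requires
same-chromosome inward orientation with a template length within +-4 sd of
the insert mean.  On the synthetic genomes 30-mers are essentially unique,
so this mapper is near-exact; it does not model the mapping ambiguity of
real repeat-rich genomes.  When the insert model is not configured, the
pipeline estimates it robustly from accordant pairs (median template length;
1.4826 x MAD for the sd, floored at 1 bp), which tolerates a few percent of
artefactual outliers.

## Synthetic data

The generator emulates the evaluation protocol the method is designed for:
uniform-random chromosomes; a normal genome with 0.1% random SNPs; a cancer
genome with non-overlapping events of six types (lengths uniform in a
configured range, >= 3 kb apart and from chromosome ends, so truth junctions
are well separated relative to the 760-bp insert); 90-bp paired reads with
insert N(760, 45) at 40x; tumor purity as an exact mixing fraction of
cancer- and normal-genome read pairs.  Junction counts per event: insertion
2, deletion 1, inversion 2, tandem duplication 1, translocations 3
(cut-and-paste).  Insertions copy a segment of the normal genome
(copy-and-paste): inserted material must map somewhere for any
discordant-pair method to see the junctions at all — fully novel sequence
longer than about (insert length - 2 x read length) can never yield a pair
with both ends mapped, leaving its junctions invisible by construction, and
a discordant-pair predictor could then never approach the sensitivity the
protocol is meant to measure.  Sequencing errors are i.i.d. substitutions
at 0.1% (no indel errors, no duplicates, no GC bias).

What passing benchmarks show — and what they do not: the synthetic genome
has no repeat structure, so anchor MLUs are short and mapping is nearly
exact; real genomes add repeat-induced ambiguity (undefined or long MLUs,
MAPQ filtering losses) that the paper's own tandem-duplication results show
to be the binding constraint.  The benchmark therefore validates the
algorithmic chain (prediction geometry, dictionary queries, branch
detection, somatic logic), not performance on repeat-rich real data.

## Benchmark scale and evaluation

The standing benchmark uses a 1-Mbp two-chromosome genome with four events
of each type (48 truth junctions, event lengths 300 bp-5 kb) at 40x — sizes
chosen so the full sweep over purities 100/20/10% runs in minutes on one
core while each junction still receives realistic pair and read support.
The genome, truth set and matched normal are generated once per sweep; only
the tumor mix varies.  Sensitivity counts truth junctions matched by a call
within 10 bp on both coordinates (calls are single-base, but a matching rule
is needed and 10 bp is well below the minimum event spacing); the
false-detection rate is the fraction of calls matching no truth junction.
At 10% purity a junction is crossed by ~3 cancer-genome reads with enough
flanking sequence on both sides, so the >= 2-read support rule makes
per-junction detection a coin toss weighted near 75-80% — the sensitivity
plateau observed there is a read-depth limit, not an algorithmic one.
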