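# Methods

`hoxspec` quantifies how the genome-wide binding of related transcription
factors differs — in peak location, underlying sequence, chromatin context
and local DNA structure — using ChIP-Seq peak calls and normalized pileup
tracks as input. This note records the statistical procedures, their
assumptions, the defaults and why, and what the synthetic benchmark does
and does not establish.

## Coordinate and file conventions

All coordinates are 0-based half-open (BED native); a peak of length L
covers exactly L bases in every base-resolved computation. narrowPeak
summit offsets are converted to absolute coordinates on read. bedGraph
tracks are step functions with implicit zeros between steps; overlapping
steps are rejected (pileup output from standard peak callers never
overlaps), and values are assumed to be already depth-normalized (per
million reads) and are never rescaled. Peak analysis is restricted to a
chromosome whitelist, defaulting to the D. melanogaster euchromatic arms
(chr2L, chr2R, chr3L, chr3R, chr4, chrX, chrM).

## Peak-set algebra

Two peaks qualify as overlapping when the intersection covers at least a
fraction f of **both** intervals (reciprocal overlap, default f = 0.05,
the `bedtools intersect -f 0.05 -r` convention). The fractional test is
applied as `ov >= max(1, ceil(f * len))`, which enforces a 1 bp floor and
makes the stated fraction a true minimum; for integer overlaps this is
identical to bedtools' real-valued comparison, and the test suite
cross-checks against bedtools directly. A peak counts once however many
partners qualify (`-u` semantics); "specific" peaks have no qualifying
partner (`-v` semantics). Percent overlap of an empty set is reported as
NA, never as 0.

Reciprocal overlap is symmetric per pair but not transitive, so no
consistent 3-way Venn partition exists; 3-set comparisons are reported per
focal set (each set's peaks classified by which other sets they hit).
Peaks within a set are assumed non-overlapping; violations are kept and
logged rather than merged, since merging would silently change counts.

Chromatin-state prevalence is the fraction of total peak **length**
falling in segments of each of the five colour states (RED, YELLOW, BLUE,
BLACK, GREEN); bases in no annotated segment count as UNKNOWN, and the six
fractions sum to 1 exactly.

## Track statistics

The binding score per genome window (default 1 kb) is the mean per-base
pileup, implicit zeros included; terminal partial windows are averaged
over their actual length so all windows are comparable. Mean rather than
sum makes the statistic independent of window truncation. Pairwise
similarity of binding profiles is the Pearson correlation over all
whitelisted windows; zero-variance profiles yield NA with a warning.

Per-peak accessibility is the median track value over all bases of the
peak, uncovered bases contributing 0 — a peak more than half uncovered
therefore has median 0 by construction, which is deliberate: it keeps
barely-covered peaks from appearing accessible.

Differential ranking of peaks between two tracks uses
D = log2((a + c)/(b + c)) on the per-peak mean pileups with pseudocount
c = 0.1 (configurable). This is a deliberate, transparent replacement for
paired-track differential callers built on log-likelihood ratios: at
matched sequencing depth it is monotone in the same underlying signal
difference, is deterministic, and is exactly testable. Ties are broken by
genomic coordinate. A summit-window mode (mean over ±halfwidth around the
summit) is available by flag; the default uses the full peak interval.

## K-mer fingerprints

For a fixed panel of words (5-mers for Hox monomer cores, 8-mers for
Exd-Hox dimer composites), enrichment is
log2(foreground frequency per kb / background frequency per kb), with
overlapping occurrences counted and N positions never matching. The
background is the pooled set of 2 kb sequences upstream of TSSs (total
counts over total kb — one number per word, not a per-sequence average).
Counting is forward-strand by default, matching the frequency definition;
a both-strand mode exists because peaks are unstranded. Enrichment is
undefined (flagged, not ±inf) when either frequency is zero. The bundled
panels contain the published fingerprint members; full panels are
user-suppliable as one-word-per-line text files.

## PWM scanning and enrichment

PWMs are built from count matrices with probabilities
(count + pc·bg)/(total + pc), pseudocount pc = 0.01 allocated
proportionally to the background model (default: nucleotide frequencies
of the supplied background set; uniform otherwise). Log-odds scores are
quantized once onto a lattice of 0.01 bits. The null distribution of the
score of a random word under the 0-order background is computed exactly by
per-position convolution over that lattice, and the match threshold for a
p-value (default 0.001) is the smallest score whose exact tail probability
is ≤ p. Because the scanner uses the same quantized matrix, threshold,
scanner and null distribution agree to the lattice resolution — the test
suite verifies the tail against full 4^w enumeration. The 0.01-bit quantum
introduces score errors far below the granularity of the 0.001 threshold.
Windows containing N are skipped in both the scan and the tested-window
denominator; both strands are scanned and overlapping matches all kept.

Per-peak match density is (matches / peak length) × 1000; sets are
compared by a two-sided Mann-Whitney rank-sum test on per-peak densities.

Motif-set enrichment tests each motif's foreground match count m over n
scanned windows against Poisson(λn), where λ is the background match rate
per scanned window at the same exact-p-value cutoff; the score is
log10(1/p), capped (default 16). This Poisson count statistic replaces
lognormal-affinity group enrichment models: it is self-contained, exactly
testable, and monotone in the same signal. Absolute scores from
affinity-based tools will differ; the motif **ranking** is the comparable
output, and the documentation and tests treat it as such.

## DNA shape and GC profiles

Minor groove width is assigned per base from the pentamer centred on it
via a lookup table; the first/last two bases and N-containing pentamers
are missing. A pentamer and its reverse complement denote the same
double-helical context, so the table must be symmetric; asymmetric inputs
are symmetrized by averaging with a warning. Profiles are built over 2 kb
windows centred on peak summits (interval midpoint when no summit is
annotated, logged), averaged across peaks position-by-position first, then
smoothed with a 100 bp rolling mean at 10 bp steps — average-then-smooth,
reported at window midpoints. Missing values are excluded from numerator
and denominator, and per-position contributing-peak counts are reported so
thinly covered positions are visible. GC profiles use the per-base G/C
indicator with the same machinery.

A synthetic pentamer table (width = 5.8 − 0.5 × AT-count Å, range
3.3–5.8 Å) ships for tests and demonstrations. It preserves only the
dominant qualitative rule — AT tracts narrow the minor groove — inside the
physical range of real predictions; analyses of real data should supply a
real pentamer query table in the same two-column TSV format.

## Synthetic data generator

The generator emulates the statistical structure of the cultured-cell
experiment the pipeline is designed for, at desk scale:

- **Genome**: i.i.d. nucleotides at 42 % GC (fly euchromatin-like) over
  configurable chromosomes (study-structure scenario: 2 × 800 kb).
- **Chromatin states**: renewal process with exponential segment lengths
  (mean 5 kb, floor 200 bp) and genome-wide label weights defaulting to
  BLACK 0.48, YELLOW 0.17, BLUE 0.13, RED 0.12, GREEN 0.10; 8 % of
  segments left unannotated to exercise the UNKNOWN class.
- **Peak sets with controlled overlap**: a set copies a chosen fraction of
  an earlier set's peaks, jittered by ≤5 % of their length (guaranteeing
  reciprocal overlap ≥95 % for those pairs), and places the remainder
  disjoint from everything placed so far (guaranteeing zero overlap). The
  realized overlap fraction is therefore the copy fraction by
  construction and is recorded in the ground truth from provenance, not
  re-measured by the code under test.
- **State bias**: fresh peaks of designated sets are placed inside
  segments of sampled target colours.
- **Motifs**: planted by substitution (never insertion, so coordinates
  stay valid) at uniform positions inside designated peaks, with recorded
  coordinates; AT-rich summit cores (for shape contrasts) likewise.
- **Tracks**: per peak a triangular kernel (height = set amplitude,
  half-width = peak half-length) block-averaged at 10 bp over a 0.01
  noise floor, so median-signal distributions are non-degenerate;
  window-correlated track pairs are drawn from a bivariate normal
  (mean 5, sd 1, clipped at 0 — negligible mass) with the requested
  Pearson r.
- **Determinism**: one integer seed; each stage draws from an independent
  substream keyed by (seed, fixed stage offset), so adding a stage never
  perturbs earlier draws. Fixture regeneration is byte-identical.

What the generator does **not** emulate: read-level noise and fragment-size
effects, mappability artefacts, sequence composition heterogeneity
(isochores, repeats), correlated peak shapes, or realistic motif flanking
preferences. Passing recovery tests therefore demonstrates correctness of
the statistics and plumbing, not performance on real data.

## Benchmark problem sizes

The parameter-recovery scenario uses a 6 Mb genome with 1000-peak
reference/probe sets (planted overlap 0.89), 200-peak sets with exactly
2 vs 1 planted motif copies per 1 kb peak plus a motif-free control set
(the control measures the scanner's incidental match rate, which is
subtracted before forming the recovered ratio), a 150-peak BLUE/BLACK
biased set, and 10 000 correlated 1 kb windows at r = 0.6. These sizes put
binomial/sampling error well inside the stated recovery bounds
(±2 percentage points, ratio ±15 %, r ±0.05, bias direction at p < 0.01).
The study-structure scenario (`emulate_study_design`) uses a 1.6 Mb
genome, 300–400 peaks per factor and 300 TSSs, which the full pipeline
processes in a few seconds.

## Known limitations

- The Poisson enrichment score and the log2 differential ranking are
  monotone analogues, not re-implementations, of affinity-model enrichment
  and paired log-likelihood differential calling; absolute values are not
  comparable across tools.
- The exact PWM null assumes a 0-order background; k-order composition
  effects (e.g. CpG avoidance) are not modelled.
- Fingerprint counting is forward-strand by default; for palindrome-rich
  panels the both-strand flag changes absolute frequencies (never the
  identity foreground = background ⇒ enrichment 0).
- Stage results are recomputed on every pipeline run; no caching layer is
  maintained, since a desk-scale run completes in seconds and a content
  cache would add staleness risk for no benefit.
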