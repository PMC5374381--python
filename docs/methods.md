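# Methods

## Word-frequency representation

A read over A/C/G/T is mapped to the concatenation of its di-, tri- and
tetranucleotide relative-frequency blocks (16 + 64 + 256 = 336
features; word order is ascending k, lexicographic A<C<G<T within k).
Frequencies are *per block*: the count of each k-word is divided by the
number of windows of that length (L−k+1), so each block is a
probability simplex and a full row sums to the number of blocks. This
removes read-length scaling, which matters because downstream
correlations compare reads of slightly different lengths (e.g. after
homopolymer length errors). Words are not canonicalised by reverse
complement — amplicon reads have a defined strand, and collapsing
complements would halve the feature space. Reads shorter than the
longest word length are dropped, not zero-padded: padding would break
block normalisation. GC content is reported as (#G+#C)/L per read and
binned at 0.5% by default for distribution plots.

## Correlation pipeline

For two cells of reads (a *cell* is one group in one sample), Pearson's
r is computed between the frequency vectors of all read pairs — the
full Cartesian product across different cells; all unordered distinct
pairs, self-pairs excluded, within a cell. Each r is transformed to
Fisher z = artanh(r), the z values are averaged arithmetically, and the
mean is back-transformed to R = tanh(z̄). r is clipped to ±(1 − 1e-7)
before the transform: identical reads are legitimate (deduplication is
off by default precisely because duplicate reads carry abundance
information) and would otherwise send z to infinity.

When a cell pair has more than `max_pairs` (default 200 000) pairs, a
uniform seeded subsample of exactly `max_pairs` pairs is used and
flagged in the summary; on 200-read cells a 5 000-pair subsample stays
within ±0.02 of the exhaustive mean (tested). Reads with zero feature
variance are excluded with a logged count.

The inner-vs-outer wedge comparison is an unpooled two-sided two-sample
z statistic on the Fisher-z samples, with the pair counts as sample
sizes. Pairwise correlations sharing a read are not independent, so the
nominal p-values overstate precision; they are reported as a ranking
device, which is how such tests are used in practice for this
construction. Degenerate inputs (both z samples constant and equal)
raise rather than return a p-value.

## Heatmap assembly

Groups are ranked by the *smaller* of their two per-sample read counts
(both cells must be populated), ties broken lexicographically, and the
top N (default 4) are kept. The nearest group for an outer wedge is by
default the candidate with the highest Fisher-mean cross-correlation
within the sample; a PCA-centroid alternative (nearest group-centroid
in the first-two-PC score space) is selectable, and the two can be
cross-checked with a logged warning on disagreement. The pattern label
is per-group strict: `phylogenetic_clustering` when every inner R
exceeds both of its outer Rs, `sample_clustering` when every inner R is
below both, `mixed` otherwise.

Shading maps R to a gray level, darker = lower. The default
`fixed_unit` scale clips R to [0, 1] so shades are comparable across
runs; `data_range` rescales over the model's own wedge range, which
maximises per-figure contrast at the cost of comparability. Negative R
(possible between dissimilar groups) is clipped for shading but
reported unclipped in the serialized model.

## PCA and load factors

PCA is fitted on the concatenation of both samples' frequency matrices
(a single shared space), columns mean-centred but *not* variance-scaled:
all features share the frequency scale and unit-variance scaling would
inflate rare-word noise. Each loading column is sign-flipped so its
largest-magnitude entry is positive, making results deterministic. The
load-factor report lists the top m (default 20) positive and bottom m
negative PC coefficients, each annotated with its word's GC class
(all-GC / mixed / no-GC) for the red/green/blue histogram colouring.

## Synthetic data generator

The generator emulates a two-sample amplicon comparison at desk scale.

**Templates.** Group 0's template is drawn with an exact GC count at
its target; each further group differs from it at exactly
round(divergence x L) positions, with replacement base classes chosen
so the group's own GC target is hit exactly. A GC target further from
the ancestor's than the divergence budget is an error (the GC change is
carried entirely by divergent positions).

**Reads.** Each read is its group's template with i.i.d. substitutions
at `mutation_rate` (uniform over the three alternative bases), optional
±1 length errors at homopolymer runs ≥ 3, and optional logistic GC
dropout applied by rejection sampling until the exact requested group
size is met — exact sizes keep pair counts stable across scenarios.
Qualities are constant Phred 38 so the quality filter is a pass-through
unless a test injects low-quality bases.

**Platform bias (`gc_shift`).** Real platform bias is reproducible:
specific local sequence contexts (homopolymer runs on 454, motif-driven
errors elsewhere) are miscalled the same way in every read. The shift
is therefore a *per-sample rule*, not per-read noise: every A/T-centred
5-mer context (G/C-centred for negative shift) is assigned a fixed
replacement base, contexts are shuffled once per sample, and vulnerable
contexts are accumulated under an occurrence-weighted quota until the
realized flipped fraction of eligible bases matches |gc_shift|. Because
the shuffle is independent of the magnitude, rules for increasing shift
under one seed are nested, which makes the dose-response monotone by
construction. An i.i.d. per-read flip model was evaluated and rejected
during design: independent flip positions degrade within-sample pair
correlations exactly as fast as cross-sample ones, so no bias strength
can ever produce sample clustering — contrary to how platform bias
behaves on real data, where the shared systematic displacement is the
point.

**Default study conditions.** 4 groups, 250 nt templates, 2%
inter-group divergence, GC targets (55.5, 55.0, 54.5, 54.0)%, 200 reads
per group, 1% per-base read noise. These emulate *species-level* groups
within one hypervariable region: 16S regions of congeneric species are
typically 95–99% identical with GC differences of a few percent, and it
is exactly this regime where platform bias can overwhelm phylogenetic
signal (a mock community pooling two congeneric strains shows
within-group correlations as low as ~0.7). The defaults were chosen
from a regime exploration before the test suite was written and are
stable across generator seeds. With 30% divergence and 9% GC spread
(genus/phylum-scale contrasts, also expressible through the config) the
phylogenetic signal dominates any realistic per-base bias — a real
property of the statistic, not a shortcoming of the generator.

**Scenarios.** `positive_control`: two unbiased runs over identical
templates → expected phylogenetic clustering. `negative_control`: the
samples read disjoint halves of double-length parents (same groups,
different amplified regions) → expected sample clustering.
`platform_bias`: identical templates, GC shift (default 0.08) on sample
B only → expected sample clustering, degenerating to the positive
control at zero shift.

**What the generator does not model.** Realistic 16S evolutionary
processes (it uses uniform substitutions from a single ancestor),
chimeras, indel-rich error profiles, within-group diversity beyond
i.i.d. read noise, paired ends, and abundance skew (group sizes are
exact). Passing tests therefore demonstrate that the statistics recover
planted composition structure under controlled conditions, not that any
particular real dataset is biased.

## Problem sizes and numerics

Synthetic validations run at 4 groups x 200 reads per sample (1 600
reads, 40 000 pairs per wedge), which gives wedge means precise to
~1e-3 while keeping a full scenario run under a second; desk-scale unit
tests use 25–60 reads per group. Correlations are computed by row
standardisation and matrix products; the Fisher-mean identity
R = tanh(mean(artanh r)) holds to 1e-12 against a brute-force pair loop,
and PCA component variances match a dense covariance eigendecomposition
to 1e-8. SVG output is built with fixed float formatting (three
decimals) and no timestamps, so identical inputs render byte-identically.

## Sequence intake

FASTQ is assumed Sanger/Phred+33 with no auto-detection. The quality
filter's threshold is strict (mean or per-base Phred must *exceed*
`min_phred`, default 20) and N-containing reads are always removed;
reads without qualities (FASTA) are N-screened only, or rejected when
`allow_missing_qualities=False`. Primer/barcode removal searches an
IUPAC-aware best placement of the forward primer within the first 30 nt
and of the reverse-complemented reverse primer within the last 30 nt
(constructs rarely exceed this, and the window bounds the mismatch
search); identical-insert deduplication is available but off by
default. Exact primer sets are dataset-specific and are always explicit
configuration, never inferred. All coordinates are 0-based, half-open.
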