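# Methods

This note documents the models, conventions and numerical choices
behind `uvclap`, and what the synthetic-data tests do and do not show
about real data.

## The measurement model

A multiplexed CLIP pool contains several libraries — protein pulldowns
(signal) and mock pulldowns (control) — that are barcoded and combined
*before* PCR amplification and sequencing. Each captured RNA molecule
becomes a cDNA whose 5′ end sits one nucleotide downstream of the
protein–RNA crosslink (reverse transcription stops at the crosslinked
base). PCR produces a variable number of copies per molecule;
sequencing samples the pool. The analysis must (i) return each read to
its source library despite barcode sequencing errors, (ii) collapse
PCR copies back to molecules, and (iii) compare libraries on the
common molecular scale that joint amplification preserves.

## Tri-barcode design

* **Condition tags**: 5-nt words over ACGT with minimum pairwise
  Levenshtein distance 3. By the standard sphere-packing argument a
  code of distance *d* corrects ⌊(d−1)/2⌋ = 1 edit; the package
  *verifies* rather than assumes this, by corrupting every tag with
  every possible single substitution and indel and checking unique
  nearest-neighbour decoding, then exhibiting a failing two-edit
  corruption. Construction is greedy over a seeded shuffle of all 4⁵
  candidates; greedy codebooks are deterministic per seed but
  seed-dependent in content (typically 12–18 tags survive the artifact
  filters). Candidates with homopolymer runs ≥ 3 ("polybases") are
  excluded up front; "self-complement" exclusion is interpreted as
  rejecting a candidate whose reverse complement is already accepted
  (preventing tag/revcomp collisions during ligation) and is off by
  default. Post-filters remove tags whose two terminal bases repeat at
  either end and tags whose reverse complement appears in the adapter.
* **Replicate tags**: semi-random 5-mers constrained to `DRYYR` or
  `DYRRY` (D = not C, R = purine, Y = pyrimidine). Each pattern has
  3·2·2·2·2 = 48 realizations; positions 2–5 lie in disjoint
  purine/pyrimidine classes, so the patterns are ≥ 4 substitutions
  apart and one class violation still assigns uniquely. The realized
  5-mer is not error-correcting but contributes UMI capacity.
* **Layout**: mate 1 starts `NNN T₁T₂T₃T₄T₅ NN`; mate 2 starts with
  the 3′ semi-random tag. The five random 5′ bases give 1024
  combinations, times 48 for the 3′ tag: 49 152 distinguishable events
  per position, before the extra resolution from differing insert
  lengths.
* **Color balance**: a tag pool is "balanced" when every cycle shows
  at least one base from each detection channel of a two-channel
  sequencer. The base-to-channel assignment is instrument-specific;
  the default convention here is red = {A, C}, green = {G, T},
  configurable.

## Demultiplexing

The condition tag is decoded by nearest neighbour within one edit. An
indel inside the tag shifts everything downstream, so decoding also
tries tag windows one base shorter and longer; the chosen window moves
the UMI/insert boundary with it. Ties prefer the nominal window
(substitutions dominate on Illumina-type instruments). A caveat
documented deliberately: when the flanking bases are random, a 1-indel
explanation pointing to one tag and a 1-substitution explanation
pointing to another can both be consistent with the observed read even
at code distance 3, so *embedded* indel decoding is best-effort; the
zero-error exhaustive guarantee holds at the isolated tag-word level
and, at read level, for all substitutions.

The dedup UMI is the concatenation of the five 5′ random bases and the
realized 3′ 5-mer (both count toward capacity); a 5′-only mode exists
for protocols that treat the 3′ tag purely as a replicate label.
Unconditional 3′-end clipping (5 nt from mate 1, 10 nt from mate 2)
removes read-through into the opposite barcode; any clipped genomic
sequence remains covered by the other mate. Unassigned reads are
written to a separate FASTQ pair for audit, and all statistics are
conservation-checked against the input count.

## Event calling

Events are defined on (chromosome, strand, mate-1 start, mate-2 start,
UMI); group size becomes `read_count`. The spurious filter removes,
within each identical-coordinate group, events with strictly fewer
than 10 % of the reads of the group maximum — UMI errors during
amplification/sequencing create exactly such low-count siblings at
identical mapping coordinates. The boundary is strict (<), so counts
{100, 10} both survive while {100, 9} loses the 9. The filter never
removes a group maximum and is the identity at threshold 0.

Crosslink coordinates default to the *truncation convention*: the
nucleotide immediately 5′ of the cDNA start in transcript orientation
(plus strand: mate-1 start − 1; minus strand: the half-open fragment
end). A `start` convention (the cDNA 5′ base itself) is available
because protocols differ; positions that would fall below 0 are
clamped and flagged. Coordinates are 0-based half-open throughout;
BED is native, GTF converted at the boundary. Multi-mapping status is
a boolean input column; the SAM reader translates the aligner-specific
`XS:i` auxiliary-tag convention.

## Quantification

* **Binning**: fixed-width bins (default 100 nt) anchored at 0,
  strand-collapsed by default (stranded mode available); each event
  falls in exactly one bin, so totals are conserved.
* **Enrichment**: ratio of summed event totals, signal replicates
  combined over control replicates combined. A zero control total is
  reported as infinite with a flag — pseudocounts would silently change
  the statistic.
* **MA tables**: raw counts (jointly amplified replicates need no
  prior scaling), restricted to bins with ≥ 2 events in both
  libraries; the median log2 fold change is the summary and is exactly
  antisymmetric under swapping the libraries.
* **Size factors**: the median-of-ratios estimator — per-bin geometric
  mean across libraries as pseudo-reference, per-library factor =
  median of count/reference over bins with all-nonzero counts. The
  factor *multiplies the reference to give the library* (a c-fold
  deeper library gets factor c); the estimator is exactly
  scale-equivariant on noiseless data. Cross-checked in the test suite
  against an independent DESeq-style implementation.
* **Enriched-bin caller** (plumbing, not a production peak caller): a
  bin qualifies on fold change of normalized counts, a minimum signal
  count, and a one-sided binomial test of the signal share against the
  library-size expectation, Benjamini–Hochberg corrected; adjacent
  qualifying bins merge.

## Annotation

Priority classification gives each peak exactly one label in the fixed
order rRNA, ncRNA, pseudogene, 3′UTR, 5′UTR, exon, intron, antisense,
intergenic. Overlap of ≥ 1 nt with a same-strand feature suffices (no
fractional threshold); a peak overlapping genes only on the opposite
strand is antisense; pure priority applies even across genes (a 3′UTR
of one gene outranks an exon of another). Gene-level classes come from
GTF biotypes (anything non-coding that is not rRNA or a pseudogene
counts as ncRNA; the mapping table is editable); introns are derived
as gene body minus exon union.

Standardization extends peaks below 41 nt symmetrically about their
midpoint — an odd deficit puts the extra base 3′ (right for plus or
unstranded peaks) — then merges overlapping or abutting (gap 0,
configurable) intervals. The operation is idempotent and its output
intervals are pairwise disjoint and non-adjacent. Overlap reports
attribute each merged-universe region to every input set with ≥ 1 nt
of overlap; counts partition the universe. Peak–control proximity uses
the edge-to-edge gap between half-open intervals with a strict > 50 nt
rule (gap 51 is "far", gap 50 is "near"). Motif scanning expands an
IUPAC motif (U ≡ T) into per-position base classes and scans the
strand-oriented peak sequence.

## Junction metaprofiles

Junctions are unique (chromosome, strand, donor-exon end,
acceptor-exon start) tuples from multi-exon transcripts. Distance −1
is the last exonic nucleotide 5′ of the junction in transcript
direction, +1 the first base of the downstream exon; there is no 0.
Crosslinks are counted in genomic coordinates against the genomic
flanks, intronic positions are excluded, and a crosslink near several
junctions counts once per junction within the window (a
nearest-junction mode is available). The uniformity statistic is a
chi-square goodness-of-fit against a flat profile; the `rebin`
parameter pools unit distances (tests use 20-nt bins) to keep expected
counts well above the chi-square approximation's comfort zone.

## Synthetic data

The generator emulates the structure of a multiplexed study: a random
genome (default two 60-kb chromosomes, GC 0.5), non-overlapping genes
of four classes (16 protein-coding three-exon genes with 100/150-nt
UTRs, plus rRNA, ncRNA and pseudogene singletons) so the full priority
ladder is exercised, planted binding sites in three regimes
(IUPAC-motif instances written into exonic sequence;
junction-upstream sites uniform at 20–30 nt upstream of junctions;
5′UTR sites), and per-library reads. Default libraries are two signal
replicates sharing a condition tag but differing in replicate pattern,
plus two matched controls; each library draws 3000 molecules, signal
libraries with 10 % background. Background is uniform over transcribed
regions with 20 % of its mass on rRNA (nonspecific pulldown material
is dominated by abundant RNA). cDNA lengths are uniform on 30–80 nt;
PCR copies are geometric with mean 1.5, multiplied by 3 for lengths in
40–60 nt — the simplest mechanism that reproduces the
duplicate-excess-at-mid-lengths shape. Sequencing errors are uniform
substitutions (default 0); qualities are constant. All draws flow
through one seeded generator in fixed order, so outputs are fully
reproducible per seed.

What the synthetic tests show: exact algebraic behavior (collapse,
filters, factors, overlaps) against brute-force oracles; exact
end-to-end truth recovery when error and duplication are off; and
correct statistical behavior of the profile tests (the uniform mode
rejects at its nominal rate over 200 seeds). What they do not show:
robustness to alignment artifacts, splice-junction-spanning reads,
realistic error/quality profiles, or genome-scale multiple-testing
behavior — real libraries need a real aligner and a production peak
caller in front of / behind this package.

## Problem sizes

Test and example runs are sized for a laptop: genomes ≤ 160 kb,
libraries of 10²–10⁴ molecules, oracle-equivalence checks at 10⁵
random alignment records, overlap oracles on 10⁵-nt genomes, and
200-seed calibration loops. These sizes were chosen so every check
runs in seconds while the statistical assertions retain power.

## Known limitations

* Embedded single-indel barcode decoding is best-effort (see above).
* The enriched-bin caller is deliberately simple plumbing; it ignores
  overdispersion and spatial correlation.
* Junction flanks are genomic and not clipped to short exons, so for
  exons shorter than the window a position can be exonic for one
  junction and beyond the neighbouring exon for another.
* The simulator does not model spliced reads; junction-mode truth uses
  contiguous genomic fragments near junction flanks.
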