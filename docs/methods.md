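# Methods

## Problem and scope

`indelkit` characterises short insertion/deletion variants (≤15 bp) called
across an exome cohort: are they already described in variant databases, what
do they do to transcripts, how are they distributed across the cohort
frequency spectrum, and how well do orthogonally validated calls concord
with those classes. The package deliberately starts *after* alignment and
calling: BAM handling, realignment-based calling and coverage computation
are out of scope, as are live annotation-service queries — gene models and
databases are consumed as local GFF3/VCF files.

## Coordinate model

Internally every indel is anchor-free and 1-based: `ref_seq` holds only the
deleted bases (empty for pure insertions), `alt_seq` only the inserted ones,
and `pos` is the first deleted base, or for insertions the base immediately
5′ of the insertion point. The VCF padding base and BED's 0-based half-open
intervals are converted exactly once, at the I/O boundary. This makes the
"difference between start positions" used by the matcher a well-defined
integer, independent of representation quirks.

Signed length is `len(alt) − len(ref)`: insertions positive, deletions
negative. "Same length" always means same *signed* length — an insertion
never matches a deletion of equal magnitude.

## Normalization

Left-alignment uses the standard rotation: while the allele's last base
equals the reference base immediately 5′ of the current position, prepend
that base to the allele, drop the allele's last base, and step the position
down; stop at the contig start. The result is the unique lowest-coordinate
representation of the alternative haplotype, at O(shift) cost. Complex
alleles (both sides non-empty) are not repositioned; calls from
realignment-based callers are pure insertions or deletions at this stage.
Tests verify idempotence, haplotype preservation and 5′-minimality against
a brute-force enumeration oracle that regenerates every equivalent
representation in a 50 bp window.

## Database matching

A call is compared with database entries within ±`match_window_bp`
(default 10) of its left-aligned start position. Rules, first hit wins:

1. exact allele (same position, same sequences);
2. same signed length and same allele sequence, minimal |distance|;
3. same signed length, minimal |distance|;
4. nearest entry of any length.

Ties on |distance| resolve toward the 5′ candidate (database entries of the
pre-left-alignment era sit downstream of the canonical position, so the 5′
candidate is the conservative choice), then lexicographically by allele
sequence so results are deterministic. Provenance classification
(known / newly-released-only / novel) accepts only tiers 1–3: a nearby indel
of a *different* length marks a described region, not a described variant,
and counting it would inflate the known fraction. The primary database takes
priority over the newly released one, so the classes partition the calls.

Distance profiling uses a wider ±100 bp window and, per query, the closest
entry of *identical* length when one exists, else the closest of any length.
"Similar length" is not quantified anywhere authoritative; identical-with-
fallback is the strictest reading and is recorded per profile row. Size
concordance between called and matched database lengths is reported as
squared Pearson correlation per insertion/deletion stratum (scipy's test
p-value); a stratum with under 3 pairs or zero variance is omitted.

## Consequence annotation

Ten categories with legacy semantics, assigned per variant × transcript in
this order: essential splice site (footprint touches the first/last
`essential_splice_intron_bp` = 2 intronic bases of an intron); complex indel
(footprint spans an exon–intron boundary not already caught — with the
default 2 bp essential window a boundary-spanning footprint always touches
an edge base first, so this class is empty unless the window is narrowed;
it is kept because the category exists in the reporting vocabulary);
coding (frameshift iff |length| mod 3 ≠ 0; STOP when an in-frame,
fully-CDS-contained edit gains a premature stop codon or loses the terminal
one, evaluated on the spliced CDS in transcript orientation;
NON_SYNONYMOUS_CODING otherwise — the historical term for in-frame coding
indels); splice region (3–8 bp into the intron, first/last 3 exonic bases
at a junction); 5′/3′ UTR (strand-aware); intronic; OTHER (within
`upstream_downstream_bp` = 5000 of the transcript, or overlapping a
non-coding transcript). Variants touching nothing produce no call.

Insertions have an empty reference footprint and are attributed to their
two flanking bases; exactly at an exon/intron junction only the intron-side
base counts, preserving the annotated junction sequence on the exon side.
Per-variant summaries take the most severe category across transcripts
under the fixed order STOP > FRAMESHIFT_CODING > ESSENTIAL_SPLICE_SITE >
COMPLEX_INDEL > NON_SYNONYMOUS_CODING > SPLICE_SITE > 5′UTR > 3′UTR >
INTRONIC > OTHER. Loss of function = {STOP, FRAMESHIFT_CODING,
ESSENTIAL_SPLICE_SITE}. All extents are configurable and echoed into
reports.

The annotation oracle in the test suite is a base-to-category map painted
by interval arithmetic in increasing precedence order — an independent
construction from the annotator's per-variant rule evaluation — swept with
1 bp deletions on both strands.

## Cohort statistics

Non-reference allele frequency is AC/(2N) over all N cohort samples;
non-carriers and missing genotypes count as homozygous reference (missing
calls are tallied and reported, but no missingness model is applied; no
per-genotype quality filter is applied either, as none is defined for this
pipeline). Classification precedence: PRIVATE (exactly one carrier sample),
then COMMON (frequency ≥ 0.05, threshold inclusive), then RARE. Summary
tables additionally use a "rare" stratum meaning frequency < threshold,
which is the MAF-based rarity used in per-consequence summaries and covers
RARE plus (in any realistically sized cohort) PRIVATE variants.

Variant identity across samples is the exact normalized tuple
(chrom, pos, ref, alt): all calls come from one caller convention, so fuzzy
merging is reserved for database matching only.

Group comparisons convert per-sample consequence counts to percentages (so
samples with different call totals are comparable) and apply a two-sided
Wilcoxon rank-sum test per category: exact null for small samples without
ties, tie-corrected normal approximation otherwise (scipy's `auto` policy,
matching the classical R behaviour), with Benjamini–Hochberg adjustment
across categories by default (the adjustment method is recorded in output).
Validation concordance uses Pearson's chi-squared; Yates continuity
correction is applied to 2×2 tables by default — the convention of R's
`chisq.test` and the form under which the published 66/16 vs 75/3 comparison
reproduces as χ² = 7.9378, p = 0.004841 (uncorrected it would be ≈9.38) —
and never to wider tables. Validation rates are rendered at two decimals
with half-up rounding (141/160 → 88.13, where banker's rounding would give
88.12).

## Synthetic data

The generator emulates the statistical structure of a patient-exome indel
call set, with ground truth recorded per variant:

- **Reference**: a random contig sized to the gene layout, with homopolymer
  and dinucleotide tracts at `repeat_density` (default 0.001 tract starts
  per bp, lengths 6–12 bp) to create left-alignment ambiguity.
- **Gene models**: 2–4 exon genes on both strands, CDS exon pieces
  90–180 bp, introns 80–400 bp, UTRs 40–120 bp, separated by 12 kb of
  intergenic sequence. Each CDS is stamped into the contig as
  ATG + non-stop codons + stop, with GT/AG dinucleotides at intron edges, so
  stop gain/loss logic operates on well-formed ORFs.
- **Indel lengths**: geometric(p = 0.45) truncated to 1..15 — about 95% of
  draws below 6 bp and nothing above 15, matching the short-skewed spectra
  such cohorts show.
- **Placement**: each variant targets a consequence category drawn from
  configured weights (defaults proportioned like a real exome cohort:
  intronic ≈ 63%, splice region 10%, frameshift 9%, in-frame coding 7%,
  UTRs 7.5%, essential splice 1%, STOP 0.5%) and is placed inside a
  category-safe window derived from the painted feature map; coding
  placements are codon-aligned so STOP / in-frame truth holds by
  construction. Placements that left-alignment would move, or that come
  within 40 bp of another variant, are redrawn — so recorded truth is exact
  without ever running the annotator, and variants cannot interfere with
  each other's 10 bp match windows. COMPLEX_INDEL carries weight 0 because
  the class is empty under the default splice windows (see above).
- **Provenance and databases**: defaults 60% known / 10% newly released /
  30% novel. Described variants get a database copy whose start position is
  right-shifted by a uniform 0–10 bp (`db_jitter_min/max`) with allele
  sequences kept — un-normalized representations, shifted only downstream as
  historical databases are relative to left-aligned calls.
- **Frequencies**: drawn per provenance class. Described variants
  concentrate at higher frequencies (known: 90% common), novel ones at low
  frequencies (50% private, 23% rare, 27% common — i.e. 73% below the
  common threshold). Genotypes are per-sample binomial(2, f) draws,
  resampled until the realised class matches the target; private variants
  get exactly one heterozygous carrier. The recorded class is the realised
  one. With 20 diploid samples the RARE class is arithmetically empty (two
  carriers already reach 2/40 = 0.05), so configurations requesting rare
  variants at such sizes raise an explicit unsatisfiable-target error;
  the default configuration keeps a 173-sample cohort (33 familial) where
  all three classes are attainable.
- **Validation panel**: 82 common and 78 private variants by default, one
  carrier and one homozygous-reference sample each; carrier confirmations
  are Bernoulli at per-class rates 66/82 and 75/78, and reference samples
  always confirm negative (the emulated design observed no false
  negatives).

What the generator does *not* emulate: read-level errors, caller biases,
genotype uncertainty, linkage between variants, population structure or any
demographic model (frequencies are a class mixture, not a site-frequency
spectrum). Passing the closure tests therefore demonstrates that the
pipeline's classification logic is exact on its own conventions — not that
it is robust to caller artefacts or representation disagreements beyond the
jitter model.

## Problem sizes and numerical choices

The end-to-end check runs 20 samples × 2,000 variants (250 genes × 8), a
scaled-down analogue of a 173-exome cohort chosen so the whole loop —
generation, per-sample VCF round-trip, normalization, matching, annotation,
summaries — completes in seconds while still exercising every category and
both jitter regimes. Randomised property tests use 1,000 instances each.
All simulation randomness flows from a single integer seed through
per-stage generators, and reports contain no timestamps, so identical
inputs give byte-identical outputs. Fixed tie-breaks (5′-first, then allele
sequence) remove the only nondeterminism in matching; float rendering in
reports is at a precision recorded in each file's header.

## Known limitations

- The matcher compares start positions, not footprint overlap; a database
  entry whose representation differs by more than the window is invisible
  (this is by design, and quantified by the jitter-beyond-window check).
- STOP detection requires the edit to be fully contained in the CDS of a
  single exon; in-frame edits straddling a CDS boundary fall back to
  NON_SYNONYMOUS_CODING.
- Non-coding transcripts fold into OTHER on any overlap; regulatory
  sub-categories are not distinguished.
- Cohort-specific published quantities that depend on unavailable patient
  data (per-sample averages, the insertion/deletion size correlations, the
  three-group validation chi-squared whose inputs were only plotted) are
  not reproduced; the property-based and scaled-down checks above stand in
  for them.
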