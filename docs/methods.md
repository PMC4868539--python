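# Methods

## Measurement model

The pipeline estimates the frequency of single-base mismatches that
survive a fixed cascade of technical-error filters, as a proxy whose
*relative* changes between samples track RNA polymerase fidelity. The
absolute value is an upper bound: residual sequencing error, rare
unfiltered DNA variation and RNA editing all contribute, so only
samples counted under an identical filter configuration are comparable.
The filter configuration is therefore a first-class object
(`RunConfig`), logged verbatim into every output directory.

Counting proceeds read → pileup → position filter:

- Read gates: primary alignments only; mapq ≥ `min_mapq` (default 30,
  the only multi-mapping signal available in standard alignments);
  CIGAR exactly one match op of the expected read length (default 76);
  at most `max_mm` = 2 substitutions. Duplicate removal is off by
  default: for single-ended or high-coverage libraries, reads sharing
  coordinates are usually distinct molecules, and removing them is not
  possible without molecular identifiers.
- Masks: first/last `trim_n` = 10 bases to `N`/quality 0; optionally,
  sequencing cycles flagged by the cycle QC (below). Masks are
  idempotent and commute with the gates.
- Pileup: a base is counted iff its quality ≥ `min_baseq` (default 39),
  and neither it nor the reference base is `N`. Insertions/deletions
  are tallied separately per (position, length).
- Recurrent-identical-mismatch filter: a position is dropped when any
  single alternative base is observed more than `max_obs` = 1 times.
  Identity means the pair (position, alternative base): two different
  alternative bases at one position are independent candidate errors.
  When a position is dropped its entire coverage leaves the
  denominator, keeping the numerator and denominator filters
  symmetric; the opposite convention is available via
  `overall_error_rate(include_dropped=True)`.

The per-sample output is `ErrorRateEstimate(total_mismatches,
total_bases, rate)`; binomial standard deviations on `rate` are
appropriate because, with one read per molecule, counted bases at a
position come from distinct molecules with independent error draws.

### Cycle-level QC

"Abnormally high" per-cycle error rates are undefined in general; the
rule used is fold-over-median: a cycle is flagged when its rate exceeds
`fold` (default 3) times the median rate over defined cycles; when the
median is zero any positive rate is flagged. Cycle indices refer to the
original machine cycle (reverse-strand alignments are un-reversed)
because cycle artifacts are instrument-side. Flagged cycles are masked
like read ends.

### Null mismatch-count distribution

To choose or justify `max_obs`, the expected fraction of positions
carrying k mismatches under a uniform error process is computed either
analytically (the mixture of Binomial(coverage, rate) pmfs over the
observed coverage vector) or by Monte-Carlo with a fixed seed; the two
agree to sampling accuracy. An excess of k ≥ 2 positions over this null
is the signature of subclonal DNA variants.

## Splice-junction analyses

Windows of `flank` (default 10, 20 supported) exonic plus intronic
offsets are built around the donor and acceptor of each canonical
GT..AG intron. Offsets are strand-oriented and 1-based away from the
boundary: +1 is the donor G (for the acceptor, the G of AG), −1 the
last exonic base; there is no offset 0. Profiles pool totals: the rate
at an offset is Σ errors / Σ coverage across junctions, never a mean of
per-junction rates, because junction coverage is wildly unbalanced.

Junction profiles are computed **without** the recurrent-mismatch
filter: an error-prone splice motif legitimately recurs across
molecules at the same genomic position, which is exactly the pattern
that filter removes. Genome-wide rate estimation and junction profiling
therefore use different position filters by design.

Intron retention is estimated from junction-spanning reads
(≥ `min_overhang` = 6 aligned bases each side; shorter overhangs are
alignment artifacts). Spliced support of an intron is the count of
reads whose gap matches it exactly; retained support is the **average**
of the donor- and acceptor-boundary contiguous-spanning counts, because
a retained transcript exposes two spanning boundaries where a spliced
transcript exposes one junction — counting reads at either boundary
without averaging inflates a true retention of 0.20 to ~0.31.
retention = retained / (retained + spliced), per intron and pooled.

Mono-, di- and trinucleotide background rates are pooled per context
and within-context position and normalized to the base-weighted grand
mean, whose weighted average is exactly 1 by construction. An optional
position mask restricts the tally (e.g. to exonic positions matching
splice motifs).

## Substitution spectrum and comparisons

The 12 directed changes ref→alt are counted with per-source-base
denominators (rates per total counted base are also emitted, since both
normalizations are in use in the field). With transcript annotation the
spectrum is projected onto the transcribed strand (positions under
minus-strand transcripts have ref and alt complemented; unannotated
positions are excluded), so C→U is distinct from G→A; a genomic-strand
mode exists for unannotated genomes.

The Ts/Tv summary divides pooled transition and transversion error
counts by the same total-base denominator, so the ratio is the
transition:transversion error ratio; equal rates in all 12 classes give
0.5 (4 vs 8 classes).

Between-sample comparisons are the classical paired t-test (n−1 df,
two-sided; zero-variance differences are flagged rather than tested)
and Welch's unequal-variance t-test for independent groups, both via
scipy.

## Stop-codon proximity

`near_stop_codons()` enumerates the sense codons with at least one
single-substitution neighbor among TAA/TAG/TGA; there are 18. "One
polymerase error" means one substitution — indels are excluded, since
substitutions are the error classes the pipeline measures. Frame-f
scanning reads codons from offset f; the terminal stop is excluded in
frame 0; out-of-frame windows overlapping it are kept. The positional
distribution normalizes codon index to [0,1) and pools near-stop
density over `n_bins` = 5 equal-width bins (binning is a free choice;
per-gene tables are also emitted). A spectrum-weighted variant scores
each codon→stop channel by measured (ref, alt) rates.

## The simulator

The generator emulates the data regime the method targets, with full
ground truth:

- **Genome**: `n_genes` protein-coding genes (valid ORFs: ATG start,
  single terminal stop, no internal in-frame stop) split by 1–3
  canonical GT..AG introns, on both strands, separated by random
  intergenic sequence. Defaults: exons 150–300 bp (≥ read length so
  exon-interior reads pass the full-length gate), introns 60–120 bp.
- **Molecules**: each transcript molecule independently accrues
  substitutions at `polymerase_error_rate` per pre-mRNA base (default
  10⁻⁵, the plausible 10⁻⁶–10⁻⁵ regime). An error on an intron's first
  two or last two bases triggers retention of that intron with
  probability `retention_on_splice_error` (default 1). Polymerase
  errors are **per molecule** — inherited by every read of the
  molecule — which is the biological premise of both the method and its
  duplicate-read caveat. Subclonal DNA variants are carried by each
  molecule with their allele fraction.
- **Reads**: sampled uniformly per molecule (`reads_per_molecule`,
  default 1; read length 76). Sequencing errors are per read base with
  a two-level quality model: Q40 at `sequencing_error_rate` (default
  10⁻⁴) and a `low_quality_fraction` (default 2%) of Q10 bases at
  10⁻², enough to exercise the Q39 threshold without modelling full
  quality profiles. `bad_cycles` multiply the error rate at given
  machine cycles. Optional single-base read insertions/deletions
  support the indel-rate analysis. Alignments are emitted from truth
  (no aligner in the loop): exon-interior and retained-intron reads get
  single match CIGARs, junction-spanning reads N-gapped CIGARs at the
  true intron; FASTQ is also written for users who want a real aligner.
- **Truth**: every planted event carries type (polymerase, subclonal,
  sequencing, insertion, deletion), genomic position, ref/alt, the
  molecule and (for read-level events) the read, and whether it is
  expressed in the mature molecule. `truth_summary` recomputes, from
  truth and read geometry alone, the mismatch rate the pipeline should
  measure under a filter configuration — including recurrent-filter
  drops — and matches the pipeline exactly on every configuration
  tested.

All randomness flows from a single seed through three spawned
generator streams (genome, molecules, reads); outputs are
byte-deterministic.

### What the simulator does not model

Uniform base composition; no PCR amplification bias beyond the fixed
reads-per-molecule count; no RNA degradation, editing, or paired-end
insert-size structure; quality values take two levels only; planted
indels are restricted to plus-strand, non-junction reads. Reads are
drawn per molecule rather than per base, so longer (retained) molecules
are slightly under-sampled relative to uniform coverage, leaving a
small known downward bias (a few percent) in recovered retention. Passing tests therefore demonstrate correctness of the counting
machinery and estimator logic under a clean generative model, not
robustness to alignment error, context-dependent sequencing chemistry
or library-preparation artifacts in real data.

## Problem sizes and numerical choices

Test and acceptance runs use simulated datasets of 10⁴–2×10⁵ reads
(up to ~10⁷ counted bases per condition), chosen to give 3-σ binomial
resolution on the planted effects they check: rate-difference recovery
at 4×10⁻⁵ uses ≥10⁷ counted bases for the headline pair and ~3×10⁶ per
replicate for direction checks; spectrum recovery uses ≥10⁴ planted
events at coverage ~14 (low coverage keeps recurrent-filter collisions,
which scale with coverage × rate, below 1% of events at a planted rate
of 10⁻³). Subclonal-rejection runs use counted coverage ~100, where a
10% allele-fraction variant is seen at least twice with probability
> 99.9%. Ties and degenerate inputs: positions with zero counted bases
are undefined (NaN) rather than zero; an all-masked read contributes
nothing; a zero total denominator raises rather than returning 0.
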