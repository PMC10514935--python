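# Methods

## Study design being modelled

Three near-isogenic tomato lines share a genetic background and differ
only in the wild-species (*S. pennellii*-like) segment they carry around
a resistance locus: a multi-Mbp **long** introgression, a ~150-kbp
**short** introgression nested inside the long one's footprint, and
**none**.  Each line's de novo contigs are aligned to two references —
the domesticated background genome and the wild donor genome — and the
introgression is delineated from the presence/absence pattern of
variants across the trio.  All coordinates are 0-based half-open
internally; VCF output is 1-based with the anchor-base convention.

## Synthetic trio generator

The generator is first-class, tested code: it defines the conditions
every acceptance property is scored under.

**Divergence model.**  The domesticated reference is uniform random
ACGT.  The wild reference is derived from it by planting substitutions
at `divergence_snp_rate` (default **0.03/bp**), small indels at
`divergence_indel_rate` (default **0.002/bp**, lengths 1–10), and
`sv_count` (default 25) insertions/deletions of 50–2000 bp.  The 3%
figure is a deliberately conservative stand-in for the deep
domesticated/wild divergence of real material; it is config-exposed
because the true rate for any given line pair is unknown.  Events are
placed uniformly with rejection of overlaps (1-bp padding); placement
failure after 200 attempts raises an error naming the crowded region.

**Reference N-gaps.**  Real wild-relative assemblies carry runs of
ambiguous bases where sequence could not be resolved.  These are
modelled as **inserted** N-runs in the wild reference (`gap_count`
= 40, lengths 50–3000): placeholders for sequence that exists in the
organism but not in the assembly's coordinate system.  Consequently (i)
the wild reference's non-N base count equals the domesticated length
plus the net planted indel length, and (ii) the NIL genomes — built from
the *underlying* haplotype — carry real bases where the reference shows
N, which is exactly the situation the gap-spanning analysis measures.
Contig-internal assembly gaps are a separate mechanism: same-length
N-masking of contig sequence at `contig_gap_rate` (default 5·10⁻⁷/bp),
so that contig concatenation still reconstructs the genome outside
masked runs.

**Trio construction.**  The none line equals the domesticated
reference.  The long and short lines substitute the wild segment (N-gap
insertions excised) over their introgression intervals.  Configured
intervals are given in wild coordinates; boundaries are snapped outward
to the nearest position not inside any planted-edit footprint in either
coordinate system, and the *realized* intervals (both coordinate
systems) are recorded in the truth set — tests and benchmarks use the
truth, never the raw config.  Line-unique SVs (default 12, 50–2000 bp)
are additionally planted inside the long line's introgression, spaced
≥ 500 bp apart, with breakpoints kept out of divergence-event footprints
so the long genome's composite edit set against either reference stays
well defined.

**Fragmentation.**  Contig lengths are drawn uniformly from
[0.75, 1.25] × `contig_n50_target` (default 1.2 Mbp at desk scale) until
the genome is covered; the draw is retried (≤ 20 times) until the
realized N50 is within 25% of target.  Desk-scale defaults — 5-Mbp
chromosome, 3.5-Mbp long and 150-kbp short introgression — mirror the
scale *ratios* of the real study at a size that runs in about a minute
per replicate on one CPU.

## Aligner

A whole-genome contig aligner in three stages:

1. **Minimizer anchoring.**  Canonical (k, w) = (15, 10) minimizers
   (splitmix64-hashed, hashes kept below 2⁵² so SciPy's running filters
   compare them exactly); k-mers containing N are skipped; minimizers
   occurring > 200 times on the reference are masked as repeats.
2. **Chaining.**  Anchors are first compressed into *fragments* —
   maximal runs of same-diagonal, overlapping/abutting anchors, which
   are provably exact match blocks and always co-chained — then chained
   by LIS-style DP (numba kernel; 64-fragment lookback) with score
   `weight − 0.5·|diagonal shift| − 0.01·gap`; a coordinate gap > 10 kbp
   on either sequence terminates a chain; chains with < 4 anchors are
   dropped.  Ties break toward the earlier reference, then contig,
   start, so output is deterministic.
3. **Refinement.**  Fragment interiors are exact; inter-fragment
   segments are aligned with unit costs: equal-length segments
   column-wise (with a DP arbitration fallback when the mismatch load
   suggests a compensating indel pair), unequal-length segments by
   common prefix/suffix trimming and then either a small exact DP
   (areas ≤ 4·10⁴) or a banded DP whose corridor always covers the
   length-difference envelope plus `band` (default 64) extra columns —
   a band smaller than the length difference is widened automatically
   and logged once.  Block ends are extended by greedy exact matching.
   N matches nothing, itself included.

Identity is **per-column**: matches / aligned columns, indel columns
included (the gap-compressed alternative would read higher; per-column
was chosen and is stated here because the original description leaves it
open).  Blocks round-trip through 12-column PAF with a `cg:Z` extended
cigar; imported PAF (e.g. minimap2 `--eqx`) can replace the internal
aligner at the pipeline seam, with edit lists reconstructed from the
cigar and sequences.

## Variant discovery and the presence matrix

Substitutions and indels < 50 bp become small variants; indels ≥ 50 bp
and inter-block events (reference span ≥ 50 bp missing from a contig, or
vice versa, between consecutive collinear blocks) become SVs.  Variants
with N in either allele are dropped.  Duplicate calls at one locus
within a line are collapsed only when they come from *different* blocks
(overlapping chains seeing one event twice), keeping the call with the
larger block; nearby distinct events from a single block are legitimate
split representations and are kept.

Cross-line matching: SNPs match on exact position and alternate allele;
deletions on reciprocal overlap ≥ 0.5; insertions on position within
50 bp and length ratio ≥ 0.5 (standard SV benchmarking conventions,
config-exposed).  Clustering is single-linkage.  Presence flags are
coverage-aware: 1 = matching call, 0 = locus covered by that line's
blocks but no call, undefined = uncovered — undefined loci are excluded
from differential classes, so assembly dropouts are never counted as
biological absence.

## Differential classes and boundary inference

The classification is a total truth table over the 8 presence triples ×
2 reference roles.  Fixed entries: (1,1,0) → `diagnostic_dom` under the
domesticated role; (0,1,1) → `diagnostic_wild` under the wild role and
`short_none_shared_vs_long` under the domesticated role; (1,0,0) →
`long_unique` under either role; (1,1,1) and (0,0,0) → `background`.
All remaining role/triple combinations — including (1,1,0) under the
wild role, where the pattern has no diagnostic meaning — map to
`other`.

Density profiles count classified small variants in 100-kbp half-open
windows.  The long introgression is traced by {`long_unique`,
`diagnostic_dom`} on the domesticated reference and {`diagnostic_wild`}
on the wild reference; the short introgression by {`diagnostic_dom`}
alone (the pattern only arises where *both* carriers hold wild
sequence).  Runs of windows with count ≥ τ, allowing ≤ 2 consecutive
below-threshold windows (so the short segment's signal dip inside the
long run does not split it), become calls refined to the [first,
last+1) supporting variant.  τ defaults to the adaptive
max(5, background mean + 3·SD), computed from windows outside candidate
runs; the windowing parameters have no counterpart in the original
description and are all config keys.  Boundaries are reported per
reference; no coordinate lift-over is attempted.

Line-unique SVs are the (1,0,0) SV rows inside an explicitly supplied
interval (the pipeline uses the long call on the wild reference), with
(0,1,1) rows reported as the complementary class.  A gap is *spanned*
when one block from a contig > `min_contig_length` (default 1 Mbp)
fully contains it on the reference and the contig subsequence aligned
across it — obtained by a cigar walk — contains no N; `--partial`
relaxes containment to any overlap for sensitivity analysis.

## Benchmarking against truth

Variant representation is not unique (a 10-bp insertion may be split, or
traded against substitutions, without being wrong), so recall/precision
are **haplotype-aware**: a truth event is recovered — and a call correct
— when applying the call set to the reference reproduces the same local
sequence as the truth set over a window around the event (radius 50 bp,
expanded so no edit is cut and no length-changing edit sits within 25 bp
of a boundary).  SV recovery additionally requires breakpoints within
50 bp and type agreement.  Uncovered truth loci leave the denominator.

## Determinism and numerical choices

All randomness flows from `SimConfig.seed` through seeded NumPy
generators (per-stage child seeds).  Chaining and DP tie-breaks are
fixed (diagonal > reference-consuming > contig-consuming).  Pipeline
reruns with identical config and inputs are byte-identical for BED, TSV,
VCF, and PAF outputs; VCF headers carry no timestamps.

## Scope of what passing tests show — and limitations

The generator emulates divergence, SVs, reference gaps, introgression
nesting, and contig fragmentation, but **not** sequencing error,
assembler misjoins or collapses, repeat families (the sequence is
uniform random, so repeat-induced ambiguity is rare: minimizer masking
is exercised only lightly), centromeric composition, inversions or
translocations, or heterozygosity.  Passing tests therefore demonstrate
the correctness of the comparative logic under clean assemblies, not
robustness to assembly artifacts.  Desk-scale problem sizes (5-Mbp
chromosome, 10 replicates for boundary recovery, 20 replicates for the
gap oracle at 100 kbp) were chosen so that the full property suite runs
in minutes; all scale linearly with chromosome length.  Inversions are
excluded from v1 (deletions/insertions suffice to exercise the ≥ 50 bp
logic); the shortest detectable introgression is bounded below by the
window size and the divergence rate (a segment must contain enough
diagnostic variants to clear τ in at least one window).
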