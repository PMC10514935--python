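"""Generate a small synthetic NIL trio and inspect the planted truth.

The generator builds a domesticated reference, a diverged wild reference
(SNPs, indels, SVs, inserted N-gaps), and three near-isogenic genomes
that differ only by the wild introgression they carry (long, short
nested inside it, or none), then fragments each genome into contigs.
"""

from introscope.simulate import SimConfig, simulate_all

cfg = SimConfig(
    seed=42, chrom_length=300_000, sv_count=5, gap_count=6,
    sv_length_range=(50, 500), gap_length_range=(50, 400),
    introgression_long=(50_000, 250_000),
    introgression_short=(180_000, 190_000),
    contig_n50_target=80_000, line_unique_sv_count=3,
    line_unique_sv_spacing=400,
)
dom, wild, genomes, contigs, truth = simulate_all(cfg)

print(f"domesticated reference: {len(dom.sequence):,} bp")
print(f"wild reference:         {len(wild.sequence):,} bp "
      f"({wild.sequence.count('N'):,} ambiguous)")
for line in ("long", "short", "none"):
    iv = truth.introgression_by_line[line]
    print(f"{line:>5} line: {len(genomes[line].sequence):,} bp, "
          f"{len(contigs[line])} contigs, introgression (wild coords): "
          f"{iv['wild']}")
print(f"planted: {len(truth.planted_variants):,} divergence variants, "
      f"{len(truth.planted_gaps)} reference gaps, "
      f"{len(truth.unique_svs)} long-line-unique SVs")
# The realized introgression intervals are the oracle every later stage
# is scored against.
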