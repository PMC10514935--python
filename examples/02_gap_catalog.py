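"""Catalog assembly N-gaps in a (wild) reference and summarise contigs.

Assembly gaps are maximal runs of ambiguous nucleotides (N) of at least
50 bp; their positions and length distribution feed the gap-spanning
analysis that shows which unresolved regions the new contigs close.
"""

from introscope.seqio import contig_n50, find_gaps
from introscope.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=42, chrom_length=300_000, gap_count=6,
                gap_length_range=(50, 400),
                introgression_long=(50_000, 250_000),
                introgression_short=(180_000, 190_000),
                contig_n50_target=80_000)
dom, wild, genomes, contigs, truth = simulate_all(cfg)

gaps = find_gaps(wild, min_length=50)
print(f"{len(gaps)} gaps >= 50 bp on {wild.name}:")
for g in gaps:
    print(f"  {g.chrom}:{g.start}-{g.end}  ({g.length} bp)")
# each line is one unresolved stretch of the wild assembly

lengths = [len(c.sequence) for c in contigs["long"]]
print(f"long-line assembly: {len(lengths)} contigs, "
      f"N50 = {contig_n50(lengths):,} bp")
# N50: half the assembled bases live in contigs at least this long
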