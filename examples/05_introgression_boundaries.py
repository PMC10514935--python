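"""Infer introgression boundaries from windowed differential-variant
density, on both references, and compare with the planted truth.

Windowed counts of the diagnostic classes rise sharply across the
introgression; maximal above-threshold runs of windows, refined to the
first/last supporting variant, give the boundary calls.
"""

from introscope.pipeline import PipelineParams, analyze_trio
from introscope.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=42, chrom_length=300_000,
                introgression_long=(50_000, 250_000),
                introgression_short=(180_000, 190_000),
                contig_n50_target=80_000, line_unique_sv_count=3,
                line_unique_sv_spacing=400)
dom, wild, genomes, contigs, truth = simulate_all(cfg)
res = analyze_trio(dom, wild, contigs,
                   PipelineParams(window_size=10_000, min_contig_length=50_000))

for key, label in (("dom_long", "long introgression, domesticated coords"),
                   ("wild_long", "long introgression, wild coords"),
                   ("dom_short", "short introgression, domesticated coords")):
    call = res.primary_call(key)
    scope = "long" if "long" in key else "short"
    ref = "dom" if key.startswith("dom") else "wild"
    t = truth.introgression_by_line[scope][ref]
    print(f"{label}:")
    print(f"  called  {call.start:>7,} - {call.end:>7,}  "
          f"({call.length/1e3:.1f} kbp, {call.n_variants} variants)")
    print(f"  planted {t[0]:>7,} - {t[1]:>7,}")
# boundary error is a few tens of bp: the first/last diagnostic variant
# sits within ~1/divergence of the true crossover point
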