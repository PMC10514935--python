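import numpy as np
import pytest

from introscope.seqio import contig_n50, find_gaps
from introscope.simulate import (SimConfig, apply_edits, fragment_into_contigs,
                                 simulate_all, simulate_references,
                                 simulate_trio)


def _mini_cfg(**kw):
    base = dict(seed=3, chrom_length=50_000, sv_count=2, gap_count=3,
                sv_length_range=(50, 200), gap_length_range=(50, 60),
                introgression_long=(10_000, 40_000),
                introgression_short=(25_000, 27_000),
                contig_n50_target=20_000, line_unique_sv_count=2,
                line_unique_sv_spacing=300)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_short_must_nest_in_long(self):
        with pytest.raises(ValueError, match="nest"):
            _mini_cfg(introgression_short=(5_000, 12_000))

    def test_rates_bounded(self):
        with pytest.raises(ValueError, match="outside"):
            _mini_cfg(divergence_snp_rate=1.5)

    def test_interval_within_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            _mini_cfg(introgression_long=(10_000, 60_000),
                      introgression_short=(25_000, 27_000))

    def test_yaml_round_trip(self, tmp_path):
        cfg = _mini_cfg()
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestReferences:
    def test_zero_divergence_identity(self):
        cfg = _mini_cfg(divergence_snp_rate=0.0, divergence_indel_rate=0.0,
                        sv_count=0, gap_count=0)
        dom, wild, truth = simulate_references(cfg)
        assert dom.sequence == wild.sequence
        assert truth.planted_variants == [] and truth.planted_gaps == []

    def test_gap_count_and_lengths_forced(self):
        cfg = _mini_cfg(gap_count=3, gap_length_range=(50, 60))
        _dom, wild, truth = simulate_references(cfg)
        gaps = find_gaps(wild, 1)
        assert len(gaps) == 3
        assert all(50 <= g.length <= 60 for g in gaps)
        assert [(g.start, g.end) for g in gaps] == truth.planted_gaps

    def test_seed_determinism(self):
        a = simulate_references(_mini_cfg())
        b = simulate_references(_mini_cfg())
        assert a[0].sequence == b[0].sequence
        assert a[1].sequence == b[1].sequence

    def test_edit_round_trip_rebuilds_wild(self):
        dom, wild, truth = simulate_references(_mini_cfg())
        rebuilt, _ = apply_edits(dom.sequence, truth.dom_to_wild_edits())
        assert rebuilt == wild.sequence

    def test_non_gap_base_conservation(self):
        dom, wild, truth = simulate_references(_mini_cfg())
        net = sum(len(v.alt_allele) - len(v.ref_allele)
                  for v in truth.planted_variants)
        non_gap = len(wild.sequence) - wild.sequence.count("N")
        assert non_gap == len(dom.sequence) + net


class TestTrio:
    def test_none_line_equals_dom(self, tiny_sim):
        dom, _wild, genomes, _contigs, truth = tiny_sim
        assert genomes["none"].sequence == dom.sequence

    def test_substitution_respects_boundaries(self, tiny_sim):
        dom, wild, genomes, _contigs, truth = tiny_sim
        for line in ("long", "short"):
            a_d, b_d = truth.introgression_by_line[line]["dom"]
            g = genomes[line].sequence
            if line == "none" or line == "short":
                assert g[:a_d] == dom.sequence[:a_d]
                assert g[-(len(dom.sequence) - b_d):] == dom.sequence[b_d:]
        # short line carries the wild allele inside its introgression and
        # dom outside; verified via its expected edit set
        for line in ("long", "short", "none"):
            edits = truth.line_edits_vs_dom(line, dom)
            rebuilt, _ = apply_edits(dom.sequence, edits)
            assert rebuilt == genomes[line].sequence

    def test_whole_chromosome_introgression_limiting_case(self):
        cfg = _mini_cfg(introgression_long=(0, 50_000),
                        introgression_short=(25_000, 27_000),
                        line_unique_sv_count=0)
        dom, wild, truth = simulate_references(cfg)
        genomes, truth = simulate_trio(dom, wild, cfg, truth)
        a, b = truth.introgression_by_line["long"]["wild"]
        a_d, b_d = truth.introgression_by_line["long"]["dom"]
        # expected middle: the wild segment with reference N-gap
        # insertions excised (the NIL carries real sequence there)
        mid = wild.sequence[a:b]
        for s, e in reversed([g for g in truth.planted_gaps if a <= g[0] and g[1] <= b]):
            mid = mid[: s - a] + mid[e - a:]
        g = genomes["long"].sequence
        assert g == dom.sequence[:a_d] + mid + dom.sequence[b_d:]
        # the configured interval covers the wild chromosome up to the net
        # inserted length (wild coordinates run past chrom_length) plus a
        # few snapped bases
        slack = len(wild.sequence) - cfg.chrom_length + 50
        assert a_d < 50 and len(dom.sequence) - b_d <= slack
        assert "N" not in g

    def test_presence_flags_match_interval_containment(self, tiny_sim):
        _dom, _wild, _genomes, _contigs, truth = tiny_sim
        for v in truth.planted_variants:
            contained = tuple(
                int(truth.line_contains(ln, v.wild_pos))
                for ln in ("long", "short", "none"))
            assert truth.flags_vs(v, "domesticated") == contained
            assert truth.flags_vs(v, "wild") == tuple(1 - c for c in contained)
            # nesting: present in short implies present in long
            if contained[1]:
                assert contained[0]
            assert contained[2] == 0

    def test_introgression_exceeding_chromosome_rejected(self):
        cfg = _mini_cfg(divergence_indel_rate=0.0, sv_count=0, gap_count=0)
        dom, wild, truth = simulate_references(cfg)
        cfg2 = _mini_cfg()
        cfg2.introgression_long = (10_000, 60_000)  # beyond the wild chromosome
        with pytest.raises(ValueError, match="exceeds|outside"):
            simulate_trio(dom, wild, cfg2, truth)


class TestFragmentation:
    def test_single_contig_when_target_is_genome_length(self):
        cfg = _mini_cfg(contig_gap_rate=0.0)
        dom, _w, truth = simulate_references(cfg)
        cfg.contig_n50_target = len(dom.sequence)
        contigs = fragment_into_contigs(dom, cfg, "x")
        assert len(contigs) == 1 and contigs[0].sequence == dom.sequence

    def test_target_larger_than_genome_rejected(self):
        cfg = _mini_cfg()
        dom, _w, _t = simulate_references(cfg)
        cfg.contig_n50_target = len(dom.sequence) + 1
        with pytest.raises(ValueError, match="exceeds"):
            fragment_into_contigs(dom, cfg, "x")

    def test_concatenation_reconstructs_genome(self, tiny_sim):
        _dom, _wild, genomes, contigs, truth = tiny_sim
        for line in ("long", "short", "none"):
            ordered = sorted(contigs[line],
                             key=lambda c: truth.contig_provenance[c.name][1])
            joined = "".join(c.sequence for c in ordered)
            genome = genomes[line].sequence
            assert len(joined) == len(genome)
            # equal except at N-masked assembly gaps
            diff = [i for i, (x, y) in enumerate(zip(joined, genome)) if x != y]
            assert all(joined[i] == "N" for i in diff)

    def test_realized_n50_within_25_percent(self, tiny_sim, tiny_cfg):
        _dom, _wild, _genomes, contigs, _truth = tiny_sim
        for line in ("long", "short", "none"):
            n50 = contig_n50([len(c.sequence) for c in contigs[line]])
            assert abs(n50 - tiny_cfg.contig_n50_target) <= 0.25 * tiny_cfg.contig_n50_target

    def test_fragmentation_deterministic(self):
        cfg = _mini_cfg()
        dom, _w, _t = simulate_references(cfg)
        a = fragment_into_contigs(dom, cfg, "x")
        b = fragment_into_contigs(dom, cfg, "x")
        assert [(c.name, c.sequence) for c in a] == [(c.name, c.sequence) for c in b]


def test_simulate_all_writes_artifacts(tmp_path):
    cfg = _mini_cfg()
    simulate_all(cfg, tmp_path)
    for name in ("reference_dom.fasta", "reference_wild.fasta",
                 "genome_long.fasta", "contigs_short.fasta",
                 "truth/truth_introgressions.bed", "truth/truth_variants.tsv",
                 "sim_config.yaml"):
        assert (tmp_path / name).exists(), name
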