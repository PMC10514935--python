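import numpy as np
import pytest

from introscope import align as al
from introscope.align import (Anchor, Chain, align_contigs, align_segment,
                              build_minimizer_index, chain_anchors,
                              collect_anchors, dotplot_data, export_paf,
                              import_paf, refine_blocks, revcomp)
from introscope.seqio import SeqRecord


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMinimizerIndex:
    def test_w1_indexes_every_kmer(self):
        rng = np.random.default_rng(0)
        s = _rand_seq(rng, 300)
        idx = build_minimizer_index(SeqRecord("r", s), k=11, w=1,
                                    max_occurrences=10**6)
        assert len(idx.positions) == len(s) - 11 + 1

    def test_homopolymer_single_key(self):
        idx = build_minimizer_index(SeqRecord("r", "A" * 100), k=7, w=5,
                                    max_occurrences=10**6)
        assert len(np.unique(idx.codes)) == 1

    def test_k_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            build_minimizer_index(SeqRecord("r", "ACGT"), k=15, w=5)

    def test_self_query_anchors_on_main_diagonal(self):
        rng = np.random.default_rng(1)
        s = _rand_seq(rng, 2000)
        ref = SeqRecord("r", s)
        idx = build_minimizer_index(ref, k=15, w=10)
        r, q = collect_anchors(idx, SeqRecord("q", s))["+"]
        assert len(r) > 50
        assert np.all(r == q)
        # anchors cover the full diagonal densely
        assert r.min() < 15 and r.max() > len(s) - 40


class TestChaining:
    def _collinear(self, n, r0=0, q0=0, step=100, strand="+"):
        return [Anchor(r0 + i * step, q0 + i * step, 15, strand)
                for i in range(n)]

    def test_collinear_anchors_form_one_chain(self):
        chains = chain_anchors(self._collinear(8), min_chain_anchors=2)
        assert len(chains) == 1
        assert chains[0].n_anchors == 8

    def test_large_reference_jump_splits_chains(self):
        # two collinear groups, 20-kbp reference jump, max_gap 10 kbp:
        # hand DP confirms no predecessor link crosses the jump
        anchors = self._collinear(5) + self._collinear(5, r0=20_500, q0=500)
        chains = chain_anchors(anchors, max_gap=10_000, min_chain_anchors=2)
        assert len(chains) == 2
        assert [c.n_anchors for c in chains] == [5, 5]
        # a modest deletion-like jump with well-anchored flanks is bridged:
        # the flank score outweighs the diagonal-shift penalty
        dense = (self._collinear(30, step=50)
                 + self._collinear(30, r0=30 * 50 + 500, q0=30 * 50, step=50))
        merged = chain_anchors(dense, max_gap=10_000, min_chain_anchors=2)
        assert len(merged) == 1 and merged[0].n_anchors == 60

    def test_non_collinear_anchors_dropped(self):
        anchors = [Anchor(1000, 5000, 15, "+"), Anchor(2000, 200, 15, "+"),
                   Anchor(500, 9000, 15, "+")]
        assert chain_anchors(anchors, min_chain_anchors=2) == []

    def test_empty_input(self):
        assert chain_anchors([]) == []


class TestRefinement:
    def _block_for(self, ref_seq, ctg_seq, **kw):
        ref = SeqRecord("ref", ref_seq)
        ctg = SeqRecord("ctg", ctg_seq)
        _chains, blocks = align_contigs(ref, [ctg], min_chain_anchors=2, **kw)
        assert blocks, "alignment produced no block"
        return max(blocks, key=lambda b: b.aligned_columns)

    def test_identical_segments_identity_one(self):
        rng = np.random.default_rng(2)
        s = _rand_seq(rng, 400)
        b = self._block_for(s, s)
        assert b.identity == 1.0
        assert (b.ref_start, b.ref_end) == (0, 400)

    def test_single_substitution_identity(self):
        rng = np.random.default_rng(3)
        s = _rand_seq(rng, 400)
        mutated = s[:200] + ("A" if s[200] != "A" else "C") + s[201:]
        b = self._block_for(s, mutated)
        assert b.aligned_columns == 400
        assert b.identity == pytest.approx(399 / 400)
        assert len(b.edits) == 1 and b.edits[0].ref_pos == 200

    def test_identity_equals_match_recount_from_cigar(self, tiny_result):
        for role in ("domesticated", "wild"):
            for line in ("long", "short", "none"):
                for b in tiny_result.blocks[role][line]:
                    cols = sum(ln for _op, ln in b.cigar)
                    matches = sum(ln for op, ln in b.cigar if op == "=")
                    assert cols == b.aligned_columns
                    assert matches == b.matches
                    assert 0.0 <= b.identity <= 1.0

    def test_banded_identity_close_to_full_dp_oracle(self):
        """Banded refinement vs edlib (exact, unbanded NW) on diverged pairs."""
        import edlib
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = _rand_seq(rng, 500)
            b_list = list(a)
            # ~5% divergence with indels
            for _ in range(20):
                i = int(rng.integers(10, len(b_list) - 10))
                op = rng.random()
                if op < 0.6:
                    b_list[i] = "ACGT"[int(rng.integers(4))]
                elif op < 0.8:
                    b_list.insert(i, "ACGT"[int(rng.integers(4))])
                else:
                    del b_list[i]
            b = "".join(b_list)
            ops = align_segment(a, b, band=64)
            cols = sum(ln for _o, ln in ops)
            ident = sum(ln for o, ln in ops if o == "=") / cols
            # edlib emits an extended cigar: '=' match, 'X' mismatch,
            # 'I' consumes the query (b), 'D' consumes the target (a)
            res = edlib.align(b, a, mode="NW", task="path")
            import re
            o_cols = o_match = 0
            for ln, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
                o_cols += int(ln)
                if op == "=":
                    o_match += int(ln)
            assert abs(ident - o_match / o_cols) <= 0.01

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        s = _rand_seq(rng, 3000)
        frag = s[500:1500]
        fwd = self._block_for(s, frag)
        rev = self._block_for(s, revcomp(frag))
        assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)
        assert fwd.strand == "+" and rev.strand == "-"
        assert fwd.identity == rev.identity == 1.0


class TestPaf:
    def test_round_trip_preserves_fields(self, tiny_result, tmp_path):
        blocks = tiny_result.blocks["domesticated"]["long"]
        p = tmp_path / "a.paf"
        export_paf(blocks, p)
        back = import_paf(p)
        for x, y in zip(blocks, back):
            assert (x.ctg_name, x.ctg_start, x.ctg_end, x.strand,
                    x.ref_name, x.ref_start, x.ref_end, x.matches,
                    x.aligned_columns) == \
                   (y.ctg_name, y.ctg_start, y.ctg_end, y.strand,
                    y.ref_name, y.ref_start, y.ref_end, y.matches,
                    y.aligned_columns)
            assert x.cigar == y.cigar

    def test_reverse_strand_forward_query_coordinates(self):
        rng = np.random.default_rng(6)
        s = _rand_seq(rng, 2000)
        ref = SeqRecord("r", s)
        ctg = SeqRecord("c", revcomp(s[300:900]))
        _ch, blocks = align_contigs(ref, [ctg], min_chain_anchors=2)
        line = export_paf(blocks)[0].split("\t")
        assert line[4] == "-"
        qs, qe, qlen = int(line[2]), int(line[3]), int(line[1])
        assert 0 <= qs < qe <= qlen  # forward-strand interval

    def test_hand_written_line(self):
        line = "ctgA\t500\t10\t110\t+\tchr1\t9000\t1000\t1100\t95\t100\t60"
        (b,) = import_paf([line])
        assert (b.ctg_name, b.ctg_len, b.ctg_start, b.ctg_end) == ("ctgA", 500, 10, 110)
        assert (b.ref_name, b.ref_start, b.ref_end) == ("chr1", 1000, 1100)
        assert b.matches == 95 and b.aligned_columns == 100
        assert b.identity == pytest.approx(0.95)

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 1"):
            import_paf(["only\tfour\tcolumns\there"])


class TestDotplot:
    def _blk(self, rs, re_, cs, ce, matches, cols, name="c"):
        from introscope.align import AlignmentBlock
        return AlignmentBlock(name, "r", cs, ce, rs, re_, "+",
                              matches, cols, 10_000, 10_000)

    def test_single_full_identity_block(self):
        data = dotplot_data([self._blk(0, 300, 0, 300, 300, 300)], bin=100)
        assert len(data) == 3
        assert all(v == 1.0 for *_k, v in data)

    def test_empty(self):
        assert dotplot_data([], bin=100) == []

    def test_weighted_mean_in_shared_bin(self):
        # two blocks of one contig inside the same (ref, ctg) bin with
        # equal reference weight: mean of 0.9 and 1.0 is 0.95
        b1 = self._blk(0, 40, 0, 40, 40, 40)
        b2 = self._blk(50, 90, 50, 90, 36, 40)
        data = dotplot_data([b1, b2], bin=100)
        assert len(data) == 1
        assert data[0][4] == pytest.approx(0.95)


class TestSelfAlignment:
    def test_fragments_cover_reference_at_identity_one(self, tiny_sim):
        from introscope.simulate import SimConfig, fragment_into_contigs
        dom, wild, _genomes, _contigs, _truth = tiny_sim
        cfg = SimConfig(seed=9, chrom_length=len(wild.sequence),
                        contig_n50_target=60_000, contig_gap_rate=0.0,
                        introgression_long=(30_000, 170_000),
                        introgression_short=(120_000, 126_000))
        frags = fragment_into_contigs(wild, cfg, "self")
        _ch, blocks = align_contigs(wild, frags)
        non_n = len(wild.sequence) - wild.sequence.count("N")
        covered = np.zeros(len(wild.sequence), dtype=bool)
        for b in blocks:
            covered[b.ref_start:b.ref_end] = True
            for e in b.edits:
                assert "N" in e.ref or "N" in e.alt  # only Ns mismatch
        wild_arr = np.frombuffer(wild.sequence.encode(), dtype=np.uint8)
        cov_non_n = int((covered & (wild_arr != ord("N"))).sum())
        assert cov_non_n >= 0.99 * non_n
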