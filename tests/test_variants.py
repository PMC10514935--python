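import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscope.align import AlignmentBlock, EditOp, align_contigs
from introscope.seqio import SeqRecord
from introscope.variants import (VariantRecord, build_presence_matrix,
                                 call_small_variants, call_svs,
                                 coverage_intervals, match_variants, read_vcf,
                                 write_vcf)


def _block(edits, ref_start=100, ref_end=400, name="c1", cols=300):
    matches = cols - sum(e.length for e in edits)
    return AlignmentBlock("c1" if name is None else name, "chr", 0, 300,
                          ref_start, ref_end, "+", matches, cols,
                          1000, 5000, cigar=[("=", cols)], edits=edits)


class TestSmallVariants:
    def test_identity_block_yields_nothing(self):
        assert call_small_variants([_block([])]) == []

    def test_substitution_coordinates(self):
        b = _block([EditOp(110, "A", "G")])
        (v,) = call_small_variants([b])
        assert (v.kind, v.pos, v.ref_allele, v.alt_allele) == ("SNP", 110, "A", "G")

    def test_sv_sized_edits_excluded(self):
        b = _block([EditOp(110, "A" * 60, ""), EditOp(200, "C", "T")])
        calls = call_small_variants([b], sv_min_length=50)
        assert [v.kind for v in calls] == ["SNP"]

    def test_n_alleles_dropped(self):
        b = _block([EditOp(110, "N", "G"), EditOp(120, "A", "N"),
                    EditOp(130, "A", "G")])
        assert [v.pos for v in call_small_variants([b])] == [130]

    def test_missing_edit_list_rejected(self):
        b = _block([])
        b.edits = None
        with pytest.raises(ValueError, match="edit list"):
            call_small_variants([b])

    def test_size_partition_invariant(self, tiny_result):
        for line in ("long", "short", "none"):
            small = tiny_result.small_calls["domesticated"][line]
            svs = tiny_result.sv_calls["domesticated"][line]
            assert all(v.length < 50 for v in small)
            assert all(v.length >= 50 for v in svs)


class TestCallSvs:
    def _surgery(self, op):
        rng = np.random.default_rng(12)
        ref_seq = "".join(rng.choice(list("ACGT"), size=4000))
        if op == "del":
            ctg_seq = ref_seq[:2000] + ref_seq[2100:]  # 100-bp deletion
        elif op == "ins":
            ctg_seq = ref_seq[:2000] + "".join(rng.choice(list("ACGT"), size=60)) + ref_seq[2000:]
        else:  # 40-bp deletion, below the SV cutoff
            ctg_seq = ref_seq[:2000] + ref_seq[2040:]
        ref = SeqRecord("chr", ref_seq)
        ctg = SeqRecord("ctg", ctg_seq)
        chains, blocks = align_contigs(ref, [ctg], min_chain_anchors=2)
        return ref, chains, blocks

    def test_planted_deletion_called(self):
        ref, chains, blocks = self._surgery("del")
        svs = call_svs(chains, blocks, 50, ref=ref)
        assert len(svs) == 1
        assert svs[0].kind == "DEL" and svs[0].length == 100
        assert abs(svs[0].pos - 2000) <= 50

    def test_planted_insertion_called(self):
        ref, chains, blocks = self._surgery("ins")
        svs = call_svs(chains, blocks, 50, ref=ref)
        assert len(svs) == 1
        assert svs[0].kind == "INS" and svs[0].length == 60
        assert abs(svs[0].pos - 2000) <= 50

    def test_sub_threshold_indel_stays_small(self):
        ref, chains, blocks = self._surgery("small")
        assert call_svs(chains, blocks, 50, ref=ref) == []
        small = call_small_variants(blocks, 50)
        assert [(v.kind, v.length) for v in small] == [("DEL", 40)]


class TestMatchVariants:
    def _del(self, start, end):
        return VariantRecord("chr", start, "DEL", end - start, "", "")

    def _ins(self, pos, length):
        return VariantRecord("chr", pos, "INS", length, "", "")

    def test_identical_records_match(self):
        v = VariantRecord("chr", 10, "SNP", 1, "A", "G")
        assert match_variants(v, v)

    def test_deletion_reciprocal_overlap(self):
        # overlap 60 of max length 100 -> 0.6 >= 0.5
        assert match_variants(self._del(1000, 1100), self._del(1040, 1140),
                              min_reciprocal_overlap=0.5)
        # overlap 10/100 -> no match
        assert not match_variants(self._del(1000, 1100), self._del(1090, 1190),
                                  min_reciprocal_overlap=0.5)

    def test_insertion_position_and_length_ratio(self):
        assert match_variants(self._ins(1000, 80), self._ins(1040, 60), pos_tol=50)
        assert not match_variants(self._ins(1000, 80), self._ins(1060, 80), pos_tol=50)
        assert not match_variants(self._ins(1000, 80), self._ins(1000, 30))

    def test_cross_type_never_matches(self):
        assert not match_variants(self._del(1000, 1100), self._ins(1000, 100))
        assert not match_variants(VariantRecord("chr", 10, "SNP", 1, "A", "G"),
                                  self._ins(10, 1))

    @given(st.integers(0, 5000), st.integers(0, 5000),
           st.integers(50, 500), st.integers(50, 500),
           st.sampled_from(["SNP", "INS", "DEL"]),
           st.sampled_from(["SNP", "INS", "DEL"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry(self, p1, p2, l1, l2, k1, k2):
        a = VariantRecord("chr", p1, k1, 1 if k1 == "SNP" else l1,
                          "A" if k1 == "SNP" else "", "G" if k1 == "SNP" else "")
        b = VariantRecord("chr", p2, k2, 1 if k2 == "SNP" else l2,
                          "A" if k2 == "SNP" else "", "G" if k2 == "SNP" else "")
        assert match_variants(a, b) == match_variants(b, a)


class TestPresenceMatrix:
    def _calls(self, pos=1000):
        v = lambda line: VariantRecord("chr", pos, "SNP", 1, "A", "G", line=line)
        return v

    def test_present_in_all_lines(self):
        v = self._calls()
        m = build_presence_matrix(
            {"long": [v("long")], "short": [v("short")], "none": [v("none")]},
            {ln: [(0, 5000)] for ln in ("long", "short", "none")})
        (row,) = m.rows
        assert row.triple == (1, 1, 1)

    def test_covered_absence_is_zero(self):
        v = self._calls()
        m = build_presence_matrix(
            {"long": [v("long")], "short": [v("short")], "none": []},
            {ln: [(0, 5000)] for ln in ("long", "short", "none")})
        (row,) = m.rows
        assert row.triple == (1, 1, 0)

    def test_uncovered_locus_is_undefined(self):
        v = self._calls()
        m = build_presence_matrix(
            {"long": [v("long")], "short": [], "none": []},
            {"long": [(0, 5000)], "short": [(0, 5000)], "none": [(2000, 5000)]})
        (row,) = m.rows
        assert row.triple == (1, 0, None)
        assert not row.fully_defined

    def test_cross_line_indel_clustering(self):
        a = VariantRecord("chr", 1000, "INS", 80, "", "A" * 80, line="long")
        b = VariantRecord("chr", 1010, "INS", 75, "", "A" * 75, line="short")
        m = build_presence_matrix(
            {"long": [a], "short": [b], "none": []},
            {ln: [(0, 5000)] for ln in ("long", "short", "none")})
        (row,) = m.rows
        assert row.triple == (1, 1, 0)

    def test_coverage_union(self):
        blocks = [_block([], ref_start=0, ref_end=100),
                  _block([], ref_start=50, ref_end=200),
                  _block([], ref_start=300, ref_end=400)]
        assert coverage_intervals(blocks) == [(0, 200), (300, 400)]


class TestVcf:
    def test_round_trip_and_coordinate_conventions(self, tmp_path):
        ref = SeqRecord("chr7", "ACGT" * 600)
        vs = [
            VariantRecord("chr7", 110, "SNP", 1, "A", "G"),
            VariantRecord("chr7", 999, "DEL", 100,
                          ("ACGT" * 600)[999:1099], ""),
            VariantRecord("chr7", 500, "INS", 60, "", "A" * 60),
            VariantRecord("chr7", 200, "DEL", 3, ("ACGT" * 600)[200:203], ""),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(vs, ref, path)
        text = path.read_text()
        # SNP at 0-based 110 -> POS 111
        assert "\t111\t.\tA\tG" in text
        # 100-bp DEL at 0-based 999 -> POS 999, END 1099, SVLEN -100
        sv_line = next(ln for ln in text.splitlines() if "<DEL>" in ln)
        f = sv_line.split("\t")
        assert f[1] == "999"
        assert "END=1099" in f[7] and "SVLEN=-100" in f[7]
        # read back through a standards-conformant parser (pysam)
        back = read_vcf(path)
        assert [(v.kind, v.pos, v.length) for v in back] == \
            [(v.kind, v.pos, v.length) for v in sorted(vs, key=lambda x: x.pos)]

    def test_position_outside_reference_rejected(self, tmp_path):
        ref = SeqRecord("chr7", "ACGT")
        with pytest.raises(ValueError, match="outside"):
            write_vcf([VariantRecord("chr7", 10, "SNP", 1, "A", "G")],
                      ref, tmp_path / "bad.vcf")
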