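"""Variant discovery from alignment blocks: small variants, structural
variants (>= 50 bp), cross-line matching, and the coverage-aware
presence matrix that drives differential classification.

A variant is "absent" from a line only when that line's alignments cover
the locus but no matching call exists; loci a line does not cover are
left undefined and excluded from differential classes, so assembly
dropouts are never counted as biological absence.  Variants with N in
either allele are dropped (the unambiguous-sequence principle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import AlignmentBlock, Chain
from .seqio import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SV_MIN_LENGTH",
    "POS_TOL",
    "MIN_RECIPROCAL_OVERLAP",
    "VariantRecord",
    "PresenceMatrix",
    "MatrixRow",
    "call_small_variants",
    "call_svs",
    "match_variants",
    "build_presence_matrix",
    "coverage_intervals",
    "write_vcf",
    "read_vcf",
]

SV_MIN_LENGTH = 50
POS_TOL = 50
MIN_RECIPROCAL_OVERLAP = 0.5
LINES = ("long", "short", "none")


@dataclass(frozen=True)
class VariantRecord:
    """A small variant or SV in reference coordinates (0-based).

    For deletions ``pos`` is the first deleted base; for insertions the
    insertion point.  ``alt_allele`` may be empty for symbolic SVs
    imported without sequence.
    """

    ref_name: str
    pos: int
    kind: str  # SNP | INS | DEL
    length: int
    ref_allele: str
    alt_allele: str
    line: str = ""
    support: str = ""          # contig name
    support_span: int = 0      # aligned columns of the supporting block

    @property
    def end(self) -> int:
        """Half-open end on the reference (pos for insertions)."""
        return self.pos + (self.length if self.kind == "DEL" else 0)

    def is_sv(self, sv_min_length: int = SV_MIN_LENGTH) -> bool:
        return self.kind != "SNP" and self.length >= sv_min_length


def _has_n(*alleles: str) -> bool:
    return any("N" in a for a in alleles)


# ---------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------

def call_small_variants(
    blocks: Iterable[AlignmentBlock],
    sv_min_length: int = SV_MIN_LENGTH,
    line: str = "",
) -> list[VariantRecord]:
    """Substitutions and indels shorter than ``sv_min_length`` from block
    edit lists (adjacent indel columns were merged at refinement)."""
    out: list[VariantRecord] = []
    for b in blocks:
        if b.edits is None:
            raise ValueError(
                f"block {b.ctg_name}:{b.ctg_start}-{b.ctg_end} lacks an edit list "
                "(imported PAF without cg tag?)"
            )
        for e in b.edits:
            if e.length >= sv_min_length:
                continue
            if _has_n(e.ref, e.alt):
                continue
            out.append(VariantRecord(
                ref_name=b.ref_name, pos=e.ref_pos, kind=e.kind,
                length=e.length, ref_allele=e.ref, alt_allele=e.alt,
                line=line, support=b.ctg_name, support_span=b.aligned_columns,
            ))
    out.sort(key=lambda v: (v.ref_name, v.pos, v.kind, v.alt_allele))
    return _dedupe_within_line(out)


def call_svs(
    chains: Sequence[Chain] | None,
    blocks: Sequence[AlignmentBlock],
    sv_min_length: int = SV_MIN_LENGTH,
    line: str = "",
    ref: SeqRecord | None = None,
    ctg_gap_tol: int = POS_TOL,
) -> list[VariantRecord]:
    """SVs (>= ``sv_min_length``): indels promoted from block edit lists,
    plus deletions/insertions implied by the gap between consecutive
    collinear blocks of one contig (reference span missing from the
    contig and vice versa)."""
    out: list[VariantRecord] = []
    for b in blocks:
        if b.edits is None:
            continue
        for e in b.edits:
            if e.kind == "SNP" or e.length < sv_min_length:
                continue
            if _has_n(e.ref, e.alt):
                continue
            out.append(VariantRecord(
                ref_name=b.ref_name, pos=e.ref_pos, kind=e.kind,
                length=e.length, ref_allele=e.ref, alt_allele=e.alt,
                line=line, support=b.ctg_name, support_span=b.aligned_columns,
            ))

    # inter-block events within one contig and strand
    by_ctg: dict[tuple[str, str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        by_ctg.setdefault((b.ctg_name, b.ref_name, b.strand), []).append(b)
    for (_ctg, ref_name, strand), bs in sorted(by_ctg.items()):
        bs = sorted(bs, key=lambda b: b.ref_start)
        for prev, nxt in zip(bs, bs[1:]):
            ref_gap = nxt.ref_start - prev.ref_end
            if strand == "+":
                ctg_gap = nxt.ctg_start - prev.ctg_end
            else:
                ctg_gap = prev.ctg_start - nxt.ctg_end
            if ref_gap >= sv_min_length and 0 <= ctg_gap <= ctg_gap_tol:
                allele = (ref.sequence[prev.ref_end : nxt.ref_start]
                          if ref is not None else "")
                if _has_n(allele):
                    continue
                out.append(VariantRecord(
                    ref_name=ref_name, pos=prev.ref_end, kind="DEL",
                    length=ref_gap, ref_allele=allele, alt_allele="",
                    line=line, support=prev.ctg_name,
                    support_span=prev.aligned_columns + nxt.aligned_columns,
                ))
            elif ctg_gap >= sv_min_length and 0 <= ref_gap <= ctg_gap_tol:
                out.append(VariantRecord(
                    ref_name=ref_name, pos=prev.ref_end, kind="INS",
                    length=ctg_gap, ref_allele="", alt_allele="",
                    line=line, support=prev.ctg_name,
                    support_span=prev.aligned_columns + nxt.aligned_columns,
                ))
    out.sort(key=lambda v: (v.ref_name, v.pos, v.kind))
    return _dedupe_within_line(out)


def _dedupe_within_line(records: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicate/conflicting calls at one locus within a line
    that come from *different* alignment blocks (overlapping chains seeing
    the same event twice), keeping the call with the larger supporting
    block.  Distinct nearby events reported by one and the same block are
    legitimate split representations and are kept."""
    out: list[VariantRecord] = []
    for v in records:  # records sorted by (ref, pos)
        if out:
            p = out[-1]
            same_block = (p.support == v.support
                          and p.support_span == v.support_span)
            same_locus = (p.ref_name == v.ref_name and p.kind == v.kind
                          and not same_block
                          and (p.pos == v.pos or match_variants(p, v)))
            if same_locus:
                if v.support_span > p.support_span:
                    out[-1] = v
                if (p.pos, p.alt_allele, p.length) != (v.pos, v.alt_allele, v.length):
                    logger.debug("conflicting calls at %s:%d kept larger block",
                                 v.ref_name, v.pos)
                continue
        out.append(v)
    return out


# ---------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------

def match_variants(
    a: VariantRecord,
    b: VariantRecord,
    pos_tol: int = POS_TOL,
    min_reciprocal_overlap: float = MIN_RECIPROCAL_OVERLAP,
) -> bool:
    """Whether two calls on the same reference describe the same event.

    SNP/SNP: same position and alt.  DEL/DEL: reciprocal overlap >=
    ``min_reciprocal_overlap``.  INS/INS: |pos difference| <= ``pos_tol``
    and length ratio >= ``min_reciprocal_overlap``.  Cross-type never
    matches.  Symmetric by construction.
    """
    if a.ref_name != b.ref_name or a.kind != b.kind:
        return False
    if a.kind == "SNP":
        return a.pos == b.pos and a.alt_allele == b.alt_allele
    if a.kind == "DEL":
        ov = min(a.end, b.end) - max(a.pos, b.pos)
        return ov > 0 and ov >= min_reciprocal_overlap * max(a.length, b.length)
    # INS
    ratio = min(a.length, b.length) / max(a.length, b.length)
    return abs(a.pos - b.pos) <= pos_tol and ratio >= min_reciprocal_overlap


# ---------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------

def coverage_intervals(blocks: Iterable[AlignmentBlock]) -> list[tuple[int, int]]:
    """Merged union of block reference intervals."""
    ivs = sorted((b.ref_start, b.ref_end) for b in blocks)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covered(pos: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    if starts.size == 0:
        return False
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


@dataclass
class MatrixRow:
    """One clustered variant with per-line presence flags (1 present,
    0 covered-but-absent, None uncovered)."""

    ref_name: str
    kind: str
    pos: int
    length: int
    alt_allele: str
    flags: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)
    label: str | None = None  # filled by differential classification

    @property
    def triple(self) -> tuple:
        return tuple(self.flags.get(ln) for ln in LINES)

    @property
    def fully_defined(self) -> bool:
        return all(f is not None for f in self.triple)

    def is_sv(self, sv_min_length: int = SV_MIN_LENGTH) -> bool:
        return self.kind != "SNP" and self.length >= sv_min_length


@dataclass
class PresenceMatrix:
    """Cross-line variant presence flags on one reference."""

    rows: list[MatrixRow]
    lines: tuple = LINES

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            cols = ["ref", "pos", "type", "length"] + list(self.lines) + ["class"]
            fh.write("\t".join(cols) + "\n")
            for r in self.rows:
                flags = ["." if r.flags.get(ln) is None else str(r.flags[ln])
                         for ln in self.lines]
                fh.write("\t".join([r.ref_name, str(r.pos), r.kind, str(r.length)]
                                   + flags + [r.label or "."]) + "\n")


def build_presence_matrix(
    calls_by_line: Mapping[str, Sequence[VariantRecord]],
    coverage_by_line: Mapping[str, Sequence[tuple[int, int]]],
    pos_tol: int = POS_TOL,
    min_reciprocal_overlap: float = MIN_RECIPROCAL_OVERLAP,
    lines: Sequence[str] = LINES,
) -> PresenceMatrix:
    """Cluster calls across lines (single linkage via ``match_variants``)
    and attach coverage-aware presence flags."""
    cov = {}
    for ln in lines:
        ivs = list(coverage_by_line.get(ln, []))
        starts = np.asarray([s for s, _ in ivs], dtype=np.int64)
        ends = np.asarray([e for _, e in ivs], dtype=np.int64)
        cov[ln] = (starts, ends)

    rows: list[MatrixRow] = []

    # SNPs: exact (ref, pos, alt) key
    snp_groups: dict[tuple, dict] = {}
    per_kind: dict[str, list[tuple[str, VariantRecord]]] = {"INS": [], "DEL": []}
    for ln in lines:
        for v in calls_by_line.get(ln, []):
            if v.kind == "SNP":
                snp_groups.setdefault((v.ref_name, v.pos, v.alt_allele), {})[ln] = v
            else:
                per_kind[v.kind].append((ln, v))
    for (ref_name, pos, alt), recs in sorted(snp_groups.items()):
        rows.append(MatrixRow(ref_name, "SNP", pos, 1, alt, records=recs))

    # indels / SVs: positional single-linkage clustering per kind
    for kind in ("INS", "DEL"):
        items = sorted(per_kind[kind], key=lambda t: (t[1].ref_name, t[1].pos))
        cluster: list[tuple[str, VariantRecord]] = []

        def flush():
            if not cluster:
                return
            recs: dict[str, VariantRecord] = {}
            for ln, v in cluster:
                if ln not in recs or v.support_span > recs[ln].support_span:
                    recs[ln] = v
            rep = next(recs[ln] for ln in lines if ln in recs)
            rows.append(MatrixRow(rep.ref_name, kind, rep.pos, rep.length,
                                  rep.alt_allele, records=recs))

        for ln, v in items:
            if cluster and any(
                c.ref_name == v.ref_name
                and match_variants(c, v, pos_tol, min_reciprocal_overlap)
                for _, c in cluster
            ):
                cluster.append((ln, v))
            else:
                flush()
                cluster = [(ln, v)]
        flush()

    for r in rows:
        for ln in lines:
            if ln in r.records:
                r.flags[ln] = 1
            elif _covered(r.pos, *cov[ln]):
                r.flags[ln] = 0
            else:
                r.flags[ln] = None
    rows.sort(key=lambda r: (r.ref_name, r.pos, r.kind, r.alt_allele))
    return PresenceMatrix(rows=rows, lines=tuple(lines))


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=introscope
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length difference between ALT and REF alleles">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=LINE,Number=1,Type=String,Description="Source line">
"""


def write_vcf(
    variants: Sequence[VariantRecord],
    reference: SeqRecord | Mapping[str, SeqRecord],
    path: str | Path,
    sv_min_length: int = SV_MIN_LENGTH,
) -> None:
    """VCF v4.2: 1-based, anchor-base convention for indels; SVs >=
    ``sv_min_length`` written symbolically with SVTYPE/SVLEN/END."""
    refs = {reference.name: reference} if isinstance(reference, SeqRecord) else dict(reference)
    recs = sorted(variants, key=lambda v: (v.ref_name, v.pos, v.kind, v.alt_allele))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, rec in refs.items():
            fh.write(f"##contig=<ID={name},length={len(rec.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in recs:
            if v.ref_name not in refs:
                raise ValueError(f"variant on unknown reference {v.ref_name!r}")
            seq = refs[v.ref_name].sequence
            if not (0 <= v.pos <= len(seq)):
                raise ValueError(f"variant position {v.pos} outside {v.ref_name}")
            info = f"LINE={v.line}" if v.line else "."
            if v.kind == "SNP":
                fh.write(f"{v.ref_name}\t{v.pos + 1}\t.\t{v.ref_allele}\t"
                         f"{v.alt_allele}\t.\tPASS\t{info}\n")
            elif v.is_sv(sv_min_length):
                anchor_pos = v.pos - 1
                anchor = seq[anchor_pos] if anchor_pos >= 0 else seq[v.end]
                svtype = v.kind
                svlen = -v.length if v.kind == "DEL" else v.length
                end = v.pos + v.length if v.kind == "DEL" else v.pos
                extra = f"SVTYPE={svtype};SVLEN={svlen};END={end}"
                if info != ".":
                    extra += f";{info}"
                fh.write(f"{v.ref_name}\t{max(v.pos, 1)}\t.\t{anchor}\t"
                         f"<{svtype}>\t.\tPASS\t{extra}\n")
            else:
                # small indel: anchor base before the event
                a = v.pos - 1
                if a >= 0:
                    anchor = seq[a]
                    ref_field = anchor + v.ref_allele
                    alt_field = anchor + v.alt_allele
                    pos1 = v.pos  # 1-based position of the anchor
                else:
                    anchor = seq[v.pos + len(v.ref_allele)]
                    ref_field = v.ref_allele + anchor
                    alt_field = v.alt_allele + anchor
                    pos1 = 1
                fh.write(f"{v.ref_name}\t{pos1}\t.\t{ref_field}\t{alt_field}"
                         f"\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF through pysam (standards-conformant parsing); returns
    records in the package's 0-based convention."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            line = rec.info.get("LINE", "")
            alt = rec.alts[0] if rec.alts else ""
            if alt in ("<DEL>", "<INS>"):
                kind = alt[1:-1]
                svlen = abs(int(rec.info["SVLEN"]))
                pos = rec.pos  # 1-based anchor -> 0-based event start
                out.append(VariantRecord(rec.chrom, pos, kind, svlen,
                                         "", "", line=line))
            elif len(rec.ref) == 1 and len(alt) == 1:
                out.append(VariantRecord(rec.chrom, rec.pos - 1, "SNP", 1,
                                         rec.ref, alt, line=line))
            else:
                # anchored indel
                if len(rec.ref) > len(alt):
                    kind = "DEL"
                    length = len(rec.ref) - len(alt)
                    ref_allele = rec.ref[len(alt):]
                    alt_allele = ""
                else:
                    kind = "INS"
                    length = len(alt) - len(rec.ref)
                    ref_allele = ""
                    alt_allele = alt[len(rec.ref):]
                out.append(VariantRecord(rec.chrom, rec.pos, kind, length,
                                         ref_allele, alt_allele, line=line))
    out.sort(key=lambda v: (v.ref_name, v.pos, v.kind))
    return out
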