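"""Contig-to-reference alignment: minimizer anchoring, collinear
chaining, and banded refinement.

The aligner produces identity-scored blocks suitable for dot plots
(identity color-coded 0 to 1), variant discovery (per-block edit lists),
and gap-spanning analysis.  It is deliberately a whole-genome *contig*
aligner: minimizers anchor exact k-mer matches, a longest-increasing-
subsequence-style DP chains collinear anchors per strand, and the
inter-anchor segments are resolved with a banded unit-cost alignment.
PAF import/export allows substituting an external whole-genome aligner
at the same seam.

Identity is per-column: matches / aligned columns, where aligned columns
count substitution and indel columns alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .seqio import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Anchor",
    "Chain",
    "EditOp",
    "AlignmentBlock",
    "MinimizerIndex",
    "build_minimizer_index",
    "collect_anchors",
    "chain_anchors",
    "refine_blocks",
    "align_contigs",
    "export_paf",
    "import_paf",
    "dotplot_data",
    "revcomp",
]

DEFAULT_K = 15
DEFAULT_W = 10
DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_CHAIN_ANCHORS = 4
DEFAULT_BAND = 64
DEFAULT_MAX_OCCURRENCES = 200

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")
# hashes are kept below 2**52 so scipy's float64-based running filters
# compare them exactly; the sentinel marks windows containing N
_SENTINEL = np.int64(1) << np.int64(52)


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_RC)[::-1].decode("ascii")


# ---------------------------------------------------------------------
# minimizers
# ---------------------------------------------------------------------

def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer — an invertible hash so minimizer choice is
    not biased toward poly-A."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _minimizers(seq: str, k: int, w: int):
    """Positions, canonical codes, and strand flags of (k,w)-minimizers.

    Canonical code = min(forward, reverse-complement) k-mer code; the
    strand flag records whether the forward form was canonical.  Windows
    containing N never contribute.  Selection keeps every position whose
    hash is minimal in at least one window (standard rule, deterministic).
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if k > len(arr):
        raise ValueError(f"k={k} exceeds sequence length {len(arr)}")
    vals = _LUT[arr].astype(np.int64)
    n = len(arr) - k + 1

    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    v = np.where(vals >= 0, vals, 0).astype(np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | v[j : j + n]
        rc = (rc << np.uint64(2)) | (np.uint64(3) - v[k - 1 - j : k - 1 - j + n])

    bad = np.concatenate(([0], np.cumsum((vals < 0).astype(np.int64))))
    invalid = (bad[k:] - bad[:-k]) > 0

    is_fwd = fwd <= rc
    canon = np.where(is_fwd, fwd, rc)
    h = (_mix64(canon) >> np.uint64(12)).astype(np.int64)
    h[invalid] = _SENTINEL

    if w == 1:
        sel = ~invalid
    else:
        if n < w:
            w = n
        big = _SENTINEL
        # wmin[i] = min(h[i:i+w]) via a centered filter shifted by w//2
        wmin = minimum_filter1d(h, size=w, mode="constant", cval=big)
        wmin = wmin[w // 2 : w // 2 + n - w + 1]
        # G[p] = max over windows covering p of wmin -> start-aligned max
        pad = np.concatenate(
            (np.full(w - 1, -1, dtype=np.int64), wmin, np.full(w - 1, -1, dtype=np.int64))
        )
        g = maximum_filter1d(pad, size=w, mode="constant", cval=-1)
        g = g[w // 2 : w // 2 + n]  # G[p] = max(pad[p : p+w]) = max over windows covering p
        sel = (h == g) & ~invalid
    pos = np.flatnonzero(sel)
    return pos.astype(np.int64), canon[pos], is_fwd[pos]


@dataclass
class MinimizerIndex:
    """Sorted-array minimizer index of one reference sequence."""

    ref_name: str
    ref_len: int
    k: int
    w: int
    codes: np.ndarray      # sorted canonical codes
    positions: np.ndarray  # reference positions, grouped by code
    strands: np.ndarray    # True where the forward k-mer was canonical
    masked: int = 0        # distinct codes dropped as over-represented

    def lookup(self, code_arr: np.ndarray):
        lo = np.searchsorted(self.codes, code_arr, side="left")
        hi = np.searchsorted(self.codes, code_arr, side="right")
        return lo, hi


def build_minimizer_index(
    ref: SeqRecord,
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
) -> MinimizerIndex:
    """Index reference minimizers; codes occurring more than
    ``max_occurrences`` times are masked (repeat control)."""
    if not (1 <= k <= 31):
        raise ValueError("k must be in [1, 31]")
    if w < 1:
        raise ValueError("w must be >= 1")
    pos, codes, strands = _minimizers(ref.sequence, k, w)
    order = np.argsort(codes, kind="stable")
    codes, pos, strands = codes[order], pos[order], strands[order]

    masked = 0
    if codes.size:
        uniq, starts, counts = np.unique(codes, return_index=True, return_counts=True)
        heavy = counts > max_occurrences
        masked = int(heavy.sum())
        if masked:
            keep = np.ones(codes.size, dtype=bool)
            for s, c in zip(starts[heavy].tolist(), counts[heavy].tolist()):
                keep[s : s + c] = False
            codes, pos, strands = codes[keep], pos[keep], strands[keep]
    return MinimizerIndex(ref.name, len(ref.sequence), k, w, codes, pos, strands, masked)


# ---------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """An exact k-mer match; ctg_pos is on the oriented contig (reverse
    complement coordinates for '-' anchors)."""

    ref_pos: int
    ctg_pos: int
    length: int
    strand: str  # '+' or '-'


def collect_anchors(index: MinimizerIndex, ctg: SeqRecord):
    """Anchor arrays (ref_pos, oriented ctg_pos, strand) for one contig.

    Returns dict strand -> (r, q) int64 arrays, plus contig length.
    """
    k = index.k
    qlen = len(ctg.sequence)
    if k > qlen:
        return {"+": (np.empty(0, np.int64), np.empty(0, np.int64)),
                "-": (np.empty(0, np.int64), np.empty(0, np.int64))}
    qpos, qcodes, qfwd = _minimizers(ctg.sequence, k, index.w)
    lo, hi = index.lookup(qcodes)
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return {"+": (np.empty(0, np.int64), np.empty(0, np.int64)),
                "-": (np.empty(0, np.int64), np.empty(0, np.int64))}
    q_rep = np.repeat(qpos, counts)
    qf_rep = np.repeat(qfwd, counts)
    # vectorized flattening of [lo, hi) ranges
    nz = counts > 0
    cnt = counts[nz]
    ends = np.cumsum(cnt)
    within = np.arange(total, dtype=np.int64) - np.repeat(ends - cnt, cnt)
    idx = np.repeat(lo[nz], cnt) + within
    r_pos = index.positions[idx]
    r_fwd = index.strands[idx]
    same = r_fwd == qf_rep

    out = {}
    # forward-strand anchors
    out["+"] = (r_pos[same], q_rep[same])
    # reverse: contig coordinate on the reverse complement
    q_rc = qlen - q_rep[~same] - k
    out["-"] = (r_pos[~same], q_rc)
    return out


# ---------------------------------------------------------------------
# fragments & chaining
# ---------------------------------------------------------------------

def _compress_fragments(r: np.ndarray, q: np.ndarray, k: int):
    """Merge same-diagonal overlapping/abutting anchors into exact match
    fragments; returns (rs, re, qs, qe, n_anchors) sorted by (rs, qs)."""
    if r.size == 0:
        e = np.empty(0, np.int64)
        return e, e, e, e, e
    diag = r - q
    order = np.lexsort((r, diag))
    r, q, diag = r[order], q[order], diag[order]
    new_run = np.ones(r.size, dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (r[1:] > r[:-1] + k)
    run_id = np.cumsum(new_run) - 1
    nruns = int(run_id[-1]) + 1
    first = np.flatnonzero(new_run)
    last = np.concatenate((first[1:] - 1, [r.size - 1]))
    rs = r[first]
    re = r[last] + k
    qs = q[first]
    qe = q[last] + k
    n_anchors = (last - first + 1).astype(np.int64)
    order2 = np.lexsort((qs, rs))
    return rs[order2], re[order2], qs[order2], qe[order2], n_anchors[order2]


@dataclass
class Chain:
    """A maximal-scoring collinear chain of exact match fragments."""

    ctg_name: str
    ref_name: str
    strand: str
    rs: np.ndarray
    re: np.ndarray
    qs: np.ndarray
    qe: np.ndarray
    n_anchors: int
    score: float
    ctg_len: int
    ref_len: int

    @property
    def ref_span(self) -> tuple[int, int]:
        return int(self.rs[0]), int(self.re[-1])

    @property
    def ctg_span(self) -> tuple[int, int]:
        """Oriented contig span (reverse-complement coords for '-')."""
        return int(self.qs[0]), int(self.qe[-1])


def _chain_fragment_arrays(rs, re, qs, qe, n_anchors, max_gap, min_chain_anchors,
                           lookback: int = 64, max_overlap: int | None = None):
    """DP + backtrack over fragment arrays; returns list of index arrays."""
    from ._kernels import chain_dp

    if rs.size == 0:
        return []
    if max_overlap is None:
        max_overlap = 2 * DEFAULT_K
    weight = (re - rs).astype(np.float64)
    score, prev = chain_dp(rs, re, qs, qe, weight,
                           np.int64(max_gap), np.int64(lookback),
                           np.int64(max_overlap))
    used = np.zeros(rs.size, dtype=bool)
    chains = []
    for i in np.argsort(-score, kind="stable").tolist():
        if used[i]:
            continue
        members = []
        j = i
        while j >= 0 and not used[j]:
            members.append(j)
            used[j] = True
            j = prev[j]
        members.reverse()
        idx = np.asarray(members, dtype=np.int64)
        if int(n_anchors[idx].sum()) >= min_chain_anchors:
            chains.append(idx)
    return chains


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    min_chain_anchors: int = DEFAULT_MIN_CHAIN_ANCHORS,
    ctg_name: str = "ctg",
    ref_name: str = "ref",
    ctg_len: int = 0,
    ref_len: int = 0,
) -> list[Chain]:
    """Chain anchors of one contig-reference pair into maximal-scoring
    collinear subsets (same strand, increasing in both coordinates);
    coordinate gaps beyond ``max_gap`` terminate a chain and chains with
    fewer than ``min_chain_anchors`` anchors are dropped."""
    out: list[Chain] = []
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        k = sub[0].length
        r = np.asarray([a.ref_pos for a in sub], dtype=np.int64)
        q = np.asarray([a.ctg_pos for a in sub], dtype=np.int64)
        rs, re, qs, qe, n_anch = _compress_fragments(r, q, k)
        for idx in _chain_fragment_arrays(rs, re, qs, qe, n_anch,
                                          max_gap, min_chain_anchors):
            out.append(Chain(ctg_name, ref_name, strand,
                             rs[idx], re[idx], qs[idx], qe[idx],
                             int(n_anch[idx].sum()),
                             0.0, ctg_len, ref_len))
    out.sort(key=lambda c: (c.ref_span[0], c.ctg_span[0], c.strand))
    return out


# ---------------------------------------------------------------------
# banded refinement
# ---------------------------------------------------------------------

_INF = np.int32(10**9)
_widen_logged = False


def _banded_align(a: str, b: str, band: int):
    """Global unit-cost banded alignment of ``a`` (reference side) and
    ``b`` (contig side); returns ops [(op, length)] with ops in
    {'=','X','D','I'} ('D' consumes reference only, 'I' contig only).

    The corridor always contains the |len(a)-len(b)| diagonal envelope;
    ``band`` is the extra half-width.  Traceback prefers diagonal, then
    reference-consuming, then contig-consuming moves (deterministic,
    left-shifted indels).
    """
    global _widen_logged
    m, n = len(a), len(b)
    if m == 0 and n == 0:
        return []
    if m == 0:
        return [("I", n)]
    if n == 0:
        return [("D", m)]
    if m * n <= 40_000:
        return _full_dp_small(a, b)
    if band < abs(n - m) and not _widen_logged:
        logger.info("banded alignment corridor widened to cover length "
                    "difference %d (band=%d)", abs(n - m), band)
        _widen_logged = True
    # slack beyond the shorter side is unreachable; keep the corridor tight
    slack = max(8, min(band, min(m, n)))
    lo = min(0, n - m) - slack
    hi = max(0, n - m) + slack
    W = hi - lo + 1

    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    offs = np.arange(lo, hi + 1, dtype=np.int64)

    ptr = np.full((m + 1, W), -1, dtype=np.int8)
    prev = np.full(W, _INF, dtype=np.int32)
    # row 0: j = off, cost j (insertions)
    valid0 = (offs >= 0) & (offs <= n)
    prev[valid0] = offs[valid0].astype(np.int32)
    ptr[0, valid0] = 3
    if 0 >= lo:
        ptr[0, -lo] = -1  # origin

    for i in range(1, m + 1):
        j = offs + i
        valid = (j >= 0) & (j <= n)
        jj = np.clip(j, 0, n)
        # substitution cost: a[i-1] vs b[j-1]
        bj = bb[np.clip(jj - 1, 0, n - 1)]
        is_match = (bj == aa[i - 1]) & (bj != ord("N"))
        sub = np.where((jj >= 1) & is_match, 0, 1).astype(np.int32)
        diag = np.where((j >= 1) & (j <= n), prev + sub, _INF)
        up = np.full(W, _INF, dtype=np.int32)
        up[:-1] = prev[1:] + 1
        up = np.where(valid, up, _INF)
        tmp = np.minimum(diag, up)
        # left closure: cur[k] = min_{k'<=k} tmp[k'] + (k - k')
        idx = np.arange(W, dtype=np.int64)
        run = np.minimum.accumulate(
            np.where(valid, tmp.astype(np.int64) - idx, np.int64(_INF))
        )
        cur = np.minimum(tmp.astype(np.int64), run + idx)
        cur = np.where(valid, cur, np.int64(_INF)).astype(np.int32)
        p = np.full(W, -1, dtype=np.int8)
        is_left = cur < tmp
        p[cur == up] = 2
        p[cur == diag] = np.where(sub[cur == diag] == 0, 0, 1)
        p[is_left] = 3
        p[~valid] = -1
        ptr[i] = p
        prev = cur

    # traceback from (m, offset n-m)
    kk = (n - m) - lo
    if not (0 <= kk < W) or prev[kk] >= _INF:
        raise RuntimeError("banded alignment corridor exhausted")
    ops_rev: list[str] = []
    i = m
    while True:
        op = ptr[i, kk]
        if op == -1:
            break
        if op == 0:
            ops_rev.append("=")
            i -= 1
        elif op == 1:
            ops_rev.append("X")
            i -= 1
        elif op == 2:
            ops_rev.append("D")
            i -= 1
            kk += 1
        else:
            ops_rev.append("I")
            kk -= 1
        if i == 0 and kk == -lo:
            rem = ptr[0, kk]
            if rem == -1:
                break
    ops_rev.reverse()
    return _merge_ops(ops_rev)


def _full_dp_small(a: str, b: str):
    """Exact unit-cost global alignment for small segments (plain lists;
    cheaper than the vectorized corridor below this size)."""
    m, n = len(a), len(b)
    rows = [list(range(n + 1))]
    for i in range(1, m + 1):
        prev = rows[-1]
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            d = prev[j - 1] + (ai != b[j - 1] or ai == "N")
            u = prev[j] + 1
            l = cur[j - 1] + 1
            cur[j] = d if d <= u and d <= l else (u if u <= l else l)
        rows.append(cur)
    ops_rev: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = a[i - 1] != b[j - 1] or a[i - 1] == "N"
            if rows[i][j] == rows[i - 1][j - 1] + sub:
                ops_rev.append("X" if sub else "=")
                i -= 1
                j -= 1
                continue
        if i > 0 and rows[i][j] == rows[i - 1][j] + 1:
            ops_rev.append("D")
            i -= 1
            continue
        ops_rev.append("I")
        j -= 1
    ops_rev.reverse()
    return _merge_ops(ops_rev)


def _merge_ops(ops: Iterable[str]):
    merged: list[tuple[str, int]] = []
    for op in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + 1)
        else:
            merged.append((op, 1))
    return merged


def _column_align(a: str, b: str):
    """Substitution-only alignment of equal-length segments (vectorized)."""
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    # N never matches anything, itself included (unambiguous-sequence rule)
    mismatch = (aa != bb) | (aa == ord("N")) | (bb == ord("N"))
    ops: list[tuple[str, int]] = []
    if not mismatch.any():
        return [("=", len(a))] if len(a) else []
    padded = np.concatenate(([False], mismatch, [False]))
    delta = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(delta == 1)
    ends = np.flatnonzero(delta == -1)
    cur = 0
    for s, e in zip(starts.tolist(), ends.tolist()):
        if s > cur:
            ops.append(("=", s - cur))
        ops.append(("X", e - s))
        cur = e
    if cur < len(a):
        ops.append(("=", len(a) - cur))
    return ops


def _common_prefix(a: str, b: str, limit: int) -> int:
    n = 0
    while n < limit and a[n] == b[n] and a[n] != "N":
        n += 1
    return n


def align_segment(a: str, b: str, band: int = DEFAULT_BAND):
    """Align an inter-anchor segment (reference side ``a``, contig side
    ``b``).  Equal-length segments use column-wise comparison; a segment
    pair reducible to one pure indel by common prefix/suffix trimming is
    resolved directly; everything else goes through the banded DP."""
    m, n = len(a), len(b)
    if m == n:
        ops = _column_align(a, b)
        cost = sum(ln for op, ln in ops if op != "=")
        # a heavier mismatch load may hide a compensating indel pair that
        # a substitution-only alignment cannot express; arbitrate with DP
        if cost <= 4:
            return ops
        dp = _banded_align(a, b, band)
        return dp if sum(ln for op, ln in dp if op != "=") < cost else ops
    if m == 0 or n == 0:
        return _banded_align(a, b, band)
    # prefix/suffix trim: most inter-anchor length differences are a
    # single clean indel flanked by exact sequence
    lim = min(m, n)
    p = _common_prefix(a, b, lim)
    s = _common_prefix(a[::-1], b[::-1], lim - p)
    ops: list[tuple[str, int]] = []
    if p:
        ops.append(("=", p))
    mid_a, mid_b = a[p : m - s], b[p : n - s]
    if not mid_a:
        ops.append(("I", len(mid_b)))
    elif not mid_b:
        ops.append(("D", len(mid_a)))
    else:
        ops.extend(_banded_align(mid_a, mid_b, band))
    if s:
        ops.append(("=", s))
    # merge adjacent same ops at the seams
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


@dataclass(frozen=True)
class EditOp:
    """One difference on the reference: substitution (len-1 ref/alt),
    insertion (empty ref) or deletion (empty alt).  ``ref_pos`` is the
    0-based reference start (insertion point for insertions)."""

    ref_pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "DEL" if len(self.ref) > len(self.alt) else "INS"

    @property
    def length(self) -> int:
        return max(len(self.ref), len(self.alt), 1)


@dataclass
class AlignmentBlock:
    """An identity-scored contig-to-reference alignment interval pair.

    ``ctg_start``/``ctg_end`` are forward-strand contig coordinates (PAF
    convention).  ``cigar`` ops are '=XID' with the reference on the
    consuming side of 'D'.  ``edits`` lists substitutions and indels with
    reference coordinates (adjacent indel columns merged).
    """

    ctg_name: str
    ref_name: str
    ctg_start: int
    ctg_end: int
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    aligned_columns: int
    ctg_len: int
    ref_len: int
    cigar: list = field(default_factory=list)
    edits: list | None = None

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def ctg_interval(self) -> tuple[int, int]:
        return (self.ctg_start, self.ctg_end)


def _extend_exact(ref: str, ctg: str, r: int, q: int, direction: int) -> int:
    """Greedy exact extension; returns number of matching bases."""
    n = 0
    if direction < 0:
        while r - n - 1 >= 0 and q - n - 1 >= 0 and ref[r - n - 1] == ctg[q - n - 1] \
                and ref[r - n - 1] != "N":
            n += 1
    else:
        R, Q = len(ref), len(ctg)
        while r + n < R and q + n < Q and ref[r + n] == ctg[q + n] and ref[r + n] != "N":
            n += 1
    return n


def refine_blocks(
    chain: Chain,
    ref: SeqRecord,
    ctg: SeqRecord,
    band: int = DEFAULT_BAND,
) -> AlignmentBlock:
    """Resolve a chain into an alignment block: fragments are exact
    matches, inter-fragment segments are aligned (column-wise or banded
    DP), and block ends are extended by greedy exact match."""
    rseq = ref.sequence
    qseq = ctg.sequence if chain.strand == "+" else revcomp(ctg.sequence)
    qlen = len(ctg.sequence)

    ops: list[tuple[str, int]] = []
    edits: list[EditOp] = []

    cur_r = int(chain.rs[0])
    cur_q = int(chain.qs[0])
    ext = _extend_exact(rseq, qseq, cur_r, cur_q, -1)
    block_r0 = cur_r - ext
    block_q0 = cur_q - ext
    if ext:
        ops.append(("=", ext))

    def emit(op_list, r_off, rseg, qseg):
        ri = qi = 0
        for op, ln in op_list:
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + ln)
            else:
                ops.append((op, ln))
            if op == "=":
                ri += ln
                qi += ln
            elif op == "X":
                for t in range(ln):
                    edits.append(EditOp(r_off + ri + t, rseg[ri + t], qseg[qi + t]))
                ri += ln
                qi += ln
            elif op == "D":
                edits.append(EditOp(r_off + ri, rseg[ri : ri + ln], ""))
                ri += ln
            else:  # I
                edits.append(EditOp(r_off + ri, "", qseg[qi : qi + ln]))
                qi += ln

    nfrag = chain.rs.size
    for fi in range(nfrag):
        rs, re_, qs, qe = (int(chain.rs[fi]), int(chain.re[fi]),
                           int(chain.qs[fi]), int(chain.qe[fi]))
        if fi > 0:
            # trim fragment start against the running cursor (same-diagonal
            # shifts preserve exactness)
            d = max(cur_r - rs, cur_q - qs, 0)
            rs += d
            qs += d
            if rs >= re_ or qs >= qe:
                continue
            seg_r = rseq[cur_r:rs]
            seg_q = qseq[cur_q:qs]
            if seg_r or seg_q:
                emit(align_segment(seg_r, seg_q, band), cur_r, seg_r, seg_q)
        ln = min(re_ - rs, qe - qs)
        if ops and ops[-1][0] == "=":
            ops[-1] = ("=", ops[-1][1] + ln)
        else:
            ops.append(("=", ln))
        cur_r = rs + ln
        cur_q = qs + ln

    ext = _extend_exact(rseq, qseq, cur_r, cur_q, +1)
    if ext:
        if ops and ops[-1][0] == "=":
            ops[-1] = ("=", ops[-1][1] + ext)
        else:
            ops.append(("=", ext))
    block_r1 = cur_r + ext
    block_q1 = cur_q + ext

    matches = sum(ln for op, ln in ops if op == "=")
    columns = sum(ln for _, ln in ops)
    if chain.strand == "+":
        c0, c1 = block_q0, block_q1
    else:
        c0, c1 = qlen - block_q1, qlen - block_q0
    return AlignmentBlock(
        ctg_name=ctg.name,
        ref_name=ref.name,
        ctg_start=c0,
        ctg_end=c1,
        ref_start=block_r0,
        ref_end=block_r1,
        strand=chain.strand,
        matches=matches,
        aligned_columns=columns,
        ctg_len=qlen,
        ref_len=len(rseq),
        cigar=ops,
        edits=edits,
    )


# ---------------------------------------------------------------------
# top-level convenience
# ---------------------------------------------------------------------

def align_contigs(
    ref: SeqRecord,
    contigs: Iterable[SeqRecord],
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    max_gap: int = DEFAULT_MAX_GAP,
    min_chain_anchors: int = DEFAULT_MIN_CHAIN_ANCHORS,
    band: int = DEFAULT_BAND,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
    index: MinimizerIndex | None = None,
) -> tuple[list[Chain], list[AlignmentBlock]]:
    """Anchor, chain, and refine every contig against one reference."""
    if index is None:
        index = build_minimizer_index(ref, k, w, max_occurrences)
    chains_all: list[Chain] = []
    blocks: list[AlignmentBlock] = []
    for ctg in contigs:
        anchors = collect_anchors(index, ctg)
        for strand in ("+", "-"):
            r, q = anchors[strand]
            rs, re_, qs, qe, n_anch = _compress_fragments(r, q, index.k)
            for idx in _chain_fragment_arrays(rs, re_, qs, qe, n_anch,
                                              max_gap, min_chain_anchors):
                ch = Chain(ctg.name, ref.name, strand,
                           rs[idx], re_[idx], qs[idx], qe[idx],
                           int(n_anch[idx].sum()), 0.0,
                           len(ctg.sequence), len(ref.sequence))
                chains_all.append(ch)
                blocks.append(refine_blocks(ch, ref, ctg, band))
    order = sorted(range(len(blocks)),
                   key=lambda i: (blocks[i].ref_start, blocks[i].ctg_name,
                                  blocks[i].ctg_start))
    return [chains_all[i] for i in order], [blocks[i] for i in order]


# ---------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------

def _cigar_str(cigar) -> str:
    return "".join(f"{ln}{op}" for op, ln in cigar)


def export_paf(blocks: Iterable[AlignmentBlock], path: str | Path | None = None) -> list[str]:
    """Standard 12-column PAF (+ cg:Z cigar tag); forward-strand query
    coordinates, 0-based half-open."""
    lines = []
    for b in blocks:
        cols = [
            b.ctg_name, str(b.ctg_len), str(b.ctg_start), str(b.ctg_end),
            b.strand,
            b.ref_name, str(b.ref_len), str(b.ref_start), str(b.ref_end),
            str(b.matches), str(b.aligned_columns), "60",
        ]
        if b.cigar:
            cols.append(f"cg:Z:{_cigar_str(b.cigar)}")
        lines.append("\t".join(cols))
    if path is not None:
        Path(path).write_text("".join(ln + "\n" for ln in lines))
    return lines


def import_paf(source: str | Path | Iterable[str]) -> list[AlignmentBlock]:
    """Parse PAF into alignment blocks; the cg:Z tag is optional (edit
    lists are then absent and identity comes from the match columns)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        lines = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    blocks = []
    for i, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"malformed PAF at line {i}: expected >=12 columns, got {len(f)}")
        try:
            qlen, qs, qe = int(f[1]), int(f[2]), int(f[3])
            tlen, ts, te = int(f[6]), int(f[7]), int(f[8])
            nmatch, blocklen = int(f[9]), int(f[10])
        except ValueError as exc:
            raise ValueError(f"malformed PAF at line {i}: {exc}") from None
        if f[4] not in "+-":
            raise ValueError(f"malformed PAF at line {i}: bad strand {f[4]!r}")
        cigar = []
        for tag in f[12:]:
            if tag.startswith("cg:Z:"):
                import re as _re
                cigar = [(op, int(ln)) for ln, op in _re.findall(r"(\d+)([=XIDM])", tag[5:])]
        blocks.append(AlignmentBlock(
            ctg_name=f[0], ref_name=f[5],
            ctg_start=qs, ctg_end=qe, ref_start=ts, ref_end=te,
            strand=f[4], matches=nmatch, aligned_columns=blocklen,
            ctg_len=qlen, ref_len=tlen, cigar=cigar, edits=None,
        ))
    return blocks


def attach_edits(block: AlignmentBlock, ref: SeqRecord, ctg: SeqRecord) -> AlignmentBlock:
    """Reconstruct the edit list of an imported block from its cigar and
    the two sequences ('M' ops are resolved by column comparison)."""
    if not block.cigar:
        raise ValueError(
            f"block {block.ctg_name} has no cigar; cannot reconstruct edits"
        )
    rseq = ref.sequence
    qseq = ctg.sequence if block.strand == "+" else revcomp(ctg.sequence)
    q = block.ctg_start if block.strand == "+" else block.ctg_len - block.ctg_end
    r = block.ref_start
    edits: list[EditOp] = []
    for op, ln in block.cigar:
        if op == "M":  # resolve into =/X
            for t in range(ln):
                if rseq[r + t] != qseq[q + t]:
                    edits.append(EditOp(r + t, rseq[r + t], qseq[q + t]))
            r += ln
            q += ln
        elif op == "=":
            r += ln
            q += ln
        elif op == "X":
            for t in range(ln):
                edits.append(EditOp(r + t, rseq[r + t], qseq[q + t]))
            r += ln
            q += ln
        elif op == "D":
            edits.append(EditOp(r, rseq[r : r + ln], ""))
            r += ln
        elif op == "I":
            edits.append(EditOp(r, "", qseq[q : q + ln]))
            q += ln
        else:
            raise ValueError(f"unsupported cigar op {op!r}")
    block.edits = edits
    return block


# ---------------------------------------------------------------------
# dot plot data
# ---------------------------------------------------------------------

def dotplot_data(blocks: Iterable[AlignmentBlock], bin: int = 100_000):
    """Per-(ref_bin, ctg_bin) mean identity, weighted by the reference
    bases each block contributes to the bin; suitable for a 0-to-1 color
    scale."""
    if bin < 1:
        raise ValueError("bin must be >= 1")
    acc: dict[tuple[str, str, int, int], list[float]] = {}
    for b in blocks:
        rspan = b.ref_end - b.ref_start
        if rspan <= 0:
            continue
        first = b.ref_start // bin
        last = (b.ref_end - 1) // bin
        for rb in range(first, last + 1):
            lo = max(b.ref_start, rb * bin)
            hi = min(b.ref_end, (rb + 1) * bin)
            wgt = hi - lo
            mid = (lo + hi) / 2
            frac = (mid - b.ref_start) / rspan
            if b.strand == "+":
                cpos = b.ctg_start + frac * (b.ctg_end - b.ctg_start)
            else:
                cpos = b.ctg_end - frac * (b.ctg_end - b.ctg_start)
            cb = int(cpos) // bin
            key = (b.ref_name, b.ctg_name, rb, cb)
            cell = acc.setdefault(key, [0.0, 0.0])
            cell[0] += wgt
            cell[1] += wgt * b.identity
    out = [(ref, ctgn, rb, cb, val / wgt)
           for (ref, ctgn, rb, cb), (wgt, val) in sorted(acc.items())]
    return out
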