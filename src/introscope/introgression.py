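"""Introgression delineation: differential-variant classification,
windowed density profiles, boundary inference, line-unique SVs, and
gap-spanning analysis.

The trio design makes presence patterns diagnostic.  Against the
domesticated reference, a variant present in both introgression carriers
but absent (with coverage) from the carrier-free line marks domesticated
/wild divergence inside the *shared* (short) introgression; against the
wild reference, a variant shared by the short and none lines but absent
from the long line marks the region where only the long line carries
wild sequence.  Windowed counts of these classes rise sharply across the
introgression, and run-finding over the windows recovers its boundaries
on each reference independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentBlock
from .seqio import GapRecord
from .variants import SV_MIN_LENGTH, MatrixRow, PresenceMatrix

__all__ = [
    "DIFFERENTIAL_LABELS",
    "DensityProfile",
    "IntrogressionCall",
    "GapSpanReport",
    "classify_differential",
    "classify_matrix",
    "window_density",
    "infer_boundaries",
    "unique_svs",
    "gap_overlap",
]

DIFFERENTIAL_LABELS = (
    "diagnostic_dom",
    "diagnostic_wild",
    "long_unique",
    "short_none_shared_vs_long",
    "background",
    "other",
)

WINDOW_SIZE = 100_000
MAX_GAP_WINDOWS = 2
MIN_COUNT_FLOOR = 5


def classify_differential(
    flags: tuple[int, int, int],
    reference_role: str,
) -> str:
    """Label a fully-defined (long, short, none) presence triple.

    Pure truth table: (1,1,0) is ``diagnostic_dom`` under the
    domesticated role; (0,1,1) is ``diagnostic_wild`` under the wild role
    and ``short_none_shared_vs_long`` under the domesticated role;
    (1,0,0) is ``long_unique`` under either role; (1,1,1)/(0,0,0) are
    ``background``; every remaining triple is ``other``.
    """
    if reference_role not in ("domesticated", "wild"):
        raise ValueError(f"unknown reference_role {reference_role!r}")
    t = tuple(flags)
    if any(f not in (0, 1) for f in t) or len(t) != 3:
        raise ValueError(f"presence triple {flags!r} is not fully defined; "
                         "pre-filter undefined loci")
    if t in ((1, 1, 1), (0, 0, 0)):
        return "background"
    if t == (1, 0, 0):
        return "long_unique"
    if t == (1, 1, 0):
        return "diagnostic_dom" if reference_role == "domesticated" else "other"
    if t == (0, 1, 1):
        return ("short_none_shared_vs_long" if reference_role == "domesticated"
                else "diagnostic_wild")
    return "other"


def classify_matrix(matrix: PresenceMatrix, reference_role: str) -> list[MatrixRow]:
    """Label every fully-defined row in place; returns the labeled rows
    (rows with undefined flags are excluded and left unlabeled)."""
    labeled = []
    for row in matrix.rows:
        if not row.fully_defined:
            row.label = None
            continue
        row.label = classify_differential(row.triple, reference_role)
        labeled.append(row)
    return labeled


# ---------------------------------------------------------------------
# density windows
# ---------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-window counts of classified variants along one reference."""

    ref_name: str
    window_size: int
    counts: np.ndarray
    class_filter: tuple = ()

    @property
    def n_windows(self) -> int:
        return int(self.counts.size)

    def window_interval(self, i: int) -> tuple[int, int]:
        return (i * self.window_size, (i + 1) * self.window_size)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("ref\twindow_start\twindow_end\tcount\n")
            for i, c in enumerate(self.counts.tolist()):
                s, e = self.window_interval(i)
                fh.write(f"{self.ref_name}\t{s}\t{e}\t{c}\n")


def window_density(
    variants: Sequence[MatrixRow],
    ref_length: int,
    window_size: int = WINDOW_SIZE,
    class_filter: str | Sequence[str] | None = None,
    ref_name: str = "",
) -> DensityProfile:
    """Count classified variants per half-open window ``[i*w, (i+1)*w)``;
    the last window may be short.  ``class_filter`` restricts to one or
    several differential classes (None counts everything labeled)."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if isinstance(class_filter, str):
        class_filter = (class_filter,)
    n_win = max(1, -(-ref_length // window_size))
    counts = np.zeros(n_win, dtype=np.int64)
    name = ref_name
    for row in variants:
        if row.label is None:
            continue
        if class_filter is not None and row.label not in class_filter:
            continue
        if not (0 <= row.pos < ref_length):
            continue
        counts[row.pos // window_size] += 1
        name = name or row.ref_name
    return DensityProfile(ref_name=name, window_size=window_size, counts=counts,
                          class_filter=tuple(class_filter or ()))


# ---------------------------------------------------------------------
# boundary inference
# ---------------------------------------------------------------------

@dataclass
class IntrogressionCall:
    """A called introgression interval on one reference."""

    ref_name: str
    start: int
    end: int
    window_start: int   # first window index of the run
    window_end: int     # last window index (inclusive)
    supporting_class: tuple
    n_variants: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def resolve_min_count(counts: np.ndarray, floor: int = MIN_COUNT_FLOOR) -> int:
    """Adaptive threshold: ``max(floor, background mean + 3 SD)`` where
    the background is the windows outside candidate runs found with the
    floor threshold alone."""
    counts = np.asarray(counts)
    bg = counts[counts < floor]
    if bg.size == 0:
        return floor
    return int(max(floor, np.ceil(bg.mean() + 3 * bg.std())))


def infer_boundaries(
    profile: DensityProfile,
    min_count: int | None = None,
    max_gap_windows: int = MAX_GAP_WINDOWS,
    refine_with: Sequence[MatrixRow] | None = None,
) -> list[IntrogressionCall]:
    """Find maximal runs of windows with count >= ``min_count``, allowing
    up to ``max_gap_windows`` consecutive below-threshold windows inside
    a run; each call is refined to the [first, last+1) positions of the
    supporting classified variants within the run."""
    counts = profile.counts
    if counts.size == 0:
        return []
    if min_count is None:
        min_count = resolve_min_count(counts)
    hot = np.flatnonzero(counts >= min_count)
    if hot.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(hot[0])
    for i in hot[1:].tolist():
        if i - prev - 1 <= max_gap_windows:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))

    calls = []
    w = profile.window_size
    for ws, we in runs:
        lo, hi = ws * w, (we + 1) * w
        n_var = int(counts[ws : we + 1].sum())
        start_pos, end_pos = lo, hi
        if refine_with is not None:
            positions = [r.pos for r in refine_with
                         if r.label is not None
                         and (not profile.class_filter or r.label in profile.class_filter)
                         and lo <= r.pos < hi]
            if positions:
                start_pos = min(positions)
                end_pos = max(positions) + 1
        calls.append(IntrogressionCall(
            ref_name=profile.ref_name, start=start_pos, end=end_pos,
            window_start=ws, window_end=we,
            supporting_class=profile.class_filter, n_variants=n_var,
        ))
    calls.sort(key=lambda c: c.start)
    return calls


# ---------------------------------------------------------------------
# line-unique SVs
# ---------------------------------------------------------------------

def unique_svs(
    sv_rows: Sequence[MatrixRow],
    interval: tuple[int, int],
    reference_role: str = "wild",
    sv_min_length: int = SV_MIN_LENGTH,
) -> dict[str, list[MatrixRow]]:
    """SVs inside ``interval`` split into the long-line-unique class
    ((1,0,0)) and the short+none-shared class ((0,1,1)), each sorted by
    position.  Rows with undefined flags are excluded."""
    lo, hi = interval
    out: dict[str, list[MatrixRow]] = {"long_unique": [], "short_none_shared": []}
    for row in sv_rows:
        if not row.is_sv(sv_min_length) or not row.fully_defined:
            continue
        if not (lo <= row.pos < hi):
            continue
        label = classify_differential(row.triple, reference_role)
        if label == "long_unique":
            out["long_unique"].append(row)
        elif label in ("diagnostic_wild", "short_none_shared_vs_long"):
            out["short_none_shared"].append(row)
    for v in out.values():
        v.sort(key=lambda r: r.pos)
    return out


# ---------------------------------------------------------------------
# gap spanning
# ---------------------------------------------------------------------

@dataclass
class GapSpan:
    gap: GapRecord
    spanned: bool
    contig: str | None = None


@dataclass
class GapSpanReport:
    spans: list[GapSpan]

    @property
    def spanned(self) -> list[GapSpan]:
        return [s for s in self.spans if s.spanned]

    @property
    def unspanned(self) -> list[GapSpan]:
        return [s for s in self.spans if not s.spanned]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tlength\tspanned\tcontig\n")
            for s in self.spans:
                fh.write(f"{s.gap.chrom}\t{s.gap.start}\t{s.gap.end}\t"
                         f"{s.gap.length}\t{int(s.spanned)}\t{s.contig or '.'}\n")


def _project_ref_to_ctg(block: AlignmentBlock, ref_lo: int, ref_hi: int):
    """Oriented-contig interval aligned against a reference interval
    inside the block, via a cigar walk; None when the block has no cigar."""
    if not block.cigar:
        return None
    r = block.ref_start
    q = 0  # oriented offset from block start
    q_lo = q_hi = None
    for op, ln in block.cigar:
        consumes_r = op in ("=", "X", "D", "M")
        consumes_q = op in ("=", "X", "I", "M")
        r2 = r + ln if consumes_r else r
        if q_lo is None and consumes_r and r2 > ref_lo:
            q_lo = q + (max(ref_lo - r, 0) if consumes_q else 0)
        if q_lo is None and not consumes_r and r >= ref_lo:
            q_lo = q
        if consumes_r and r2 >= ref_hi:
            q_hi = q + (max(ref_hi - r, 0) if consumes_q else 0)
            break
        r = r2
        if consumes_q:
            q += ln
    if q_lo is None or q_hi is None:
        return None
    return (q_lo, q_hi)


def gap_overlap(
    gaps: Sequence[GapRecord],
    blocks: Sequence[AlignmentBlock],
    min_contig_length: int = 1_000_000,
    ctg_seqs: dict | None = None,
    partial: bool = False,
) -> GapSpanReport:
    """Which reference N-gaps are spanned by unambiguous contig sequence.

    A gap counts as spanned when a single block (i) comes from a contig
    longer than ``min_contig_length``, (ii) fully contains the gap
    interval on the reference (any overlap when ``partial``), and (iii)
    the contig subsequence aligned across the gap contains no N (checked
    when ``ctg_seqs`` provides the contig sequences).
    """
    from .align import revcomp

    spans: list[GapSpan] = []
    for g in sorted(gaps, key=lambda g: g.start):
        hit = None
        for b in blocks:
            if b.ctg_len <= min_contig_length:
                continue
            if partial:
                ok = b.ref_start < g.end and g.start < b.ref_end
            else:
                ok = b.ref_start <= g.start and g.end <= b.ref_end
            if not ok:
                continue
            if ctg_seqs is not None and b.ctg_name in ctg_seqs:
                proj = _project_ref_to_ctg(b, max(g.start, b.ref_start),
                                           min(g.end, b.ref_end))
                if proj is None:
                    continue
                seq = ctg_seqs[b.ctg_name].sequence
                if b.strand == "-":
                    seq = revcomp(seq)
                off = (b.ctg_start if b.strand == "+"
                       else len(seq) - b.ctg_end)
                sub = seq[off + proj[0] : off + proj[1]]
                if "N" in sub:
                    continue
            hit = b.ctg_name
            break
        spans.append(GapSpan(gap=g, spanned=hit is not None, contig=hit))
    return GapSpanReport(spans=spans)
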