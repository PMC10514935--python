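"""Synthetic NIL-trio generator with machine-readable truth.

Emulates the study design behind the pipeline: a domesticated reference,
a diverged wild-species reference (SNPs, small indels, structural
variants, and assembly N-gaps), and three near-isogenic lines (NILs)
that share the domesticated background except for a wild introgression —
long (multi-Mbp), short (two orders of magnitude smaller, nested inside
the long one), or none.  Each NIL genome is then fragmented into contigs
so that every downstream stage (gap catalog, alignment, variant
discovery, boundary inference) can be verified against planted truth.

Coordinate conventions
----------------------
All intervals are 0-based half-open.  Divergence events are sampled in
domesticated coordinates and recorded in both coordinate systems once
the wild reference is built.  Reference N-gaps are modelled as *inserted*
N-runs in the wild reference — placeholders for sequence missing from
its coordinate system — and are excised from the introgressed segments
the NILs carry.  A long-line contig crossing such a gap therefore aligns
across it with unambiguous sequence, the phenomenon the gap-spanning
analysis measures; and the wild reference's non-N base count stays equal
to the domesticated length plus the net planted indel/SV length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .seqio import SeqRecord, write_fasta

__all__ = [
    "SimConfig",
    "PlantedVariant",
    "TruthSet",
    "simulate_references",
    "simulate_trio",
    "fragment_into_contigs",
    "simulate_all",
    "apply_edits",
]

LINES = ("long", "short", "none")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_PLACEMENT_TRIES = 200


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic trio.

    Defaults are the desk-scale mirror of the study: a 5-Mbp chromosome
    carrying a 3.5-Mbp long introgression with a 150-kbp short
    introgression nested near its distal end, 3% SNP divergence between
    the references, and contigs fragmented to a ~1.2-Mbp N50 so that
    contigs larger than the gap-spanning size cutoff exist.
    """

    seed: int = 0
    chrom_length: int = 5_000_000
    chrom_name: str = "chr7"
    divergence_snp_rate: float = 0.03
    divergence_indel_rate: float = 0.002
    indel_length_range: tuple[int, int] = (1, 10)
    sv_count: int = 25
    sv_length_range: tuple[int, int] = (50, 2000)
    gap_count: int = 40
    gap_length_range: tuple[int, int] = (50, 3000)
    introgression_long: tuple[int, int] = (750_000, 4_250_000)
    introgression_short: tuple[int, int] = (3_900_000, 4_050_000)
    contig_n50_target: int = 1_200_000
    contig_gap_rate: float = 5e-7
    contig_gap_length_range: tuple[int, int] = (50, 200)
    line_unique_sv_count: int = 12
    line_unique_sv_spacing: int = 500

    def __post_init__(self) -> None:
        self.introgression_long = tuple(self.introgression_long)  # type: ignore[assignment]
        self.introgression_short = tuple(self.introgression_short)  # type: ignore[assignment]
        for name in ("indel_length_range", "sv_length_range", "gap_length_range",
                     "contig_gap_length_range"):
            setattr(self, name, tuple(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        for name in ("divergence_snp_rate", "divergence_indel_rate", "contig_gap_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name}={r} outside [0, 1]")
        for name in ("sv_length_range", "gap_length_range", "indel_length_range",
                     "contig_gap_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}={(lo, hi)} is not a valid positive range")
        a, b = self.introgression_long
        s0, s1 = self.introgression_short
        if not (0 <= a < b <= self.chrom_length):
            raise ValueError(
                f"introgression_long {self.introgression_long} outside "
                f"[0, {self.chrom_length})"
            )
        if not (a <= s0 < s1 <= b):
            raise ValueError(
                "introgression_short must nest inside introgression_long"
            )
        if self.contig_n50_target <= 0:
            raise ValueError("contig_n50_target must be positive")
        if self.sv_count < 0 or self.gap_count < 0 or self.line_unique_sv_count < 0:
            raise ValueError("event counts must be non-negative")

    # -- flat key-value config file ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PlantedVariant:
    """A planted divergence event between the two references.

    ``ref_allele``/``alt_allele`` are domesticated/wild alleles; empty
    string denotes absence (pure insertion/deletion).  ``dom_pos`` and
    ``wild_pos`` are the event start in each coordinate system.
    """

    kind: str  # SNP | INS | DEL
    dom_pos: int
    wild_pos: int
    ref_allele: str
    alt_allele: str
    is_gap: bool = False  # inserted reference N-run, not a biological variant

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele), 1)

    @property
    def dom_interval(self) -> tuple[int, int]:
        return (self.dom_pos, self.dom_pos + len(self.ref_allele))

    @property
    def wild_interval(self) -> tuple[int, int]:
        return (self.wild_pos, self.wild_pos + len(self.alt_allele))


@dataclass
class UniqueSV:
    """An SV planted only in the long line, inside its introgression."""

    kind: str  # INS | DEL
    wild_pos: int
    ref_allele: str  # wild-reference allele
    alt_allele: str  # long-line allele

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))


@dataclass
class TruthSet:
    """Planted truth emitted by the simulator, the oracle for every stage."""

    config: SimConfig
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    planted_gaps: list[tuple[int, int]] = field(default_factory=list)
    # line -> {"dom": (start, end) | None, "wild": (start, end) | None}
    introgression_by_line: dict = field(default_factory=dict)
    unique_svs: list[UniqueSV] = field(default_factory=list)
    # contig name -> (line, genome_start, genome_end)
    contig_provenance: dict = field(default_factory=dict)
    # (line, genome_start, genome_end) N-masked runs inside contigs
    contig_masked: list[tuple[str, int, int]] = field(default_factory=list)

    # -- presence semantics -------------------------------------------
    def line_contains(self, line: str, wild_pos: int) -> bool:
        iv = self.introgression_by_line.get(line, {}).get("wild")
        return iv is not None and iv[0] <= wild_pos < iv[1]

    def flags_vs(self, variant: PlantedVariant, reference_role: str) -> tuple[int, int, int]:
        """Expected presence triple (long, short, none) of a planted
        divergence variant against one reference.

        Against the domesticated reference a line shows the wild allele
        iff its introgression covers the locus; against the wild
        reference the logic inverts (a line differs from wild wherever it
        carries the domesticated background).
        """
        contained = tuple(int(self.line_contains(ln, variant.wild_pos)) for ln in LINES)
        if reference_role == "domesticated":
            return contained  # type: ignore[return-value]
        if reference_role == "wild":
            return tuple(1 - c for c in contained)  # type: ignore[return-value]
        raise ValueError(f"unknown reference_role {reference_role!r}")

    def line_edits_vs_dom(self, line: str, dom: "SeqRecord") -> list[tuple[int, str, str]]:
        """The full expected edit set of one NIL genome against the
        domesticated reference: divergence edits inside the line's
        introgression (gap insertions are excised from the carried
        segment, hence absent), composed with the long line's unique SVs
        (a unique deletion removes the underlying divergence edits)."""
        iv = self.introgression_by_line.get(line, {}).get("wild")
        if iv is None:
            return []
        div = [(v.dom_pos, v.ref_allele, v.alt_allele)
               for v in self.planted_variants
               if iv[0] <= v.wild_pos < iv[1]]
        if line != "long" or not self.unique_svs:
            return sorted(div)
        wild_ends, dom_ends = _wild_to_dom_map(self)
        extra = []
        drop: list[tuple[int, int]] = []
        for u in self.unique_svs:
            d1 = _map_wild_to_dom(u.wild_pos, wild_ends, dom_ends)
            if u.kind == "DEL":
                d2 = _map_wild_to_dom(u.wild_pos + len(u.ref_allele),
                                      wild_ends, dom_ends)
                extra.append((d1, dom.sequence[d1:d2], ""))
                drop.append((d1, d2))
            else:
                extra.append((d1, "", u.alt_allele))
        div = [e for e in div
               if not any(s <= e[0] < t for s, t in drop)]
        return sorted(div + extra)

    def dom_to_wild_edits(self) -> list[tuple[int, str, str]]:
        """All planted edits (variants + gap insertions) in domesticated
        coordinates; applying them to the domesticated sequence rebuilds
        the wild reference exactly."""
        edits = [(v.dom_pos, v.ref_allele, v.alt_allele) for v in self.planted_variants]
        edits += [(g[2], "", "N" * (g[1] - g[0])) for g in self._gap_edits]
        return sorted(edits, key=lambda e: (e[0], len(e[1])))

    _gap_edits: list[tuple[int, int, int]] = field(default_factory=list)  # (wild_start, wild_end, dom_pos)

    # -- serialisation -------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chrom = self.config.chrom_name
        with open(outdir / "truth_introgressions.bed", "w") as fh:
            for line in LINES:
                for role in ("dom", "wild"):
                    iv = self.introgression_by_line.get(line, {}).get(role)
                    if iv is not None:
                        fh.write(f"{chrom}\t{iv[0]}\t{iv[1]}\t{line}:{role}\n")
        with open(outdir / "truth_gaps.bed", "w") as fh:
            for s, e in self.planted_gaps:
                fh.write(f"{chrom}\t{s}\t{e}\tgap_len={e - s}\n")
        with open(outdir / "truth_variants.tsv", "w") as fh:
            fh.write("kind\tdom_pos\twild_pos\tlength\tref_allele\talt_allele\n")
            for v in self.planted_variants:
                fh.write(
                    f"{v.kind}\t{v.dom_pos}\t{v.wild_pos}\t{v.length}\t"
                    f"{v.ref_allele or '-'}\t{v.alt_allele or '-'}\n"
                )
        with open(outdir / "truth_unique_svs.tsv", "w") as fh:
            fh.write("kind\twild_pos\tlength\n")
            for sv in self.unique_svs:
                fh.write(f"{sv.kind}\t{sv.wild_pos}\t{sv.length}\n")
        with open(outdir / "truth_contigs.tsv", "w") as fh:
            fh.write("contig\tline\tgenome_start\tgenome_end\n")
            for name, (line, s, e) in self.contig_provenance.items():
                fh.write(f"{name}\t{line}\t{s}\t{e}\n")


# ---------------------------------------------------------------------
# sequence / edit primitives
# ---------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def apply_edits(seq: str, edits: list[tuple[int, str, str]]) -> tuple[str, list[int]]:
    """Apply (pos, ref, alt) edits (0-based, sorted, non-overlapping) to
    ``seq``; returns the edited string and each edit's start position in
    the edited coordinate system."""
    pieces: list[str] = []
    out_positions: list[int] = []
    cur = 0
    out_len = 0
    for pos, ref, alt in edits:
        if pos < cur:
            raise ValueError(f"overlapping edits at position {pos}")
        if seq[pos : pos + len(ref)] != ref:
            raise ValueError(f"edit ref allele mismatch at position {pos}")
        pieces.append(seq[cur:pos])
        out_len += pos - cur
        out_positions.append(out_len)
        pieces.append(alt)
        out_len += len(alt)
        cur = pos + len(ref)
    pieces.append(seq[cur:])
    return "".join(pieces), out_positions


class _Placer:
    """Rejection-sampled non-overlapping placement on a chromosome."""

    def __init__(self, rng: np.random.Generator, length: int, pad: int = 1):
        self.rng = rng
        self.occupied = np.zeros(length + 1, dtype=bool)
        self.length = length
        self.pad = pad

    def place(self, span: int, kind: str) -> int:
        hi = self.length - span
        if hi <= 0:
            raise ValueError(f"{kind} event of span {span} does not fit the chromosome")
        for _ in range(_MAX_PLACEMENT_TRIES):
            p = int(self.rng.integers(0, hi))
            lo = max(0, p - self.pad)
            if not self.occupied[lo : p + span + self.pad].any():
                self.occupied[lo : p + span + self.pad] = True
                return p
        raise ValueError(
            f"could not place {kind} event of span {span} after "
            f"{_MAX_PLACEMENT_TRIES} attempts; region around position {p} is crowded"
        )


# ---------------------------------------------------------------------
# references
# ---------------------------------------------------------------------

def simulate_references(cfg: SimConfig) -> tuple[SeqRecord, SeqRecord, TruthSet]:
    """Build the domesticated reference, the diverged wild reference, and
    the partial truth set recording every planted event in both
    coordinate systems."""
    rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.chrom_length
    dom_seq = _random_seq(rng, L)
    dom_arr = np.frombuffer(dom_seq.encode(), dtype=np.uint8)

    placer = _Placer(rng, L)
    events: list[tuple[int, str, str, str, bool]] = []  # (pos, ref, alt, kind, is_gap)

    # structural variants: deletions remove dom sequence, insertions add novel sequence
    for _ in range(cfg.sv_count):
        span = int(rng.integers(cfg.sv_length_range[0], cfg.sv_length_range[1] + 1))
        if rng.random() < 0.5:
            p = placer.place(span, "SV deletion")
            events.append((p, dom_seq[p : p + span], "", "DEL", False))
        else:
            p = placer.place(1, "SV insertion")
            events.append((p, "", _random_seq(rng, span), "INS", False))

    # reference N-gaps: inserted runs of N in the wild assembly
    for _ in range(cfg.gap_count):
        span = int(rng.integers(cfg.gap_length_range[0], cfg.gap_length_range[1] + 1))
        p = placer.place(1, "reference gap")
        events.append((p, "", "N" * span, "INS", True))

    # small indels
    n_indel = int(rng.binomial(L, cfg.divergence_indel_rate))
    for _ in range(n_indel):
        span = int(rng.integers(cfg.indel_length_range[0], cfg.indel_length_range[1] + 1))
        if rng.random() < 0.5:
            p = placer.place(span, "deletion")
            events.append((p, dom_seq[p : p + span], "", "DEL", False))
        else:
            p = placer.place(1, "insertion")
            events.append((p, "", _random_seq(rng, span), "INS", False))

    # SNPs: batch-sampled, then filtered against occupied positions
    n_snp = int(rng.binomial(L, cfg.divergence_snp_rate))
    if n_snp:
        pos = rng.choice(L, size=n_snp, replace=False)
        pos = pos[~placer.occupied[pos]]
        pos.sort()
        base_idx = np.searchsorted(_BASES, dom_arr[pos])
        alt_idx = (base_idx + rng.integers(1, 4, size=pos.size)) % 4
        alts = _BASES[alt_idx]
        for p, b_ref, b_alt in zip(pos.tolist(), dom_arr[pos].tolist(), alts.tolist()):
            events.append((p, chr(b_ref), chr(b_alt), "SNP", False))

    events.sort(key=lambda e: e[0])
    edits = [(p, r, a) for p, r, a, _, _ in events]
    wild_seq, wild_positions = apply_edits(dom_seq, edits)

    truth = TruthSet(config=cfg)
    for (p, r, a, kind, is_gap), w in zip(events, wild_positions):
        if is_gap:
            truth.planted_gaps.append((w, w + len(a)))
            truth._gap_edits.append((w, w + len(a), p))
        else:
            truth.planted_variants.append(
                PlantedVariant(kind=kind, dom_pos=p, wild_pos=w,
                               ref_allele=r, alt_allele=a)
            )
    truth.planted_gaps.sort()
    truth._gap_edits.sort()

    dom = SeqRecord(cfg.chrom_name, dom_seq)
    wild = SeqRecord(cfg.chrom_name, wild_seq)
    return dom, wild, truth


# ---------------------------------------------------------------------
# coordinate maps and boundary snapping
# ---------------------------------------------------------------------

def _footprints(truth: TruthSet):
    """Non-degenerate edit footprints in each coordinate system, as sorted
    (starts, ends) array pairs."""
    wild_fp = []
    dom_fp = []
    for v in truth.planted_variants:
        if v.wild_interval[1] > v.wild_interval[0]:
            wild_fp.append(v.wild_interval)
        if v.dom_interval[1] > v.dom_interval[0]:
            dom_fp.append(v.dom_interval)
    wild_fp.extend((s, e) for s, e, _ in truth._gap_edits)
    wild_fp.sort()
    dom_fp.sort()

    def arrays(fp):
        if not fp:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        a = np.asarray(fp, dtype=np.int64)
        return a[:, 0], a[:, 1]

    return arrays(wild_fp), arrays(dom_fp)


def _wild_to_dom_map(truth: TruthSet):
    """Checkpoint arrays mapping wild -> dom coordinates outside edits."""
    wild_ends = [0]
    dom_ends = [0]
    w = 0
    d = 0
    for pos, ref, alt in truth.dom_to_wild_edits():
        w += pos - d + len(alt)
        d = pos + len(ref)
        wild_ends.append(w)
        dom_ends.append(d)
    return np.asarray(wild_ends), np.asarray(dom_ends)


def _map_wild_to_dom(wild_pos: int, wild_ends: np.ndarray, dom_ends: np.ndarray) -> int:
    i = int(np.searchsorted(wild_ends, wild_pos, side="right")) - 1
    return int(dom_ends[i] + (wild_pos - wild_ends[i]))


def _inside(pos: int, starts: np.ndarray, ends: np.ndarray) -> int | None:
    """Return the end of the footprint strictly containing ``pos``, else None."""
    if starts.size == 0:
        return None
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i >= 0 and starts[i] < pos < ends[i]:
        return int(ends[i])
    return None


def _snap_boundary(b: int, wild_fp, dom_fp, wild_ends, dom_ends, wild_len: int) -> int:
    """Move a wild-coordinate boundary right until it sits strictly inside
    no edit footprint in either coordinate system."""
    wild_starts_a, wild_ends_a = wild_fp
    dom_starts_a, dom_ends_a = dom_fp
    for _ in range(1000):
        e = _inside(b, wild_starts_a, wild_ends_a)
        if e is not None:
            b = e
            continue
        d = _map_wild_to_dom(b, wild_ends, dom_ends)
        e = _inside(d, dom_starts_a, dom_ends_a)
        if e is not None:
            # advance past the deletion: its wild image is a single point
            i = int(np.searchsorted(dom_ends, e, side="left"))
            b = int(wild_ends[i])
            continue
        return min(b, wild_len)
    raise ValueError(f"boundary snapping did not converge near wild position {b}")


# ---------------------------------------------------------------------
# trio construction
# ---------------------------------------------------------------------

def _excise_gaps(wild_seq: str, interval: tuple[int, int], gaps) -> str:
    """Wild segment with reference N-gap insertions removed."""
    a, b = interval
    pieces = []
    cur = a
    for s, e in gaps:
        if e <= a or s >= b:
            continue
        if s < a or e > b:
            raise ValueError("reference gap straddles an introgression boundary")
        pieces.append(wild_seq[cur:s])
        cur = e
    pieces.append(wild_seq[cur:b])
    return "".join(pieces)


def simulate_trio(
    dom: SeqRecord,
    wild: SeqRecord,
    cfg: SimConfig,
    truth: TruthSet,
) -> tuple[dict[str, SeqRecord], TruthSet]:
    """Construct the three NIL genomes and finalize the truth set.

    The none line equals the domesticated reference; the long and short
    lines substitute the wild segment over their respective realized
    introgression intervals (reference N-gap insertions excised).
    Line-unique SVs are additionally planted inside the long line's
    introgression, spaced by at least ``line_unique_sv_spacing``.
    """
    wild_fp, dom_fp = _footprints(truth)
    wild_ends, dom_ends = _wild_to_dom_map(truth)
    wild_len = len(wild.sequence)

    realized: dict[str, tuple[int, int] | None] = {}
    intervals = {"long": cfg.introgression_long, "short": cfg.introgression_short}
    snapped: dict[str, tuple[int, int, int, int]] = {}
    for line, (a, b) in intervals.items():
        if b > wild_len:
            raise ValueError(
                f"introgression_{line} {(a, b)} exceeds the wild chromosome ({wild_len} bp)"
            )
        a2 = _snap_boundary(a, wild_fp, dom_fp, wild_ends, dom_ends, wild_len)
        b2 = _snap_boundary(b, wild_fp, dom_fp, wild_ends, dom_ends, wild_len)
        if not a2 < b2:
            raise ValueError(f"introgression_{line} collapsed after boundary snapping")
        ad = _map_wild_to_dom(a2, wild_ends, dom_ends)
        bd = _map_wild_to_dom(b2, wild_ends, dom_ends)
        snapped[line] = (a2, b2, ad, bd)
    if not (snapped["long"][0] <= snapped["short"][0]
            and snapped["short"][1] <= snapped["long"][1]):
        raise ValueError("introgression_short escaped introgression_long after snapping")

    truth.introgression_by_line = {
        "long": {"wild": snapped["long"][:2], "dom": snapped["long"][2:]},
        "short": {"wild": snapped["short"][:2], "dom": snapped["short"][2:]},
        "none": {"wild": None, "dom": None},
    }

    genomes: dict[str, SeqRecord] = {}
    dom_seq = dom.sequence
    for line in ("long", "short"):
        a, b, ad, bd = snapped[line]
        segment = _excise_gaps(wild.sequence, (a, b), truth.planted_gaps)
        genomes[line] = SeqRecord(f"{line}_genome",
                                  dom_seq[:ad] + segment + dom_seq[bd:])
    genomes["none"] = SeqRecord("none_genome", dom_seq)

    # ---- line-unique SVs inside the long introgression ----------------
    if cfg.line_unique_sv_count:
        genomes["long"] = _plant_unique_svs(genomes["long"], cfg, truth, snapped["long"])

    return genomes, truth


def _plant_unique_svs(long_genome: SeqRecord, cfg: SimConfig, truth: TruthSet,
                      long_iv: tuple[int, int, int, int]) -> SeqRecord:
    rng = np.random.default_rng([cfg.seed, 2])
    a, b, ad, bd = long_iv
    gaps = [g for g in truth.planted_gaps if a <= g[0] and g[1] <= b]
    gap_starts = np.asarray([g[0] for g in gaps] or [0])
    gap_cum = np.concatenate(([0], np.cumsum([g[1] - g[0] for g in gaps])))

    def wild_to_genome(w: int) -> int:
        # genome coord = prefix + offset into segment - excised gap bases before w
        i = int(np.searchsorted(gap_starts, w, side="right")) if gaps else 0
        return ad + (w - a) - int(gap_cum[i])

    # forbidden wild intervals: large divergence events (>= 50 bp, whose
    # breakpoints must stay distinguishable from the planted unique SVs),
    # reference gaps, and boundary margins.  SNPs/small indels may fall
    # inside a unique deletion — as in real data.
    forbidden = []
    for v in truth.planted_variants:
        # conservative wild-coordinate span (DEL footprints are points in
        # wild coordinates; pad by the event length anyway)
        s, e = v.wild_pos, v.wild_pos + v.length
        if v.length >= 50 and not (e <= a or s >= b):
            forbidden.append((s, e))
    forbidden += [g for g in gaps]
    forbidden += [(a, a + 1000), (b - 1000, b)]
    forbidden.sort()

    # breakpoints must not fall strictly inside any divergence edit
    # footprint, so the composite long-genome edit set stays well defined
    # in both coordinate systems
    fp = sorted((s, e) for s, e in
                (v.wild_interval for v in truth.planted_variants) if e > s)
    fp_starts = np.asarray([s for s, _ in fp] or [0], dtype=np.int64)
    fp_ends = np.asarray([e for _, e in fp] or [0], dtype=np.int64)

    def at_breakpoint(x: int) -> bool:
        i = int(np.searchsorted(fp_starts, x, side="right")) - 1
        return i >= 0 and fp_starts[i] < x < fp_ends[i]

    spacing = max(cfg.line_unique_sv_spacing, 2 * 50)
    margin = cfg.sv_length_range[1] + spacing
    placed: list[tuple[int, int, str, int]] = []  # (wild_pos, span, kind, length)
    for _ in range(cfg.line_unique_sv_count):
        length = int(rng.integers(cfg.sv_length_range[0], cfg.sv_length_range[1] + 1))
        kind = "DEL" if rng.random() < 0.5 else "INS"
        span = length if kind == "DEL" else 1
        ok = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            w = int(rng.integers(a + 1000, b - 1000 - span))
            iv = (w - spacing, w + span + spacing)
            if any(not (e <= iv[0] or s >= iv[1]) for s, e in forbidden):
                continue
            if at_breakpoint(w) or at_breakpoint(w + span):
                continue
            if any(not (pw + psp + spacing <= iv[0] or pw - spacing >= iv[1])
                   for pw, psp, _, _ in placed):
                continue
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not place line-unique SV of length {length}; "
                f"introgression interval is crowded"
            )
        placed.append((w, span, kind, length))

    placed.sort()
    edits: list[tuple[int, str, str]] = []
    seq = long_genome.sequence
    for w, span, kind, length in placed:
        g = wild_to_genome(w)
        if kind == "DEL":
            ref_allele = seq[g : g + length]
            truth.unique_svs.append(UniqueSV("DEL", w, ref_allele, ""))
            edits.append((g, ref_allele, ""))
        else:
            alt = _random_seq(rng, length)
            truth.unique_svs.append(UniqueSV("INS", w, "", alt))
            edits.append((g, "", alt))
    new_seq, _ = apply_edits(seq, edits)
    return SeqRecord(long_genome.name, new_seq)


# ---------------------------------------------------------------------
# contig fragmentation
# ---------------------------------------------------------------------

def fragment_into_contigs(
    genome: SeqRecord,
    cfg: SimConfig,
    line: str = "line",
    truth: TruthSet | None = None,
) -> list[SeqRecord]:
    """Partition a NIL genome into contigs with realized N50 within 25%
    of ``contig_n50_target``; optionally mask short N-runs inside contigs
    (assembly gaps) at ``contig_gap_rate`` events/bp."""
    from .seqio import contig_n50

    L = len(genome.sequence)
    target = cfg.contig_n50_target
    if target > L:
        raise ValueError(f"contig_n50_target {target} exceeds genome length {L}")
    line_tag = sum(genome.name.encode()) % 1_000_003
    rng = np.random.default_rng([cfg.seed, 3, line_tag])

    if target == L:
        lengths = [L]
    else:
        lengths = None
        for _attempt in range(20):
            cand: list[int] = []
            total = 0
            while total < L:
                x = int(rng.integers(int(0.75 * target), int(1.25 * target) + 1))
                cand.append(min(x, L - total))
                total += cand[-1]
            n50 = contig_n50(cand)
            if abs(n50 - target) <= 0.25 * target:
                lengths = cand
                break
        if lengths is None:
            raise ValueError(
                f"could not fragment genome to N50 within 25% of {target}"
            )

    contigs: list[SeqRecord] = []
    offset = 0
    for i, ln in enumerate(lengths):
        name = f"{line}_ctg{i:04d}"
        sub = genome.sequence[offset : offset + ln]
        contigs.append(SeqRecord(name, sub))
        if truth is not None:
            truth.contig_provenance[name] = (line, offset, offset + ln)
        offset += ln

    # contig-internal assembly gaps: same-length N masking
    n_ev = int(rng.binomial(L, cfg.contig_gap_rate))
    for _ in range(n_ev):
        glen = int(rng.integers(cfg.contig_gap_length_range[0],
                                cfg.contig_gap_length_range[1] + 1))
        pos = int(rng.integers(0, L - glen))
        # locate the contig, clip to its bounds
        acc = 0
        for ci, ln in enumerate(lengths):
            if pos < acc + ln:
                s_local = pos - acc
                e_local = min(s_local + glen, ln)
                c = contigs[ci]
                contigs[ci] = SeqRecord(
                    c.name,
                    c.sequence[:s_local] + "N" * (e_local - s_local) + c.sequence[e_local:],
                )
                if truth is not None:
                    truth.contig_masked.append((line, acc + s_local, acc + e_local))
                break
            acc += ln
    return contigs


# ---------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write FASTA/BED/TSV artifacts.

    Returns ``(dom, wild, genomes, contigs_by_line, truth)``.
    """
    dom, wild, truth = simulate_references(cfg)
    genomes, truth = simulate_trio(dom, wild, cfg, truth)
    contigs = {line: fragment_into_contigs(genomes[line], cfg, line, truth)
               for line in LINES}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([dom], outdir / "reference_dom.fasta")
        write_fasta([wild], outdir / "reference_wild.fasta")
        for line in LINES:
            write_fasta([genomes[line]], outdir / f"genome_{line}.fasta")
            write_fasta(contigs[line], outdir / f"contigs_{line}.fasta")
        truth.write(outdir / "truth")
        cfg.to_yaml(outdir / "sim_config.yaml")
    return dom, wild, genomes, contigs, truth
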