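"""Sequence resources: FASTA I/O, N-gap cataloging, contig statistics.

Assemblies of the tomato lines and both reference genomes enter the
pipeline as plain FASTA.  Sequences are restricted to the alphabet
{A, C, G, T, N}: only ``N`` is treated as an ambiguous (gap) character;
other IUPAC ambiguity codes are rejected on input rather than silently
treated as gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset(b"ACGTN")

__all__ = [
    "SeqRecord",
    "GapRecord",
    "read_fasta",
    "write_fasta",
    "find_gaps",
    "contig_n50",
    "write_gaps_bed",
]


@dataclass
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, upper-cased."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.name!r} is empty")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def array(self) -> np.ndarray:
        """Sequence as a uint8 byte array (view-friendly for vector scans)."""
        return np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class GapRecord:
    """A maximal run of Ns on a reference sequence (0-based half-open)."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _validate_sequence(name: str, seq: str) -> None:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.zeros(256, dtype=bool)
    valid[list(b"ACGTN")] = True
    bad = ~valid[arr]
    if bad.any():
        off = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"record {name!r}: non-IUPAC/unsupported character "
            f"{seq[off]!r} at offset {off}"
        )


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into upper-cased records.

    Raises on duplicate record names and on characters outside
    {A,C,G,T,N} (case-insensitive), reporting the offending offset.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _validate_sequence(rec.id, seq)
        records.append(SeqRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 80) -> None:
    """Write records as FASTA with lines wrapped at ``wrap`` columns."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            s = rec.sequence
            for i in range(0, len(s), wrap):
                fh.write(s[i : i + wrap])
                fh.write("\n")


def read_fasta_dict(path: str | Path) -> dict[str, SeqRecord]:
    return {r.name: r for r in read_fasta(path)}


def find_gaps(
    seq: SeqRecord,
    min_length: int = 50,
    region: tuple[int, int] | None = None,
) -> list[GapRecord]:
    """Catalog maximal N-runs of length >= ``min_length``.

    ``region`` is a 0-based half-open interval; a run is reported when it
    *intersects* the region at all, but its coordinates are never truncated
    to the region, so true gap lengths are preserved for downstream length
    distributions.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    n = len(seq)
    if region is not None:
        lo, hi = region
        if not (0 <= lo <= hi <= n):
            raise ValueError(f"region {region} out of bounds for {seq.name} (len {n})")
    is_n = seq.array == ord("N")
    if not is_n.any():
        return []
    # run boundaries via diff of the padded indicator
    padded = np.concatenate(([False], is_n, [False]))
    delta = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(delta == 1)
    ends = np.flatnonzero(delta == -1)
    gaps = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if e - s < min_length:
            continue
        if region is not None and (e <= region[0] or s >= region[1]):
            continue
        gaps.append(GapRecord(seq.name, s, e))
    return gaps


def contig_n50(lengths: Sequence[int]) -> int:
    """N50: largest L such that contigs of length >= L sum to >= half the total."""
    if len(lengths) == 0:
        raise ValueError("contig_n50 requires a non-empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, half))
    return int(arr[idx])


def write_gaps_bed(gaps: Iterable[GapRecord], path: str | Path) -> None:
    """Write a gap catalog as BED3+1 (name column carries the length)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\tgap_len={g.length}\n")
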