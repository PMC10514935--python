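"""End-to-end trio analysis and file-based pipeline orchestration.

``analyze_trio`` is the in-memory engine: it aligns every line's contigs
to both references, derives variants, builds coverage-aware presence
matrices, classifies differential variants, infers introgression
boundaries per reference, identifies line-unique SVs inside the long
introgression, and runs the gap-spanning analysis.  ``run_pipeline``
wraps it with file I/O, a JSON manifest, and optional figures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import align as al
from . import introgression as intro
from . import variants as var
from .seqio import GapRecord, SeqRecord, find_gaps, read_fasta, write_gaps_bed

logger = logging.getLogger(__name__)

LINES = ("long", "short", "none")
ROLES = ("domesticated", "wild")

__all__ = ["PipelineParams", "PipelineConfig", "AnalysisResult",
           "analyze_trio", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    """Every analysis threshold, config-exposed."""

    min_gap_length: int = 50
    k: int = al.DEFAULT_K
    w: int = al.DEFAULT_W
    max_gap: int = al.DEFAULT_MAX_GAP
    min_chain_anchors: int = al.DEFAULT_MIN_CHAIN_ANCHORS
    band: int = al.DEFAULT_BAND
    max_occurrences: int = al.DEFAULT_MAX_OCCURRENCES
    sv_min_length: int = var.SV_MIN_LENGTH
    pos_tol: int = var.POS_TOL
    min_reciprocal_overlap: float = var.MIN_RECIPROCAL_OVERLAP
    window_size: int = intro.WINDOW_SIZE
    min_count: int | None = None  # None -> adaptive background threshold
    max_gap_windows: int = intro.MAX_GAP_WINDOWS
    min_contig_length: int = 1_000_000
    dotplot_bin: int = 100_000
    snps_only: bool = False
    partial_gap_overlap: bool = False


@dataclass
class PipelineConfig:
    """Paths + thresholds + toggles for a file-based run."""

    reference_dom: str
    reference_wild: str
    contigs: dict  # line -> FASTA path
    outdir: str
    seed: int = 0
    plots: bool = False
    paf_dir: str | None = None  # substitute an external aligner's PAF files
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        pfields = {f.name for f in dataclasses.fields(PipelineParams)}
        pkw = {k: v for k, v in d.items() if k in pfields}
        ckw = {k: v for k, v in d.items() if k not in pfields}
        unknown = set(ckw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        ckw["params"] = PipelineParams(**pkw)
        return cls(**ckw)

    def to_flat_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "params"}
        d.update(dataclasses.asdict(self.params))
        return d

    def validate(self) -> None:
        for label, p in [("reference_dom", self.reference_dom),
                         ("reference_wild", self.reference_wild)]:
            if not Path(p).exists():
                raise PipelineError("config", f"{label} path not found: {p}")
        for line in LINES:
            if line not in self.contigs:
                raise PipelineError("config", f"missing contig set for line {line!r}")
            if not Path(self.contigs[line]).exists():
                raise PipelineError(
                    "config", f"contig FASTA for line {line!r} not found: "
                    f"{self.contigs[line]}")
        p = self.params
        for name in ("min_gap_length", "k", "w", "max_gap", "min_chain_anchors",
                     "band", "sv_min_length", "pos_tol", "window_size",
                     "max_gap_windows", "min_contig_length", "dotplot_bin"):
            if getattr(p, name) < 0:
                raise PipelineError("config", f"threshold {name} must be non-negative")


# ---------------------------------------------------------------------
# in-memory engine
# ---------------------------------------------------------------------

# density class filters per reference role: which differential classes
# trace the long introgression, and which trace the short one
LONG_CLASSES = {
    "domesticated": ("long_unique", "diagnostic_dom"),
    "wild": ("diagnostic_wild",),
}
SHORT_CLASSES = {"domesticated": ("diagnostic_dom",)}


@dataclass
class AnalysisResult:
    refs: dict
    gaps: dict
    chains: dict
    blocks: dict
    coverage: dict
    small_calls: dict
    sv_calls: dict
    small_matrix: dict
    sv_matrix: dict
    profiles: dict
    introgression_calls: dict
    unique_interval: tuple | None
    unique_sv_report: dict
    gap_report: intro.GapSpanReport | None

    def primary_call(self, key: str):
        """Highest-support call of one profile (e.g. 'wild_long')."""
        calls = self.introgression_calls.get(key, [])
        return max(calls, key=lambda c: c.n_variants) if calls else None


def analyze_trio(
    dom: SeqRecord,
    wild: SeqRecord,
    contigs_by_line: Mapping[str, Sequence[SeqRecord]],
    params: PipelineParams | None = None,
    precomputed_blocks: Mapping[tuple[str, str], Sequence[al.AlignmentBlock]] | None = None,
) -> AnalysisResult:
    """Run the full comparative analysis on in-memory sequences.

    ``precomputed_blocks`` maps (role, line) to alignment blocks (e.g.
    imported from an external aligner's PAF, with edits attached) and
    replaces the internal aligner for those pairs.
    """
    p = params or PipelineParams()
    refs = {"domesticated": dom, "wild": wild}

    gaps = {role: find_gaps(refs[role], p.min_gap_length) for role in ROLES}

    chains: dict = {}
    blocks: dict = {}
    coverage: dict = {}
    small_calls: dict = {}
    sv_calls: dict = {}
    for role in ROLES:
        ref = refs[role]
        index = None
        chains[role] = {}
        blocks[role] = {}
        coverage[role] = {}
        small_calls[role] = {}
        sv_calls[role] = {}
        for line in LINES:
            if precomputed_blocks is not None and (role, line) in precomputed_blocks:
                ch: list = []
                bl = list(precomputed_blocks[(role, line)])
            else:
                if index is None:
                    index = al.build_minimizer_index(ref, p.k, p.w,
                                                     p.max_occurrences)
                ch, bl = al.align_contigs(
                    ref, contigs_by_line[line], k=p.k, w=p.w, max_gap=p.max_gap,
                    min_chain_anchors=p.min_chain_anchors, band=p.band,
                    max_occurrences=p.max_occurrences, index=index)
            chains[role][line] = ch
            blocks[role][line] = bl
            coverage[role][line] = var.coverage_intervals(bl)
            small_calls[role][line] = var.call_small_variants(
                bl, p.sv_min_length, line=line)
            sv_calls[role][line] = var.call_svs(
                ch, bl, p.sv_min_length, line=line, ref=ref,
                ctg_gap_tol=p.pos_tol)

    small_matrix: dict = {}
    sv_matrix: dict = {}
    profiles: dict = {}
    introgression_calls: dict = {}
    for role in ROLES:
        calls = small_calls[role]
        if p.snps_only:
            calls = {ln: [v for v in vs if v.kind == "SNP"]
                     for ln, vs in calls.items()}
        small_matrix[role] = var.build_presence_matrix(
            calls, coverage[role], p.pos_tol, p.min_reciprocal_overlap)
        sv_matrix[role] = var.build_presence_matrix(
            sv_calls[role], coverage[role], p.pos_tol, p.min_reciprocal_overlap)
        labeled = intro.classify_matrix(small_matrix[role], role)
        intro.classify_matrix(sv_matrix[role], role)

        ref_len = len(refs[role].sequence)
        tag = "dom" if role == "domesticated" else "wild"
        for scope, class_map in (("long", LONG_CLASSES), ("short", SHORT_CLASSES)):
            if role not in class_map:
                continue
            prof = intro.window_density(
                labeled, ref_len, p.window_size, class_map[role],
                ref_name=refs[role].name)
            key = f"{tag}_{scope}"
            profiles[key] = prof
            introgression_calls[key] = intro.infer_boundaries(
                prof, p.min_count, p.max_gap_windows, refine_with=labeled)

    # the short call must be nested in (and is otherwise shadowed by) the
    # long call on the domesticated reference; keep nested candidates only
    long_dom = introgression_calls.get("dom_long", [])
    if long_dom:
        spans = [c.interval for c in long_dom]
        introgression_calls["dom_short"] = [
            c for c in introgression_calls.get("dom_short", [])
            if any(s <= c.start and c.end <= e for s, e in spans)
        ]

    result = AnalysisResult(
        refs=refs, gaps=gaps, chains=chains, blocks=blocks, coverage=coverage,
        small_calls=small_calls, sv_calls=sv_calls,
        small_matrix=small_matrix, sv_matrix=sv_matrix,
        profiles=profiles, introgression_calls=introgression_calls,
        unique_interval=None, unique_sv_report={}, gap_report=None,
    )

    # line-unique SVs within the long introgression on the wild reference
    wild_call = result.primary_call("wild_long")
    if wild_call is not None:
        result.unique_interval = wild_call.interval
        result.unique_sv_report = intro.unique_svs(
            sv_matrix["wild"].rows, wild_call.interval, "wild", p.sv_min_length)

    # gap spanning: wild-reference gaps vs the long line's contigs
    result.gap_report = intro.gap_overlap(
        gaps["wild"], blocks["wild"]["long"], p.min_contig_length,
        ctg_seqs={c.name: c for c in contigs_by_line["long"]},
        partial=p.partial_gap_overlap)
    return result


# ---------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                n += 1
    return n


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts + manifest, return the manifest.

    Stages: gap catalog -> alignment -> variant discovery -> presence
    matrix -> inference -> reports.  Reruns with identical config and
    inputs are byte-identical for non-plot outputs.
    """
    t0 = time.time()
    config.validate()
    p = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "parameters": config.to_flat_dict(),
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(outdir))] = {
            "stage": stage, "rows": _count_rows(path),
        }

    try:
        dom = read_fasta(config.reference_dom)[0]
        wild = read_fasta(config.reference_wild)[0]
        contigs = {line: read_fasta(config.contigs[line]) for line in LINES}
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    for key in ("reference_dom", "reference_wild"):
        manifest["inputs"][key] = _sha256(getattr(config, key))
    for line in LINES:
        manifest["inputs"][f"contigs_{line}"] = _sha256(config.contigs[line])

    precomputed = None
    if config.paf_dir:
        stage = "import_paf"
        try:
            precomputed = {}
            refs = {"domesticated": dom, "wild": wild}
            for role in ROLES:
                tag = "dom" if role == "domesticated" else "wild"
                for line in LINES:
                    paf = Path(config.paf_dir) / f"align_{line}_vs_{tag}.paf"
                    if not paf.exists():
                        continue
                    bl = al.import_paf(paf)
                    ctg_map = {c.name: c for c in contigs[line]}
                    for b in bl:
                        if b.cigar:
                            al.attach_edits(b, refs[role], ctg_map[b.ctg_name])
                    precomputed[(role, line)] = bl
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"].append(stage)

    stage = "analyze"
    try:
        result = analyze_trio(dom, wild, contigs, p, precomputed_blocks=precomputed)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    stage = "write"
    try:
        for role in ROLES:
            tag = "dom" if role == "domesticated" else "wild"
            path = outdir / f"gaps_{tag}.bed"
            write_gaps_bed(result.gaps[role], path)
            record("gaps", path)
            for line in LINES:
                path = outdir / f"align_{line}_vs_{tag}.paf"
                al.export_paf(result.blocks[role][line], path)
                record("align", path)
                path = outdir / f"variants_{line}_vs_{tag}.vcf"
                var.write_vcf(result.small_calls[role][line]
                              + result.sv_calls[role][line],
                              result.refs[role], path, p.sv_min_length)
                record("call", path)
            path = outdir / f"presence_small_{tag}.tsv"
            result.small_matrix[role].to_tsv(path)
            record("matrix", path)
            path = outdir / f"presence_sv_{tag}.tsv"
            result.sv_matrix[role].to_tsv(path)
            record("matrix", path)
            # dot plot data
            all_blocks = [b for line in LINES for b in result.blocks[role][line]]
            path = outdir / f"dotplot_{tag}.tsv"
            with open(path, "w") as fh:
                fh.write("ref\tcontig\tref_bin\tctg_bin\tidentity\n")
                for ref_name, ctg_name, rb, cb, ident in al.dotplot_data(
                        all_blocks, p.dotplot_bin):
                    fh.write(f"{ref_name}\t{ctg_name}\t{rb}\t{cb}\t{ident:.4f}\n")
            record("align", path)

        for key, prof in result.profiles.items():
            path = outdir / f"density_{key}.tsv"
            prof.to_tsv(path)
            record("infer", path)
        path = outdir / "introgression_calls.bed"
        with open(path, "w") as fh:
            for key in sorted(result.introgression_calls):
                for c in result.introgression_calls[key]:
                    fh.write(f"{c.ref_name}\t{c.start}\t{c.end}\t{key}"
                             f"\t{c.n_variants}\n")
        record("infer", path)

        path = outdir / "unique_svs.tsv"
        with open(path, "w") as fh:
            fh.write("class\tref\tpos\ttype\tlength\n")
            for label in ("long_unique", "short_none_shared"):
                for row in result.unique_sv_report.get(label, []):
                    fh.write(f"{label}\t{row.ref_name}\t{row.pos}\t{row.kind}"
                             f"\t{row.length}\n")
        record("infer", path)

        if result.gap_report is not None:
            path = outdir / "gap_spanning.tsv"
            result.gap_report.to_tsv(path)
            record("infer", path)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    if config.plots:
        stage = "plots"
        try:
            from . import plots
            for role in ROLES:
                tag = "dom" if role == "domesticated" else "wild"
                all_blocks = [b for line in LINES
                              for b in result.blocks[role][line]]
                plots.plot_dotplot(
                    al.dotplot_data(all_blocks, p.dotplot_bin),
                    outdir / f"dotplot_{tag}.png", bin=p.dotplot_bin)
            plots.plot_density(
                [result.profiles[k] for k in sorted(result.profiles)],
                {k: result.introgression_calls[k]
                 for k in sorted(result.introgression_calls)},
                outdir / "density.png")
            plots.plot_sv_track(result.unique_sv_report, outdir / "sv_track.png")
            if result.gap_report is not None:
                plots.plot_gap_lengths(result.gap_report, outdir / "gap_lengths.png")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"].append(stage)

    manifest["elapsed_sec"] = round(time.time() - t0, 2)
    man_path = outdir / "manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "elapsed_sec"}
    man_path.write_text(json.dumps(stable, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.1fs; outputs in %s",
                manifest["elapsed_sec"], outdir)
    return manifest
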