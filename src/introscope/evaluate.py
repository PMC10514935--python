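"""Benchmarking called variants against a planted truth set.

Variant representation is not unique: an alignment may legitimately
split one planted 4-bp insertion into two nearby insertions, or trade an
indel pair for substitutions, without being wrong.  Following standard
haplotype-aware benchmarking practice, a truth variant counts as
recovered — and a call as correct — when applying the *call set* to the
reference reproduces the same local haplotype as applying the *truth
set*, over a window around the event extended to cover every edit it
touches.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from .seqio import SeqRecord
from .variants import VariantRecord, match_variants

__all__ = ["Edit", "haplotype_eval", "sv_recovery", "EvalResult"]

Edit = tuple[int, str, str]  # (ref_pos, ref_allele, alt_allele)


def _to_edits(calls: Sequence[VariantRecord]) -> list[Edit]:
    edits = []
    for v in calls:
        if v.kind == "SNP":
            edits.append((v.pos, v.ref_allele, v.alt_allele))
        elif v.kind == "DEL":
            edits.append((v.pos, v.ref_allele or "?" * v.length, v.alt_allele))
        else:
            edits.append((v.pos, "", v.alt_allele or "?" * v.length))
    edits.sort()
    # drop edits overlapping a previous one (cannot be applied jointly)
    out: list[Edit] = []
    cur = -1
    for pos, r, a in edits:
        if pos < cur:
            continue
        out.append((pos, r, a))
        cur = pos + len(r)
    return out


def _apply_window(seq: str, edits: list[Edit], lo: int, hi: int) -> str:
    # edits are sorted and the window was expanded not to cut any of them,
    # so a bisected slice contains every edit intersecting [lo, hi)
    i = bisect.bisect_left(edits, (lo, "", ""))
    j = bisect.bisect_left(edits, (hi, "", ""))
    parts = []
    cur = lo
    for pos, r, a in edits[i:j]:
        if pos + len(r) <= lo or pos >= hi or pos < cur:
            continue
        parts.append(seq[cur:pos])
        parts.append(a)
        cur = pos + len(r)
    parts.append(seq[cur:hi])
    return "".join(parts)


def _expand(lo: int, hi: int, edit_sets: list[list[Edit]], pad: int = 25):
    """Grow [lo, hi) until no edit of any set is cut by a boundary and no
    length-changing edit sits within ``pad`` of one.  Two representations
    of the same indel may differ slightly in position; keeping a margin
    stops one set's copy from falling outside the compared window."""
    for _ in range(200):
        changed = False
        for edits in edit_sets:
            i = bisect.bisect_left(edits, (hi + pad, "", ""))
            for pos, r, a in edits[max(0, i - 4) : i + 1]:
                m = pad if len(r) != len(a) else 0
                if pos - m < hi < pos + len(r) + m:
                    hi = pos + len(r) + m
                    changed = True
            i = bisect.bisect_left(edits, (lo, "", ""))
            for pos, r, a in edits[max(0, i - 4) : i + 4]:
                m = pad if len(r) != len(a) else 0
                if pos - m < lo < pos + len(r) + m:
                    lo = pos - m
                    changed = True
        if not changed:
            return lo, hi
    return lo, hi


@dataclass
class EvalResult:
    recall: float
    precision: float
    n_truth: int
    n_truth_hit: int
    n_calls: int
    n_calls_ok: int
    missed: list
    false_calls: list


def haplotype_eval(
    ref: SeqRecord,
    truth_edits: Sequence[Edit],
    calls: Sequence[VariantRecord],
    radius: int = 50,
    covered: Sequence[tuple[int, int]] | None = None,
    exclude: Sequence[tuple[int, int]] | None = None,
) -> EvalResult:
    """Haplotype-window recall/precision of ``calls`` against
    ``truth_edits`` on one reference.

    Truth events whose window is not fully inside a ``covered`` interval
    are excluded from the denominator (assembly dropouts are not call
    errors); windows intersecting ``exclude`` intervals are skipped on
    both sides.
    """
    seq = ref.sequence
    n = len(seq)
    t_edits = sorted(truth_edits)
    c_edits = _to_edits(calls)
    sets = [t_edits, c_edits]
    cov = sorted(covered) if covered is not None else None
    exc = sorted(exclude) if exclude else []

    def window_ok(lo: int, hi: int) -> bool:
        if cov is not None:
            i = bisect.bisect_right(cov, (lo, n + 1)) - 1
            if i < 0 or not (cov[i][0] <= lo and hi <= cov[i][1]):
                return False
        for s, e in exc:
            if s < hi and lo < e:
                return False
        return True

    def equivalent(pos: int, span: int) -> bool:
        lo = max(0, pos - radius)
        hi = min(n, pos + span + radius)
        lo, hi = _expand(lo, hi, sets)
        lo, hi = max(0, lo), min(n, hi)
        if not window_ok(lo, hi):
            return True  # outside the evaluable region; treated as neutral
        return (_apply_window(seq, t_edits, lo, hi)
                == _apply_window(seq, c_edits, lo, hi))

    n_truth = n_hit = 0
    missed = []
    for pos, r, a in t_edits:
        lo = max(0, pos - radius)
        hi = min(n, pos + len(r) + radius)
        if not window_ok(*_expand(lo, hi, sets)):
            continue  # uncovered / excluded: out of the denominator
        n_truth += 1
        if equivalent(pos, len(r)):
            n_hit += 1
        else:
            missed.append((pos, r, a))

    n_calls = n_ok = 0
    false_calls = []
    for v in calls:
        lo = max(0, v.pos - radius)
        hi = min(n, v.end + radius)
        if not window_ok(*_expand(lo, hi, sets)):
            continue
        n_calls += 1
        if equivalent(v.pos, v.end - v.pos):
            n_ok += 1
        else:
            false_calls.append(v)

    return EvalResult(
        recall=n_hit / n_truth if n_truth else 1.0,
        precision=n_ok / n_calls if n_calls else 1.0,
        n_truth=n_truth, n_truth_hit=n_hit,
        n_calls=n_calls, n_calls_ok=n_ok,
        missed=missed, false_calls=false_calls,
    )


def benchmark_trio(cfg, params=None):
    """Simulate a trio under ``cfg``, run the full analysis, and score it
    against the planted truth.  Returns (metrics dict, artifacts dict).

    Metrics cover the package's main outputs: contig N50, the gap
    catalog and its spanned subset, small-variant recall/precision
    (haplotype-aware, against the domesticated reference), SV recovery,
    recovered introgression boundaries on both references, the short
    introgression call, and the line-unique SV count.
    """
    from .pipeline import analyze_trio
    from .seqio import contig_n50
    from .simulate import simulate_all

    dom, wild, genomes, contigs, truth = simulate_all(cfg)
    res = analyze_trio(dom, wild, contigs, params)

    m: dict = {}
    n50s = [contig_n50([len(c.sequence) for c in contigs[ln]])
            for ln in ("long", "short", "none")]
    m["contig_n50_mbp"] = round(sum(n50s) / len(n50s) / 1e6, 4)

    gaps = res.gaps["wild"]
    m["gap_count_found"] = len(gaps)
    m["gap_catalog_matches_truth"] = int(
        [(g.start, g.end) for g in gaps] == truth.planted_gaps)
    m["gaps_spanned"] = len(res.gap_report.spanned)

    for line in ("long", "short"):
        te = truth.line_edits_vs_dom(line, dom)
        calls = (res.small_calls["domesticated"][line]
                 + res.sv_calls["domesticated"][line])
        ev = haplotype_eval(dom, te, calls,
                            covered=res.coverage["domesticated"][line])
        m[f"small_variant_recall_{line}"] = round(ev.recall, 4)
        m[f"small_variant_precision_{line}"] = round(ev.precision, 4)

    iv = truth.introgression_by_line["long"]["wild"]
    truth_svs = [VariantRecord(dom.name, v.dom_pos, v.kind, v.length,
                               v.ref_allele, v.alt_allele)
                 for v in truth.planted_variants
                 if v.length >= 50 and iv[0] <= v.wild_pos < iv[1]]
    n_t, n_rec, _ = sv_recovery(truth_svs, res.sv_calls["domesticated"]["long"])
    truth_unique = [VariantRecord(wild.name, u.wild_pos, u.kind, u.length,
                                  u.ref_allele, u.alt_allele)
                    for u in truth.unique_svs]
    n_tu, n_recu, _ = sv_recovery(truth_unique, res.sv_calls["wild"]["long"])
    m["sv_planted"] = n_t + n_tu
    m["sv_recovered"] = n_rec + n_recu
    m["sv_recall"] = round((n_rec + n_recu) / max(n_t + n_tu, 1), 4)

    win = (params.window_size if params is not None else 100_000)
    for role, tag in (("domesticated", "dom"), ("wild", "wild")):
        call = res.primary_call(f"{tag}_long")
        t_iv = truth.introgression_by_line["long"][tag]
        if call is not None:
            m[f"long_length_mbp_{tag}"] = round(call.length / 1e6, 4)
            m[f"long_boundary_error_windows_{tag}"] = round(max(
                abs(call.start - t_iv[0]), abs(call.end - t_iv[1])) / win, 3)
    short_call = res.primary_call("dom_short")
    m["short_detected"] = int(short_call is not None)
    if short_call is not None:
        m["short_length_kbp_dom"] = round(short_call.length / 1e3, 2)

    m["unique_sv_count"] = len(res.unique_sv_report.get("long_unique", []))
    m["unique_sv_planted"] = len(truth.unique_svs)

    artifacts = dict(dom=dom, wild=wild, genomes=genomes, contigs=contigs,
                     truth=truth, result=res)
    return m, artifacts


def sv_recovery(
    truth_svs: Sequence[VariantRecord],
    called_svs: Sequence[VariantRecord],
    pos_tol: int = 50,
    min_reciprocal_overlap: float = 0.5,
) -> tuple[int, int, list]:
    """How many planted SVs have a matching call with breakpoints within
    ``pos_tol``; returns (n_truth, n_recovered, missed)."""
    calls = sorted(called_svs, key=lambda v: v.pos)
    cpos = [c.pos for c in calls]
    n_rec = 0
    missed = []
    for t in truth_svs:
        i = bisect.bisect_left(cpos, t.pos - max(pos_tol, t.length))
        hit = False
        while i < len(calls) and cpos[i] <= t.pos + max(pos_tol, t.length):
            c = calls[i]
            if (c.kind == t.kind and abs(c.pos - t.pos) <= pos_tol
                    and match_variants(t, c, pos_tol, min_reciprocal_overlap)):
                hit = True
                break
            i += 1
        if hit:
            n_rec += 1
        else:
            missed.append(t)
    return len(truth_svs), n_rec, missed
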