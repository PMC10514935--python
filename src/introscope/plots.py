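"""Static figures: dot plots, density profiles, SV tracks, gap lengths."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["plot_dotplot", "plot_density", "plot_sv_track", "plot_gap_lengths"]


def _finish(fig, out, empty: bool, what: str):
    if empty:
        logger.warning("no data for %s; writing empty axes", what)
        fig.axes[0].text(0.5, 0.5, f"no {what} data", ha="center", va="center",
                         transform=fig.axes[0].transAxes)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_dotplot(dot_data, out, bin: int = 100_000):
    """Reference (x) vs contig (y) bins colored by identity on a fixed
    [0, 1] scale."""
    fig, ax = plt.subplots(figsize=(7, 6))
    if dot_data:
        # stack contigs on a common y axis in name order
        names = sorted({d[1] for d in dot_data})
        offsets = {}
        off = 0
        for n in names:
            offsets[n] = off
            off += max(d[3] for d in dot_data if d[1] == n) + 2
        xs = [d[2] * bin for d in dot_data]
        ys = [(offsets[d[1]] + d[3]) * bin for d in dot_data]
        cs = [d[4] for d in dot_data]
        sc = ax.scatter(xs, ys, c=cs, cmap="viridis", vmin=0.0, vmax=1.0, s=4)
        fig.colorbar(sc, ax=ax, label="identity")
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("contigs (stacked, bp)")
    _finish(fig, out, not dot_data, "dot plot")


def plot_density(profiles, calls_by_key, out):
    """Windowed differential-variant densities with called introgression
    intervals shaded."""
    profiles = list(profiles)
    n = max(1, len(profiles))
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.2 * n), squeeze=False)
    empty = all(p.counts.sum() == 0 for p in profiles) if profiles else True
    keys = sorted(calls_by_key)
    for i, prof in enumerate(profiles):
        ax = axes[i][0]
        x = [prof.window_interval(j)[0] for j in range(prof.n_windows)]
        ax.fill_between(x, prof.counts, step="post", color="tab:blue", alpha=0.8)
        key = keys[i] if i < len(keys) else None
        for c in calls_by_key.get(key, []):
            ax.axvspan(c.start, c.end, color="gray", alpha=0.3)
        ax.set_ylabel("variants / window")
        title = ", ".join(prof.class_filter) or "all classes"
        ax.set_title(f"{prof.ref_name}: {title}", fontsize=9)
    axes[-1][0].set_xlabel("reference position (bp)")
    fig.tight_layout()
    _finish(fig, out, empty, "density")


def plot_sv_track(unique_report, out):
    """Line-unique SVs (orange) and short+none-shared SVs (blue) as
    vertical bars along the reference."""
    fig, ax = plt.subplots(figsize=(8, 2))
    colors = {"long_unique": "tab:orange", "short_none_shared": "tab:blue"}
    ys = {"long_unique": 1.0, "short_none_shared": 0.0}
    empty = True
    for label, rows in (unique_report or {}).items():
        for row in rows:
            empty = False
            ax.vlines(row.pos, ys[label], ys[label] + 0.8, color=colors[label])
    ax.set_yticks([0.4, 1.4])
    ax.set_yticklabels(["short+none shared", "long-line unique"])
    ax.set_xlabel("wild reference position (bp)")
    fig.tight_layout()
    _finish(fig, out, empty, "SV track")


def plot_gap_lengths(gap_report, out, bins: int = 20):
    """Length histogram of all reference gaps (gray) overlaid with the
    contig-spanned subset (red)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    all_lens = [s.gap.length for s in gap_report.spans]
    sp_lens = [s.gap.length for s in gap_report.spanned]
    if all_lens:
        ax.hist(all_lens, bins=bins, color="gray", alpha=0.7, label="all gaps")
        if sp_lens:
            ax.hist(sp_lens, bins=bins, color="red", alpha=0.7, label="spanned")
        ax.legend()
    ax.set_xlabel("gap length (bp)")
    ax.set_ylabel("count")
    _finish(fig, out, not all_lens, "gap length")
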