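"""Caterpillar plots and tidy tables for benchmark reports.

Each comparator is drawn as a point (difference in net failure versus the
reference, in percentage points) with its 95% CI whisker, ranked by the
point estimate; vertical lines mark the 20% and 100% relative-risk margins.
Whiskers are coloured by classification band, and the legend lists only the
bands actually present in the report.  Internal computation stays on the
probability scale; conversion to percentage points happens only at render
time.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .benchmark import BenchmarkReport, Category, report_to_frame

__all__ = ["BAND_COLOURS", "build_figure", "render_report"]

logger = logging.getLogger(__name__)

# Five distinguishable colours, worst to best band.
BAND_COLOURS: Mapping[Category, str] = {
    Category.INFERIOR_100: "#b2182b",      # dark red
    Category.INFERIOR_20: "#ef8a62",       # light red
    Category.INCONCLUSIVE: "#999999",      # grey
    Category.NONINFERIOR_100: "#67a9cf",   # light blue
    Category.NONINFERIOR_20: "#2166ac",    # dark blue
}

_BAND_LABELS: Mapping[Category, str] = {
    Category.INFERIOR_100: "inferior (100% margin)",
    Category.INFERIOR_20: "inferior (20% margin)",
    Category.INCONCLUSIVE: "inconclusive",
    Category.NONINFERIOR_100: "noninferior (100% margin)",
    Category.NONINFERIOR_20: "noninferior (20% margin)",
}


def render_report(
    report: BenchmarkReport,
    path: str | Path,
    fmt: str = "png",
) -> tuple[Optional[Path], Path]:
    """Write the caterpillar figure and its companion CSV.

    ``path`` is the output stem; ``<stem>.csv`` always appears, and
    ``<stem>.<fmt>`` appears when the report has rows.  Returns the figure
    path (or None for an empty report) and the CSV path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    frame = report_to_frame(report)
    frame.to_csv(csv_path, index=False)
    if not report.rows:
        logger.warning(
            "t=%g stratum=%s: empty report, CSV header only, no figure",
            report.t, report.stratum,
        )
        return None, csv_path

    fig = build_figure(report)
    fig_path = path.with_suffix(f".{fmt}")
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return fig_path, csv_path


def build_figure(report: BenchmarkReport):
    """Construct the caterpillar figure for a non-empty report."""
    rows = sorted(report.rows, key=lambda r: (r.diff, r.construct.label))
    fig, ax = plt.subplots(figsize=(7.5, max(3.0, 0.32 * len(rows) + 1.6)))
    seen: set[Category] = set()
    for y, row in enumerate(rows):
        colour = BAND_COLOURS[row.category]
        label = _BAND_LABELS[row.category] if row.category not in seen else None
        seen.add(row.category)
        ax.errorbar(
            100.0 * row.diff,
            y,
            xerr=[[100.0 * (row.diff - row.ci_low)], [100.0 * (row.ci_high - row.diff)]],
            fmt="o",
            color=colour,
            ecolor=colour,
            capsize=2.5,
            markersize=4,
            label=label,
        )
    ax.axvline(0.0, color="black", lw=0.8)
    ax.axvline(100.0 * report.margins.m20, color="black", lw=0.8, ls="--")
    ax.axvline(100.0 * report.margins.m100, color="black", lw=0.8, ls=":")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([f"{r.construct.label}  (n={r.n_at_risk})" for r in rows], fontsize=7)
    ax.set_xlabel("Difference in net failure vs reference (percentage points)")
    ref = report.reference_estimate
    ax.set_title(
        f"{report.t:g}-year benchmark, stratum: {report.stratum}\n"
        f"reference {report.reference.label}: "
        f"{100 * ref.failure:.2f}% ({100 * ref.ci_low:.2f}-{100 * ref.ci_high:.2f}%), "
        f"{ref.n_at_risk} at risk",
        fontsize=9,
    )
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    return fig
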