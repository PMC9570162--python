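"""Dot-plot rendering of basic, optimal and rearranged alignments.

The x axis is the reference position; queries are stacked on the y axis,
each offset by the cumulative length of the queries below it.  A forward
match draws an ascending blue diagonal from (ref_start, offset+query_start)
to (ref_end, offset+query_end); a reverse match draws the descending red
anti-diagonal.  Thin separator lines mark query boundaries in stacked plots.

Output formats: pdf (default), png, ps, svg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection
from matplotlib.lines import Line2D

from .errors import ParameterError, UsageError
from .kmer_align import Strand
from .rearrange import QueryResult

__all__ = ["PlotSpec", "StackLayout", "layout_queries", "render_dotplot",
           "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("pdf", "png", "ps", "svg")

# Fixed hash salt + no date metadata so identical input renders identical
# bytes (svg embeds randomized ids and a timestamp otherwise).
_SVG_METADATA = {"Date": None}


@dataclass(frozen=True)
class PlotSpec:
    """Display options for one rendered dot plot."""

    title: str = ""
    xlabel: str = "Reference position (bp)"
    ylabel: str = "Query position (bp)"
    show_legend: bool = True
    point_size: float = 2.0
    line_width: float = 1.2
    forward_color: str = "blue"
    reverse_color: str = "red"
    per_query_colors: dict[str, str] | None = None
    format: str = "pdf"

    def __post_init__(self) -> None:
        if self.format not in SUPPORTED_FORMATS:
            raise ParameterError(
                f"unsupported format {self.format!r}; choose from "
                f"{', '.join(SUPPORTED_FORMATS)}"
            )
        if self.point_size <= 0 or self.line_width <= 0:
            raise ParameterError("point_size and line_width must be positive")


@dataclass(frozen=True)
class StackLayout:
    """Vertical arrangement of queries: bottom-to-top order and y offsets."""

    order: tuple[str, ...]
    offsets: dict[str, int]
    total_height: int


def layout_queries(results: list[QueryResult], order: list[str]) -> StackLayout:
    """Compute y offsets for stacking queries in the given bottom-up order.

    ``order`` must be a permutation of the result query ids; offsets are the
    prefix sums of query lengths in that order.
    """
    by_id = {r.query.id: r for r in results}
    if sorted(order) != sorted(by_id):
        raise UsageError("order is not a permutation of the query ids")
    offsets: dict[str, int] = {}
    y = 0
    for qid in order:
        offsets[qid] = y
        y += by_id[qid].query.length
    return StackLayout(order=tuple(order), offsets=offsets, total_height=y)


def render_dotplot(
    results: list[QueryResult],
    layout: StackLayout,
    mode: str,
    spec: PlotSpec,
    path: str | Path,
) -> None:
    """Draw one dot plot and write it to ``path`` in ``spec.format``.

    ``mode`` selects the segment source: ``"basic"`` draws every merged
    segment, ``"optimal"`` and ``"rearranged"`` draw only the tiling.  In
    rearranged mode ``spec.per_query_colors`` (when given) overrides strand
    colouring so the similarity ordering stands out.
    """
    if mode not in ("basic", "optimal", "rearranged"):
        raise ParameterError(f"unknown plot mode {mode!r}")
    by_id = {r.query.id: r for r in results}
    ref_length = 0
    lines, colors = [], []
    for qid in layout.order:
        res = by_id[qid]
        off = layout.offsets[qid]
        segs = res.basic_segments if mode == "basic" else res.tiling.segments
        for seg in segs:
            ref_length = max(ref_length, seg.ref_end)
            if seg.strand is Strand.FORWARD:
                y0, y1 = off + seg.query_start, off + seg.query_end
            else:
                y0, y1 = off + seg.query_end, off + seg.query_start
            lines.append([(seg.ref_start, y0), (seg.ref_end, y1)])
            if mode == "rearranged" and spec.per_query_colors:
                colors.append(spec.per_query_colors.get(
                    qid,
                    spec.forward_color if seg.strand is Strand.FORWARD
                    else spec.reverse_color,
                ))
            else:
                colors.append(spec.forward_color if seg.strand is Strand.FORWARD
                              else spec.reverse_color)

    fig, ax = plt.subplots(figsize=(7, 7))
    try:
        ax.add_collection(
            LineCollection(lines, colors=colors, linewidths=spec.line_width)
        )
        if spec.point_size > 0 and lines:
            xs = [p for seg in lines for p in (seg[0][0], seg[1][0])]
            ys = [p for seg in lines for p in (seg[0][1], seg[1][1])]
            ax.scatter(xs, ys, s=spec.point_size, c="none", linewidths=0)
        for qid in layout.order[1:]:
            ax.axhline(layout.offsets[qid], color="0.8", linewidth=0.6)
        ax.set_xlim(0, max(ref_length, 1))
        ax.set_ylim(0, max(layout.total_height, 1))
        ax.set_xlabel(spec.xlabel)
        ax.set_ylabel(spec.ylabel)
        if spec.title:
            ax.set_title(spec.title)
        if spec.show_legend:
            handles = [
                Line2D([0], [0], color=spec.forward_color, lw=spec.line_width,
                       label="forward (5'→3')"),
                Line2D([0], [0], color=spec.reverse_color, lw=spec.line_width,
                       label="reverse (3'→5')"),
            ]
            ax.legend(handles=handles, loc="upper left", fontsize=8)
        path = Path(path)
        save_kwargs = {"format": spec.format}
        if spec.format == "svg":
            save_kwargs["metadata"] = _SVG_METADATA
        with matplotlib.rc_context({"svg.hashsalt": "contigplot"}):
            fig.savefig(path, **save_kwargs)
    finally:
        plt.close(fig)
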