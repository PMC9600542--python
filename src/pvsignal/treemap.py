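"""Squarified treemap layout and a minimal SVG renderer.

Rectangle areas encode signals per system organ class; fill color encodes
report counts through a sequential colormap on a log10 scale.  The layout
is the greedy squarified algorithm: items are placed in rows along the
shorter side of the remaining canvas, extending a row only while doing so
does not worsen its worst aspect ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence
from xml.sax.saxutils import escape

import matplotlib

from .hierarchy import SOCSummary

__all__ = ["TreemapRect", "treemap_layout", "render_svg"]


@dataclass(frozen=True)
class TreemapRect:
    """One tile: position and size in normalized [0,1] canvas units."""

    soc: str
    x: float
    y: float
    width: float
    height: float
    n_signals: int
    n_reports: int

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def aspect(self) -> float:
        if min(self.width, self.height) == 0:
            return math.inf
        return max(self.width / self.height, self.height / self.width)


def _worst_ratio(row: Sequence[float], side: float) -> float:
    """Worst aspect ratio of a row of areas laid along a side of given length."""
    s = sum(row)
    if s == 0 or side == 0:
        return math.inf
    s2, l2 = s * s, side * side
    rmin, rmax = min(row), max(row)
    return max(l2 * rmax / s2, s2 / (l2 * rmin))


def _lay_row(
    row: Sequence[tuple[SOCSummary, float]],
    x: float,
    y: float,
    w: float,
    h: float,
) -> tuple[list[TreemapRect], float, float, float, float]:
    """Place one row in the remaining rect; return tiles and the leftover rect."""
    s = sum(area for _, area in row)
    rects = []
    if w >= h:  # vertical strip of thickness s/h on the left
        t = s / h
        cy = y
        for summ, area in row:
            rh = area / t
            rects.append(TreemapRect(summ.soc, x, cy, t, rh, summ.n_signals, summ.n_reports))
            cy += rh
        return rects, x + t, y, w - t, h
    t = s / w  # horizontal strip of thickness s/w on top
    cx = x
    for summ, area in row:
        rw = area / t
        rects.append(TreemapRect(summ.soc, cx, y, rw, t, summ.n_signals, summ.n_reports))
        cx += rw
    return rects, x, y + t, w, h - t


def treemap_layout(summaries: Sequence[SOCSummary]) -> list[TreemapRect]:
    """Compute a squarified layout on the unit square.

    Input is sorted by descending ``n_signals`` (ties by SOC name) before
    layout, so the result is deterministic; tile areas are exactly
    proportional to ``n_signals``.  Entries with zero signals are dropped;
    an input with no positive size is an error.
    """
    items = sorted(
        (s for s in summaries if s.n_signals > 0),
        key=lambda s: (-s.n_signals, s.soc),
    )
    if not items:
        raise ValueError("treemap requires at least one summary with n_signals > 0")
    total = sum(s.n_signals for s in items)
    areas = [(s, s.n_signals / total) for s in items]

    out: list[TreemapRect] = []
    x, y, w, h = 0.0, 0.0, 1.0, 1.0
    i = 0
    while i < len(areas):
        side = min(w, h)
        row = [areas[i]]
        i += 1
        while i < len(areas):
            cur = [a for _, a in row]
            if _worst_ratio(cur + [areas[i][1]], side) <= _worst_ratio(cur, side):
                row.append(areas[i])
                i += 1
            else:
                break
        if i < len(areas):
            tiles, x, y, w, h = _lay_row(row, x, y, w, h)
        else:  # last row fills the remainder exactly
            tiles, *_ = _lay_row(row, x, y, w, h)
        out.extend(tiles)
    return out


def _fill_colors(rects: Sequence[TreemapRect], cmap_name: str) -> list[str]:
    """Map n_reports -> hex color via log10 scaling between data min/max."""
    cmap = matplotlib.colormaps[cmap_name]
    logs = [math.log10(max(r.n_reports, 1)) for r in rects]
    lo, hi = min(logs), max(logs)
    span = hi - lo
    return [
        matplotlib.colors.to_hex(cmap(0.5 if span == 0 else (v - lo) / span))
        for v in logs
    ]


def render_svg(
    rects: Sequence[TreemapRect],
    path: str,
    *,
    width: int = 900,
    height: int = 600,
    cmap: str = "YlOrRd",
) -> None:
    """Write the layout as a standalone SVG file.

    Labels are drawn only in tiles wide and tall enough to hold them; every
    tile carries a ``<title>`` tooltip with its SOC, signal count and
    report count.
    """
    colors = _fill_colors(rects, cmap)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        '<style>text{font-family:sans-serif;fill:#222}</style>',
    ]
    for r, color in zip(rects, colors):
        px, py = r.x * width, r.y * height
        pw, ph = r.width * width, r.height * height
        title = f"{r.soc}: {r.n_signals} signals, {r.n_reports} reports"
        parts.append(
            f'<rect x="{px:.2f}" y="{py:.2f}" width="{pw:.2f}" height="{ph:.2f}" '
            f'fill="{color}" stroke="white" stroke-width="1.5">'
            f"<title>{escape(title)}</title></rect>"
        )
        if pw > 90 and ph > 28:
            label = escape(r.soc if len(r.soc) * 7 < pw else r.soc[: int(pw / 7)] + "…")
            parts.append(
                f'<text x="{px + 5:.2f}" y="{py + 16:.2f}" font-size="12">{label}</text>'
            )
            parts.append(
                f'<text x="{px + 5:.2f}" y="{py + 30:.2f}" font-size="10">'
                f"{r.n_signals} signals / {r.n_reports} reports</text>"
            )
    parts.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts) + "\n")
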