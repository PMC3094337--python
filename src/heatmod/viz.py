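"""Color scales and static heat-map export.

A :class:`ColorScale` maps one cell value to an RGB color; four kinds are
provided: ``pvalue`` (significance-aware, gradient on -log10 p below the
significance level), ``linear`` and ``zscore`` (piecewise-linear gradients
between anchors) and ``binary``.  :func:`render_heatmap` rasterizes any
matrix layer to a deterministic PNG; :func:`export_html_report` writes a
self-contained HTML heat-map with a legend and per-cell hover detail.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .matrix import DataError, DataMatrix, ResultMatrix

__all__ = [
    "ColorScale", "HeatmapStyle",
    "map_color", "render_heatmap", "export_html_report", "export_legend_tsv",
]

Color = tuple[int, int, int]

#: floor for the -log10 gradient of the p-value scale
P_FLOOR = 1e-16


def _lerp(c1: Color, c2: Color, t: float) -> Color:
    t = min(1.0, max(0.0, t))
    return tuple(int(round(c1[i] + (c2[i] - c1[i]) * t)) for i in range(3))


@dataclass
class ColorScale:
    """Maps cell values to colors.

    ``pvalue`` kind: values above the significance level ``alpha`` get
    ``non_significant_color``; values at or below it are placed on a
    gradient proportional to -log10(p) between ``alpha`` and a floor of
    1e-16.  ``linear``/``zscore`` kinds interpolate piecewise-linearly
    between ``anchors`` (value, color) pairs, clamped at the ends.
    ``binary`` maps 0 and 1 to the first and last anchor colors.
    """

    kind: str = "linear"                      # pvalue | linear | zscore | binary
    alpha: float = 0.05
    anchors: list[tuple[float, Color]] = field(default_factory=list)
    significant_low: Color = (255, 240, 80)   # color at p = alpha
    significant_high: Color = (200, 0, 0)     # color at p <= 1e-16
    non_significant_color: Color = (210, 210, 210)
    missing_color: Color = (160, 160, 160)

    def __post_init__(self):
        if self.kind not in ("pvalue", "linear", "zscore", "binary"):
            raise DataError(f"unknown scale kind {self.kind!r}")
        if self.kind == "pvalue" and not (0 < self.alpha < 1):
            raise DataError("significance level must be in (0, 1)")
        if not self.anchors:
            if self.kind in ("linear",):
                self.anchors = [(-1.0, (0, 0, 180)), (0.0, (255, 255, 255)),
                                (1.0, (180, 0, 0))]
            elif self.kind == "zscore":
                self.anchors = [(-4.0, (0, 90, 170)), (0.0, (255, 255, 255)),
                                (4.0, (190, 0, 0))]
            elif self.kind == "binary":
                self.anchors = [(0.0, (245, 245, 245)), (1.0, (60, 60, 170))]
            else:  # pvalue: anchors document the legend breakpoints
                self.anchors = [(self.alpha, self.significant_low),
                                (P_FLOOR, self.significant_high)]
        vals = [v for v, _ in self.anchors]
        if self.kind in ("linear", "zscore", "binary"):
            if sorted(vals) != vals or len(set(vals)) != len(vals):
                raise DataError("anchor values must be strictly increasing")

    # ------------------------------------------------------------------
    def legend_entries(self) -> list[tuple[str, Color]]:
        """One (label, color) entry per scale anchor, plus the special
        colors."""
        entries = []
        if self.kind == "pvalue":
            entries.append((f"> {self.alpha:g} (not significant)",
                            self.non_significant_color))
        for v, c in self.anchors:
            entries.append((f"{v:g}", c))
        entries.append(("missing", self.missing_color))
        return entries


def map_color(scale: ColorScale, value: float) -> Color:
    """Color of one value under a scale; non-finite values map to the
    missing color."""
    if value is None or not math.isfinite(value):
        return scale.missing_color
    if scale.kind == "pvalue":
        p = min(1.0, max(0.0, value))
        if p > scale.alpha:
            return scale.non_significant_color
        p = max(p, P_FLOOR)
        span = -math.log10(P_FLOOR) + math.log10(scale.alpha)
        t = (-math.log10(p) + math.log10(scale.alpha)) / span
        return _lerp(scale.significant_low, scale.significant_high, t)
    if scale.kind == "binary":
        return scale.anchors[-1][1] if value >= 0.5 else scale.anchors[0][1]
    anchors = scale.anchors
    if value <= anchors[0][0]:
        return anchors[0][1]
    if value >= anchors[-1][0]:
        return anchors[-1][1]
    for (v1, c1), (v2, c2) in zip(anchors, anchors[1:]):
        if v1 <= value <= v2:
            t = 0.0 if v2 == v1 else (value - v1) / (v2 - v1)
            return _lerp(c1, c2, t)
    return scale.missing_color  # pragma: no cover


@dataclass
class HeatmapStyle:
    """Geometry of the rendered heat-map."""

    cell_width: int = 12
    cell_height: int = 12
    grid_color: Color = (255, 255, 255)
    grid_thickness: int = 0
    label_font_size: int = 10
    show_row_labels: bool = False
    show_col_labels: bool = False
    max_pixels: int = 16_000_000

    def __post_init__(self):
        if self.cell_width < 1 or self.cell_height < 1:
            raise DataError("cell dimensions must be positive")
        if self.grid_thickness < 0:
            raise DataError("grid thickness must be >= 0")


def _layer_frame(m, layer: str | None):
    if isinstance(m, ResultMatrix):
        name = layer or m.default_layer
        if name not in m.layers:
            raise DataError(f"no layer {name!r} in result matrix")
        return m.layer(name), name
    if isinstance(m, DataMatrix):
        return m.df, m.layer_name
    raise DataError(f"cannot render object of type {type(m).__name__}")


def _label_gutters(df, style: HeatmapStyle, font) -> tuple[int, int]:
    gw = gh = 0
    if style.show_row_labels:
        gw = 4 + max(int(font.getlength(str(r))) for r in df.index)
    if style.show_col_labels:
        gh = 4 + max(int(font.getlength(str(c))) for c in df.columns)
    return gw, gh


def render_heatmap(m, layer: str | None, scale: ColorScale,
                   style: HeatmapStyle, out_path) -> None:
    """Rasterize one matrix layer to a PNG.

    Cell (i, j) occupies a ``cell_width`` x ``cell_height`` block whose
    fill is ``map_color`` of its value; optional grid lines are drawn along
    cell edges and labels in a gutter.  Output is deterministic: the same
    inputs produce byte-identical files.
    """
    df, _ = _layer_frame(m, layer)
    nrows, ncols = df.shape
    if nrows * style.cell_height * ncols * style.cell_width > style.max_pixels:
        raise DataError("heat-map exceeds the pixel budget; filter the matrix "
                        "to fewer rows/columns or reduce the cell size")
    font = ImageFont.load_default()
    gw, gh = _label_gutters(df, style, font)
    width = ncols * style.cell_width + gw
    height = nrows * style.cell_height + gh
    img = Image.new("RGB", (width, height), (255, 255, 255))
    px = img.load()
    vals = df.to_numpy()
    for i in range(nrows):
        y0 = gh + i * style.cell_height
        for j in range(ncols):
            x0 = j * style.cell_width
            color = map_color(scale, float(vals[i, j]))
            for y in range(y0, y0 + style.cell_height):
                for x in range(x0, x0 + style.cell_width):
                    px[x, y] = color
    g = style.grid_thickness
    if g > 0:
        draw = ImageDraw.Draw(img)
        for j in range(1, ncols):
            x = j * style.cell_width
            draw.rectangle([x - (g + 1) // 2, gh, x + g // 2 - 1 + (g % 2), height - 1],
                           fill=style.grid_color)
        for i in range(1, nrows):
            y = gh + i * style.cell_height
            draw.rectangle([0, y - (g + 1) // 2, width - gw - 1 if gw else width - 1,
                            y + g // 2 - 1 + (g % 2)], fill=style.grid_color)
    if style.show_row_labels or style.show_col_labels:
        draw = ImageDraw.Draw(img)
        if style.show_row_labels:
            for i, r in enumerate(df.index):
                draw.text((width - gw + 3, gh + i * style.cell_height),
                          str(r), fill=(0, 0, 0), font=font)
        if style.show_col_labels:
            for j, c in enumerate(df.columns):
                draw.text((j * style.cell_width, 1), str(c),
                          fill=(0, 0, 0), font=font)
    img.save(Path(out_path), format="PNG")


def _hex(c: Color) -> str:
    return "#{:02x}{:02x}{:02x}".format(*c)


def export_legend_tsv(scale: ColorScale, out_path) -> None:
    """Write the scale's legend as a two-column TSV (label -> hex color)."""
    lines = ["label\tcolor"]
    for label, color in scale.legend_entries():
        lines.append(f"{label}\t{_hex(color)}")
    Path(out_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_html_report(m, layer: str | None, scale: ColorScale,
                       style: HeatmapStyle, out_path,
                       title: str = "Heat-map report") -> None:
    """Write a self-contained HTML heat-map report.

    The heat-map is an HTML table with inline cell colors; each cell's
    ``title`` attribute lists every layer value for that cell, so hovering
    shows the full statistics.  A legend describes the color scale and,
    for p-value scales, the significance level.
    """
    df, layer_name = _layer_frame(m, layer)
    esc = html.escape
    parts: list[str] = []
    parts.append("<!DOCTYPE html>")
    parts.append("<html><head><meta charset='utf-8'/>")
    parts.append(f"<title>{esc(title)}</title>")
    parts.append("<style>table.hm{border-collapse:collapse}"
                 "table.hm td.cell{width:%dpx;height:%dpx;padding:0}"
                 "table.hm th{font-size:%dpx;font-weight:normal;padding:1px 3px}"
                 ".legend span.sw{display:inline-block;width:12px;height:12px;"
                 "margin-right:4px;border:1px solid #888}</style>"
                 % (style.cell_width, style.cell_height, style.label_font_size))
    parts.append("</head><body>")
    parts.append(f"<h1>{esc(title)}</h1>")
    parts.append(f"<p>Layer: <b>{esc(layer_name)}</b></p>")
    parts.append("<table class='hm'>")
    parts.append("<tr><th></th>" +
                 "".join(f"<th>{esc(str(c))}</th>" for c in df.columns) + "</tr>")
    for r in df.index:
        cells = []
        for c in df.columns:
            v = float(df.at[r, c])
            color = _hex(map_color(scale, v))
            if isinstance(m, ResultMatrix):
                detail = "; ".join(f"{k}={vv:.6g}" for k, vv in m.cell(r, c).items())
            else:
                detail = f"{layer_name}={v:.6g}"
            hover = esc(f"{r} / {c}: {detail}")
            cells.append(f"<td class='cell' style='background:{color}' "
                         f"title='{hover}'></td>")
        parts.append(f"<tr><th>{esc(str(r))}</th>" + "".join(cells) + "</tr>")
    parts.append("</table>")
    parts.append("<div class='legend'><h2>Legend</h2>")
    if scale.kind == "pvalue":
        parts.append(f"<p>Significance level &#945; = {scale.alpha:g}</p>")
    parts.append("<ul>")
    for label, color in scale.legend_entries():
        parts.append(f"<li><span class='sw' style='background:{_hex(color)}'>"
                     f"</span>{esc(label)}</li>")
    parts.append("</ul></div>")
    parts.append("</body></html>")
    Path(out_path).write_text("\n".join(parts) + "\n", encoding="utf-8")
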