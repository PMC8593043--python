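"""Layered plot specification and the multi-panel figure renderer.

A :class:`PlotSpec` is a minimal grammar-of-graphics plot: layers of
point/line/bar/segment/text/hline/vline/rect geometry, each possibly
reading a different table.  :func:`build_figure` resolves the axis
transform into a slice layout, places one matplotlib panel per slice with
pixel extents proportional to the canvas bands, clips every layer's
geometry so no mark crosses a break, and draws the break glyphs, shared
axes, titles and legend.  Output is deterministic SVG (no timestamps, a
fixed hash salt) or PNG.

Layering composes *after* the transform: adding a layer from a new table
to an already-broken plot routes it through the same clipping machinery
into the existing panels, which is the point of building the break as a
layout object rather than as a one-shot drawing.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import matplotlib
import numpy as np
import pandas as pd
from matplotlib import rc_context
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Patch, Rectangle

from .break_model import (
    AxisBreakSpec,
    AxisBreakError,
    AxisCutSpec,
    BreakWarning,
    Interval,
    WrapSpec,
)
from .clipping import (
    ReferenceLine,
    Segment,
    assign_point_layers,
    clip_bar,
    clip_segment_to_slices,
    replicate_reference_lines,
)
from .layout import SliceLayout, expand_outer_slices, resolve_layout
from .ticks import (
    DEFAULT_TARGET,
    apply_ticklabels,
    dedupe_break_edge_ticks,
    default_ticks,
    format_tick,
)

__all__ = [
    "Layer",
    "PlotSpec",
    "PanelInfo",
    "RenderedFigure",
    "build_figure",
    "draw_break_marks",
    "render_svg",
    "render_png",
]

Geom = Literal["point", "line", "bar", "segment", "text", "hline", "vline", "rect"]

# fixed minimal theme: margins of the panel region in figure fraction
_ML, _MR, _MB, _MT = 0.12, 0.04, 0.12, 0.10
#: vertical gap between wrap rows, as a fraction of the panel region height
_WRAP_ROW_GAP = 0.06
#: break glyph: 45-degree double stroke, length in px at the axis line
BREAK_GLYPH_LEN_PX = 6.0
_GLYPH_PAIR_SEP_PX = 3.0

_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":", "dashdot": "-."}

_SVG_RC = {"svg.hashsalt": "axisbreak", "svg.fonttype": "none"}


@dataclass(frozen=True)
class Layer:
    """One geometric layer bound to a data table.

    ``mapping`` names columns for the aesthetics the geom needs (x, y and
    optionally xend/yend/label/group); ``style`` holds constants (color,
    size, alpha, linetype, label for the legend, orientation/width/baseline
    for bars, value for reference lines).  ``source_id`` identifies the
    table in error messages — layers may come from different sources.
    """

    geom: Geom
    data: pd.DataFrame
    mapping: dict = field(default_factory=dict)
    style: dict = field(default_factory=dict)
    source_id: str = "layer"


@dataclass
class PlotSpec:
    """A layered plot: data + geometry, axis labels, optional log scale."""

    layers: list[Layer]
    x_label: str = ""
    y_label: str = ""
    title: str = ""
    x_scale: Literal["linear", "log10"] = "linear"
    y_scale: Literal["linear", "log10"] = "linear"
    x_limits: Optional[Interval] = None
    y_limits: Optional[Interval] = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise AxisBreakError("a plot needs at least one layer")


@dataclass(frozen=True)
class PanelInfo:
    """Pixel viewport of one rendered panel (origin bottom-left)."""

    slice_index: int
    x_px: float
    y_px: float
    width_px: float
    height_px: float


@dataclass
class RenderedFigure:
    """A built figure: panel grid plus the live matplotlib Figure.

    SVG bytes are produced (and cached) by :func:`render_svg`; repeated
    renders of the same spec are byte-identical.
    """

    panels: list[PanelInfo]
    figure: Figure
    layout: SliceLayout
    width_px: int
    height_px: int
    svg: Optional[bytes] = None
    break_marks_drawn: bool = False


# ---------------------------------------------------------------------------
# range computation

_POSITIONAL = {
    "point": (("x",), ("y",)),
    "line": (("x",), ("y",)),
    "text": (("x",), ("y",)),
    "segment": (("x", "xend"), ("y", "yend")),
    "rect": (("x", "xend"), ("y", "yend")),
    "bar": ((), ()),  # handled specially (orientation)
    "hline": ((), ()),
    "vline": ((), ()),
}


def _require_column(layer: Layer, key: str) -> str:
    col = layer.mapping.get(key)
    if col is None:
        raise AxisBreakError(f"layer '{layer.source_id}': mapping is missing '{key}'")
    if col not in layer.data.columns:
        raise AxisBreakError(
            f"layer '{layer.source_id}': column '{col}' not found in its table"
        )
    return col


def _numeric(layer: Layer, col: str) -> np.ndarray:
    vals = pd.to_numeric(layer.data[col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise AxisBreakError(
            f"layer '{layer.source_id}': column '{col}' must be numeric"
        )
    return vals


def _bar_axes(layer: Layer) -> tuple[str, str]:
    """(value_axis, category_axis) for a bar layer."""
    orient = layer.style.get("orientation", "v")
    if orient not in ("v", "h"):
        raise AxisBreakError(
            f"layer '{layer.source_id}': orientation must be 'v' or 'h', got {orient!r}"
        )
    return ("y", "x") if orient == "v" else ("x", "y")


def _layer_axis_values(layer: Layer, axis: str) -> list[np.ndarray]:
    """All data values a layer contributes to one axis's range."""
    out: list[np.ndarray] = []
    if layer.geom == "bar":
        value_axis, cat_axis = _bar_axes(layer)
        baseline = float(layer.style.get("baseline", 0.0))
        if axis == value_axis:
            out.append(_numeric(layer, _require_column(layer, value_axis)))
            out.append(np.array([baseline]))
        else:
            cats = _numeric(layer, _require_column(layer, cat_axis))
            halfw = float(layer.style.get("width", 0.8)) / 2.0
            out.append(cats - halfw)
            out.append(cats + halfw)
        return out
    if layer.geom in ("hline", "vline"):
        own = "y" if layer.geom == "hline" else "x"
        if axis == own:
            out.append(np.asarray(_reference_values(layer), dtype=float))
        return out
    keys = _POSITIONAL[layer.geom][0 if axis == "x" else 1]
    for key in keys:
        out.append(_numeric(layer, _require_column(layer, key)))
    return out


def _reference_values(layer: Layer) -> list[float]:
    if "value" in layer.style:
        return [float(layer.style["value"])]
    key = "y" if layer.geom == "hline" else "x"
    return list(_numeric(layer, _require_column(layer, key)))


def _log10_inplace(vals: np.ndarray, layer: Layer, axis: str) -> np.ndarray:
    if (vals <= 0).any():
        raise AxisBreakError(
            f"layer '{layer.source_id}': log10 {axis}-scale requires strictly "
            "positive data"
        )
    return np.log10(vals)


def _compute_range(plot: PlotSpec, axis: str) -> Interval:
    limits = plot.x_limits if axis == "x" else plot.y_limits
    if limits is not None:
        return limits
    scale = plot.x_scale if axis == "x" else plot.y_scale
    chunks: list[np.ndarray] = []
    for layer in plot.layers:
        if layer.data.empty:
            continue
        for vals in _layer_axis_values(layer, axis):
            if vals.size == 0:
                continue
            if scale == "log10":
                vals = _log10_inplace(vals, layer, axis)
            chunks.append(vals)
    if not chunks:
        warnings.warn(
            f"no data determines the {axis} range; defaulting to (0, 1)",
            BreakWarning,
            stacklevel=2,
        )
        return Interval(0.0, 1.0)
    allv = np.concatenate(chunks)
    lo, hi = float(allv.min()), float(allv.max())
    if lo == hi:
        pad = 0.5 if lo == 0 else abs(lo) * 0.05
        return Interval(lo - pad, hi + pad)
    return Interval(lo, hi)


# ---------------------------------------------------------------------------
# panel placement

def _panel_rects(layout: SliceLayout) -> list[tuple[float, float, float, float]]:
    """Figure-fraction rects [x, y, w, h] for each slice, in slice order."""
    pw = 1.0 - _ML - _MR
    ph = 1.0 - _MB - _MT
    rects = []
    if layout.mode == "wrap":
        n = layout.n
        gap = _WRAP_ROW_GAP * ph if n > 1 else 0.0
        rowh = (ph - gap * (n - 1)) / n
        for i in range(n):
            # slice 0 (lowest data) on top, increasing data reads down the page
            top_offset = i * (rowh + gap)
            y = _MB + ph - top_offset - rowh
            rects.append((_ML, y, pw, rowh))
        return rects
    for s in layout.slices:
        if layout.axis == "x":
            rects.append((_ML + s.band.lo * pw, _MB, s.band.span * pw, ph))
        else:
            rects.append((_ML, _MB + s.band.lo * ph, pw, s.band.span * ph))
    return rects


def _style_kwargs(layer: Layer) -> dict:
    st = layer.style
    kw = {}
    if "color" in st:
        kw["color"] = st["color"]
    if "alpha" in st:
        kw["alpha"] = float(st["alpha"])
    return kw


def _transformed_frame(layer: Layer, plot: PlotSpec) -> pd.DataFrame:
    """Copy of the layer table with log10 applied to mapped positional columns."""
    df = layer.data.copy()
    for axis, scale in (("x", plot.x_scale), ("y", plot.y_scale)):
        if scale != "log10":
            continue
        cols = set()
        if layer.geom == "bar":
            value_axis, cat_axis = _bar_axes(layer)
            key = value_axis if axis == value_axis else cat_axis
            cols.add(layer.mapping.get(key))
        elif layer.geom in ("hline", "vline"):
            own = "y" if layer.geom == "hline" else "x"
            if axis == own and "value" not in layer.style:
                cols.add(layer.mapping.get(own))
        else:
            for key in _POSITIONAL[layer.geom][0 if axis == "x" else 1]:
                cols.add(layer.mapping.get(key))
        for col in cols:
            if col is not None and col in df.columns:
                vals = _numeric(layer, col)
                df[col] = _log10_inplace(vals, layer, axis)
    return df


# ---------------------------------------------------------------------------
# geometry drawing


def _draw_points(axes, layer, df, plot, layout) -> None:
    xcol = _require_column(layer, "x")
    ycol = _require_column(layer, "y")
    pts = list(zip(df[xcol].to_numpy(float), df[ycol].to_numpy(float)))
    per_slice, _ = assign_point_layers(pts, layout)
    kw = _style_kwargs(layer)
    size = float(layer.style.get("size", 4.0))
    for i, ax in enumerate(axes):
        group = per_slice[i]
        if not group:
            continue
        xs = [p[0] for p in group]
        ys = [p[1] for p in group]
        ax.plot(xs, ys, linestyle="", marker="o", markersize=size,
                markeredgewidth=0, **kw)


def _draw_lines(axes, layer, df, plot, layout) -> None:
    xcol = _require_column(layer, "x")
    ycol = _require_column(layer, "y")
    kw = _style_kwargs(layer)
    lw = float(layer.style.get("size", 1.0))
    ls = _LINESTYLES.get(layer.style.get("linetype", "solid"), "-")
    groups: list[pd.DataFrame]
    gcol = layer.mapping.get("group")
    if gcol is not None:
        groups = [g for _, g in df.groupby(gcol, sort=True)]
    else:
        groups = [df]
    for g in groups:
        g = g.sort_values(xcol, kind="mergesort")
        xs = g[xcol].to_numpy(float)
        ys = g[ycol].to_numpy(float)
        # clip each consecutive pair, then draw per panel as fragments
        per_panel: list[list[Segment]] = [[] for _ in axes]
        for k in range(len(xs) - 1):
            seg = Segment((xs[k], ys[k]), (xs[k + 1], ys[k + 1]))
            for frag in clip_segment_to_slices(seg, layout):
                coord = frag.p0[0] if layout.axis == "x" else frag.p0[1]
                mid = coord if frag.p0 == frag.p1 else (
                    (frag.p0[0] + frag.p1[0]) / 2 if layout.axis == "x"
                    else (frag.p0[1] + frag.p1[1]) / 2
                )
                idx = layout.slice_index_of(mid)
                if idx is not None:
                    per_panel[idx].append(frag)
        for i, ax in enumerate(axes):
            frags = per_panel[i]
            if not frags:
                continue
            # stitch contiguous fragments into polylines for clean joins
            xs_out: list[float] = []
            ys_out: list[float] = []
            prev_end: Optional[tuple[float, float]] = None
            for frag in frags:
                if prev_end is not None and frag.p0 == prev_end:
                    xs_out.append(frag.p1[0]); ys_out.append(frag.p1[1])
                else:
                    if xs_out:
                        xs_out.append(np.nan); ys_out.append(np.nan)
                    xs_out.extend([frag.p0[0], frag.p1[0]])
                    ys_out.extend([frag.p0[1], frag.p1[1]])
                prev_end = frag.p1
            ax.plot(xs_out, ys_out, linestyle=ls, linewidth=lw, **kw)


def _draw_segments(axes, layer, df, plot, layout) -> None:
    for key in ("x", "y", "xend", "yend"):
        _require_column(layer, key)
    kw = _style_kwargs(layer)
    lw = float(layer.style.get("size", 1.0))
    ls = _LINESTYLES.get(layer.style.get("linetype", "solid"), "-")
    for _, row in df.iterrows():
        seg = Segment(
            (float(row[layer.mapping["x"]]), float(row[layer.mapping["y"]])),
            (float(row[layer.mapping["xend"]]), float(row[layer.mapping["yend"]])),
        )
        for frag in clip_segment_to_slices(seg, layout):
            mid = (
                (frag.p0[0] + frag.p1[0]) / 2
                if layout.axis == "x"
                else (frag.p0[1] + frag.p1[1]) / 2
            )
            idx = layout.slice_index_of(mid)
            if idx is None:
                continue
            axes[idx].plot(
                [frag.p0[0], frag.p1[0]], [frag.p0[1], frag.p1[1]],
                linestyle=ls, linewidth=lw, solid_capstyle="butt", **kw,
            )


def _draw_bars(axes, layer, df, plot, layout) -> None:
    value_axis, cat_axis = _bar_axes(layer)
    vcol = _require_column(layer, value_axis)
    ccol = _require_column(layer, cat_axis)
    baseline = float(layer.style.get("baseline", 0.0))
    if (plot.x_scale if value_axis == "x" else plot.y_scale) == "log10" and "baseline" not in layer.style:
        raise AxisBreakError(
            f"layer '{layer.source_id}': log10 value axis needs an explicit baseline"
        )
    width = float(layer.style.get("width", 0.8))
    kw = _style_kwargs(layer)
    kw.setdefault("color", "#4C72B0")
    broken_is_value = layout.axis == value_axis and layout.mode != "identity"
    for _, row in df.iterrows():
        cat = float(row[ccol])
        val = float(row[vcol])
        if broken_is_value:
            frags = clip_bar(cat, val, baseline, layout)
        else:
            idx = layout.slice_index_of(cat) if layout.mode != "identity" else 0
            if idx is None:
                continue
            lo, hi = min(baseline, val), max(baseline, val)
            if lo == hi:
                continue
            from .clipping import BarFragment

            frags = [BarFragment(cat, Interval(lo, hi), idx)]
        for frag in frags:
            ax = axes[frag.slice_index]
            vi = frag.value_interval
            if value_axis == "y":
                ax.bar([frag.category_position], [vi.span], bottom=vi.lo,
                       width=width, **kw)
            else:
                ax.barh([frag.category_position], [vi.span], left=vi.lo,
                        height=width, **kw)


def _draw_text(axes, layer, df, plot, layout) -> None:
    xcol = _require_column(layer, "x")
    ycol = _require_column(layer, "y")
    lcol = _require_column(layer, "label")
    pts = list(zip(df[xcol].to_numpy(float), df[ycol].to_numpy(float),
                   df[lcol].astype(str)))
    per_slice, _ = assign_point_layers(pts, layout)
    size = float(layer.style.get("size", 9.0))
    color = layer.style.get("color", "black")
    for i, ax in enumerate(axes):
        for x, y, label in per_slice[i]:
            ax.text(x, y, label, fontsize=size, color=color,
                    ha="center", va="center")


def _draw_reference(axes, layer, df, plot, layout) -> None:
    kw = _style_kwargs(layer)
    kw.setdefault("color", "black")
    lw = float(layer.style.get("size", 1.0))
    ls = _LINESTYLES.get(layer.style.get("linetype", "dashed"), "--")
    if "value" in layer.style:
        values = [float(layer.style["value"])]
        scale = plot.y_scale if layer.geom == "hline" else plot.x_scale
        if scale == "log10":
            values = [float(np.log10(v)) for v in values]
    else:
        key = "y" if layer.geom == "hline" else "x"
        values = list(df[_require_column(layer, key)].to_numpy(float))
    for v in values:
        line = ReferenceLine("hline" if layer.geom == "hline" else "vline", v)
        for idx, ln in replicate_reference_lines(line, layout):
            ax = axes[idx]
            if ln.kind == "hline":
                ax.axhline(ln.value, linestyle=ls, linewidth=lw, **kw)
            else:
                ax.axvline(ln.value, linestyle=ls, linewidth=lw, **kw)


def _draw_rects(axes, layer, df, plot, layout) -> None:
    for key in ("x", "y", "xend", "yend"):
        _require_column(layer, key)
    kw = _style_kwargs(layer)
    kw.setdefault("color", "#DD8452")
    kw.setdefault("alpha", 0.3)
    for _, row in df.iterrows():
        x0, x1 = sorted((float(row[layer.mapping["x"]]), float(row[layer.mapping["xend"]])))
        y0, y1 = sorted((float(row[layer.mapping["y"]]), float(row[layer.mapping["yend"]])))
        if x0 == x1 or y0 == y1:
            continue
        broken = Interval(x0, x1) if layout.axis == "x" else Interval(y0, y1)
        for i, s in enumerate(layout.slices):
            inter = broken.intersect(s.data)
            if inter is None:
                continue
            if layout.axis == "x":
                rect = Rectangle((inter.lo, y0), inter.span, y1 - y0,
                                 linewidth=0, **kw)
            else:
                rect = Rectangle((x0, inter.lo), x1 - x0, inter.span,
                                 linewidth=0, **kw)
            axes[i].add_patch(rect)


_DRAWERS = {
    "point": _draw_points,
    "line": _draw_lines,
    "segment": _draw_segments,
    "bar": _draw_bars,
    "text": _draw_text,
    "hline": _draw_reference,
    "vline": _draw_reference,
    "rect": _draw_rects,
}


# ---------------------------------------------------------------------------
# figure assembly


def build_figure(
    plot: PlotSpec,
    transform: Union[AxisBreakSpec, AxisCutSpec, WrapSpec, None] = None,
    width_in: float = 7.0,
    height_in: float = 5.0,
    dpi: int = 150,
) -> RenderedFigure:
    """Resolve the transform, place panels, clip and draw every layer.

    x-transforms produce side-by-side panels sharing the y range;
    y-transforms produce vertically stacked panels sharing the x range;
    wrap produces stacked rows (lowest sub-range on top) sharing the y
    range.  Panel pixel extents along the broken axis are proportional to
    the canvas band extents.  Explicit axis limits, when given, are
    interpreted in transformed (log) units if that axis uses log10.
    """
    # which axis carries the transform
    if isinstance(transform, (AxisBreakSpec, AxisCutSpec)):
        broken_axis = transform.axis
    else:
        broken_axis = "x"  # wrap folds x; identity defaults to x

    x_range = _compute_range(plot, "x")
    y_range = _compute_range(plot, "y")
    broken_range = x_range if broken_axis == "x" else y_range

    layout = resolve_layout(transform, broken_range)

    # shared (non-broken) axis: plain range with outer-edge padding
    shared_range = y_range if broken_axis == "x" else x_range
    shared_expanded = expand_outer_slices([shared_range])[0]

    fig = Figure(figsize=(width_in, height_in), dpi=dpi)
    FigureCanvasAgg(fig)
    fig.patch.set_facecolor("white")

    rects = _panel_rects(layout)
    axes = []
    for i, rect in enumerate(rects):
        ax = fig.add_axes(rect)
        ax.set_facecolor("white")
        ax.grid(True, linewidth=0.3, color="0.88", zorder=0)
        for spine in ax.spines.values():
            spine.set_linewidth(0.8)
        ax.set_axisbelow(True)
        axes.append(ax)

    # axis limits
    for i, (ax, s) in enumerate(zip(axes, layout.slices)):
        if layout.mode == "wrap" or broken_axis == "x":
            ax.set_xlim(s.data.lo, s.data.hi)
            ax.set_ylim(shared_expanded.lo, shared_expanded.hi)
        else:
            ax.set_ylim(s.data.lo, s.data.hi)
            ax.set_xlim(shared_expanded.lo, shared_expanded.hi)

    _apply_ticks(axes, layout, transform, shared_expanded, broken_axis)

    # draw layers
    for layer in plot.layers:
        if layer.data.empty:
            warnings.warn(
                f"layer '{layer.source_id}' has an empty table; skipped",
                BreakWarning,
                stacklevel=2,
            )
            continue
        df = _transformed_frame(layer, plot)
        _DRAWERS[layer.geom](axes, layer, df, plot, layout)

    _draw_labels_and_legend(fig, plot)

    width_px = int(round(width_in * dpi))
    height_px = int(round(height_in * dpi))
    panels = [
        PanelInfo(i, rect[0] * width_px, rect[1] * height_px,
                  rect[2] * width_px, rect[3] * height_px)
        for i, rect in enumerate(rects)
    ]
    rfig = RenderedFigure(panels=panels, figure=fig, layout=layout,
                          width_px=width_px, height_px=height_px)
    if layout.mode == "break":
        draw_break_marks(rfig, layout)
    return rfig


def _apply_ticks(axes, layout, transform, shared_expanded, broken_axis) -> None:
    overrides = transform.ticklabels if isinstance(transform, AxisBreakSpec) else None
    ticksets = dedupe_break_edge_ticks(apply_ticklabels(overrides, layout), layout)
    shared_ticks = default_ticks(shared_expanded, DEFAULT_TARGET)
    shared_labels = [format_tick(t) for t in shared_ticks]

    for i, (ax, ts) in enumerate(zip(axes, ticksets)):
        positions = [t[0] for t in ts.ticks]
        labels = [t[1] for t in ts.ticks]
        if layout.mode == "wrap":
            # each row draws its own x ticks; y is the shared axis
            ax.set_xticks(positions, labels, fontsize=8)
            ax.set_yticks(shared_ticks, shared_labels, fontsize=8)
        elif broken_axis == "x":
            ax.set_xticks(positions, labels, fontsize=8)
            ax.set_yticks(shared_ticks, shared_labels, fontsize=8)
            if i != 0:  # tick marks only on inner panels of the shared axis
                ax.tick_params(labelleft=False)
        else:
            ax.set_yticks(positions, labels, fontsize=8)
            ax.set_xticks(shared_ticks, shared_labels, fontsize=8)
            if i != 0:  # bottom panel (index 0: lowest data) keeps x labels
                ax.tick_params(labelbottom=False)


def _draw_labels_and_legend(fig: Figure, plot: PlotSpec) -> None:
    pw_center = _ML + (1.0 - _ML - _MR) / 2.0
    ph_center = _MB + (1.0 - _MB - _MT) / 2.0
    if plot.title:
        fig.text(pw_center, 1.0 - _MT / 2.0, plot.title,
                 ha="center", va="center", fontsize=12)
    if plot.x_label:
        fig.text(pw_center, _MB / 3.0, plot.x_label,
                 ha="center", va="center", fontsize=10)
    if plot.y_label:
        fig.text(_ML / 4.0, ph_center, plot.y_label,
                 ha="center", va="center", rotation=90, fontsize=10)
    # legend: entries deduplicated by (geom, label, color)
    handles, labels, seen = [], [], set()
    for layer in plot.layers:
        label = layer.style.get("label")
        if not label:
            continue
        color = layer.style.get("color", "#4C72B0")
        key = (layer.geom, label, color)
        if key in seen:
            continue
        seen.add(key)
        if layer.geom in ("bar", "rect"):
            handles.append(Patch(facecolor=color))
        elif layer.geom == "point":
            handles.append(Line2D([], [], linestyle="", marker="o", color=color))
        else:
            handles.append(Line2D([], [], color=color))
        labels.append(label)
    if handles:
        fig.legend(handles, labels, loc="upper right", frameon=False, fontsize=8)


def draw_break_marks(rfig: RenderedFigure, layout: SliceLayout) -> RenderedFigure:
    """Draw paired diagonal break glyphs beside every inter-panel gap.

    Break mode only — cut and wrap slices are contiguous in data, so their
    panel joins are not discontinuities and get no glyph.  Each gap
    produces two glyph pairs, one at each adjoining panel edge, on the
    broken axis line only.
    """
    if layout.mode != "break" or rfig.break_marks_drawn:
        return rfig
    fig = rfig.figure
    pw = 1.0 - _ML - _MR
    ph = 1.0 - _MB - _MT
    # px -> figure fraction
    dxf = BREAK_GLYPH_LEN_PX / rfig.width_px
    dyf = BREAK_GLYPH_LEN_PX / rfig.height_px
    sep_x = _GLYPH_PAIR_SEP_PX / rfig.width_px
    sep_y = _GLYPH_PAIR_SEP_PX / rfig.height_px
    k = 0
    for gi in range(layout.n - 1):
        edges = (layout.slices[gi].band.hi, layout.slices[gi + 1].band.lo)
        for edge in edges:
            if layout.axis == "x":
                cx = _ML + edge * pw
                cy = _MB
                for j in (0, 1):
                    x0 = cx - dxf / 2 + j * sep_x
                    line = Line2D(
                        [x0, x0 + dxf], [cy - dyf / 2, cy + dyf / 2],
                        transform=fig.transFigure, color="black",
                        linewidth=1.0, clip_on=False,
                    )
                    line.set_gid(f"break-glyph-{k}")
                    fig.add_artist(line)
                    k += 1
            else:
                cx = _ML
                cy = _MB + edge * ph
                for j in (0, 1):
                    y0 = cy - dyf / 2 + j * sep_y
                    line = Line2D(
                        [cx - dxf / 2, cx + dxf / 2], [y0, y0 + dyf],
                        transform=fig.transFigure, color="black",
                        linewidth=1.0, clip_on=False,
                    )
                    line.set_gid(f"break-glyph-{k}")
                    fig.add_artist(line)
                    k += 1
    rfig.break_marks_drawn = True
    rfig.svg = None  # invalidate any cached render
    return rfig


def render_svg(rfig: RenderedFigure) -> bytes:
    """Emit deterministic SVG 1.1 bytes (cached on the figure).

    No timestamps or random ids are embedded: the creation date is
    suppressed and element ids are derived from a fixed hash salt, so two
    renders of the same spec are byte-identical.
    """
    if rfig.svg is not None:
        return rfig.svg
    buf = io.BytesIO()
    try:
        with rc_context(_SVG_RC):
            rfig.figure.savefig(buf, format="svg", metadata={"Date": None})
    except OSError as exc:  # pragma: no cover - environment dependent
        raise AxisBreakError(f"SVG render failed: {exc}") from exc
    rfig.svg = buf.getvalue()
    return rfig.svg


def render_png(rfig: RenderedFigure, dpi: Optional[int] = None) -> bytes:
    """Emit PNG bytes at the figure's dpi (or an override)."""
    buf = io.BytesIO()
    kwargs = {} if dpi is None else {"dpi": dpi}
    try:
        rfig.figure.savefig(buf, format="png", **kwargs)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise AxisBreakError(f"PNG render failed: {exc}") from exc
    return buf.getvalue()
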