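"""Deterministic SVG rendering of heatmaps, scatters and histograms.

All renderers are pure functions of their inputs plus a style: the same
model renders to byte-identical SVG.  Plots never compute statistics —
every number shown is taken from the serialized model/report, and each
renderer writes a sidecar ``<path>.json`` with the plotted values.

Conventions follow the heatmap figures: the inner ring holds N
equal-angle wedges starting at 12 o'clock, clockwise; each group's two
outer wedges split the same angular span (first sample then second).
Wedges are grayscale; colour is reserved for group identity in the
scatter plot.  Labels use case to mark the sample: uppercase first
letter = sample A, lowercase = sample B (inner wedges show both, e.g.
"Pp"; outer wedges pair the group with its nearest group, "PS"/"ps").
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._errors import ConfigurationError
from .composition import GCHistogram
from .decomposition import LoadFactorReport, PCAResult
from .heatmap import PGHMModel

#: bar/word colours by GC class (all-GC red, no-GC blue, mixed green)
GC_CLASS_COLORS = {"all_gc": "#d62728", "no_gc": "#1f77b4", "mixed": "#2ca02c"}

_PALETTE = (
    "#1f77b4", "#d62728", "#e6b012", "#17becf", "#2ca02c", "#9467bd",
    "#ff7f0e", "#8c564b", "#e377c2", "#7f7f7f",
)


@dataclass
class PlotStyle:
    group_colors: Optional[dict[str, str]] = None
    figure_size: tuple[int, int] = (640, 640)
    font_family: str = "sans-serif"
    output_format: str = "svg"

    def colors_for(self, groups: Sequence[str]) -> dict[str, str]:
        if self.group_colors is not None:
            mapping = {g: self.group_colors[g] for g in groups}
        else:
            if len(groups) > len(_PALETTE):
                raise ConfigurationError("more groups than palette colours")
            mapping = {g: _PALETTE[i] for i, g in enumerate(groups)}
        if len(set(mapping.values())) != len(mapping):
            raise ConfigurationError("group colour map must be injective")
        return mapping


def _f(x: float) -> str:
    return f"{x:.3f}"


def _gray(shade: float) -> str:
    v = int(round(255 * min(max(shade, 0.0), 1.0)))
    return f"#{v:02x}{v:02x}{v:02x}"


def _svg_root(width: int, height: int) -> ET.Element:
    return ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": str(width),
        "height": str(height),
        "viewBox": f"0 0 {width} {height}",
    })


def _text(parent, x, y, s, size=12, anchor="middle", fill="#000000",
          family="sans-serif", transform=None) -> None:
    attrs = {
        "x": _f(x), "y": _f(y), "font-size": str(size),
        "text-anchor": anchor, "fill": fill, "font-family": family,
    }
    if transform:
        attrs["transform"] = transform
    el = ET.SubElement(parent, "text", attrs)
    el.text = s


def _write(root: ET.Element, path: str | Path) -> None:
    try:
        data = ET.tostring(root, encoding="unicode")
    except Exception as exc:  # pragma: no cover
        raise ConfigurationError(f"SVG serialization failed: {exc}") from exc
    Path(path).write_text('<?xml version="1.0" encoding="UTF-8"?>\n' + data + "\n")


def _sidecar(path: str | Path, payload: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # 0 deg = 12 o'clock, positive clockwise
    rad = math.radians(angle_deg - 90.0)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _sector_path(cx, cy, r, a0, a1) -> str:
    x0, y0 = _polar(cx, cy, r, a0)
    x1, y1 = _polar(cx, cy, r, a1)
    large = 1 if (a1 - a0) > 180.0 else 0
    return (f"M {_f(cx)} {_f(cy)} L {_f(x0)} {_f(y0)} "
            f"A {_f(r)} {_f(r)} 0 {large} 1 {_f(x1)} {_f(y1)} Z")


def _annular_path(cx, cy, r_in, r_out, a0, a1) -> str:
    xo0, yo0 = _polar(cx, cy, r_out, a0)
    xo1, yo1 = _polar(cx, cy, r_out, a1)
    xi1, yi1 = _polar(cx, cy, r_in, a1)
    xi0, yi0 = _polar(cx, cy, r_in, a0)
    large = 1 if (a1 - a0) > 180.0 else 0
    return (f"M {_f(xo0)} {_f(yo0)} "
            f"A {_f(r_out)} {_f(r_out)} 0 {large} 1 {_f(xo1)} {_f(yo1)} "
            f"L {_f(xi1)} {_f(yi1)} "
            f"A {_f(r_in)} {_f(r_in)} 0 {large} 0 {_f(xi0)} {_f(yi0)} Z")


def render_pghm(model: PGHMModel, style: Optional[PlotStyle] = None,
                path: str | Path = "pghm.svg") -> Path:
    """Concentric heatmap: N inner + 2N outer grayscale wedges plus a
    numeric legend bar."""
    style = style or PlotStyle()
    w, h = style.figure_size
    root = _svg_root(w, h)
    cx, cy = w / 2.0, h / 2.0 - 20
    r_in, r_out = 0.22 * min(w, h), 0.34 * min(w, h)
    n = model.n_groups
    span = 360.0 / n
    la, lb = model.sample_labels

    for i, wedge in enumerate(model.inner_wedges):
        a0, a1 = i * span, (i + 1) * span
        ET.SubElement(root, "path", {
            "d": _sector_path(cx, cy, r_in, a0, a1),
            "fill": _gray(wedge.shade),
            "stroke": "#000000", "stroke-width": "1",
            "class": "wedge wedge-inner",
            "id": f"inner-{wedge.group}",
        })
    for i, group in enumerate(model.groups):
        wa, wb = model.outer_pair(group)
        for half, wedge in enumerate((wa, wb)):
            a0 = i * span + half * span / 2.0
            a1 = a0 + span / 2.0
            ET.SubElement(root, "path", {
                "d": _annular_path(cx, cy, r_in, r_out, a0, a1),
                "fill": _gray(wedge.shade),
                "stroke": "#000000", "stroke-width": "1",
                "class": "wedge wedge-outer",
                "id": f"outer-{wedge.group}-{wedge.sample_label}",
            })
    # labels after all wedges so they stay on top
    for i, wedge in enumerate(model.inner_wedges):
        mid = (i + 0.5) * span
        x, y = _polar(cx, cy, 0.6 * r_in, mid)
        g0 = wedge.group[0]
        _text(root, x, y + 4, g0.upper() + g0.lower(), size=14,
              fill="#c03030", family=style.font_family)
    for i, group in enumerate(model.groups):
        wa, wb = model.outer_pair(group)
        for half, wedge in enumerate((wa, wb)):
            mid = i * span + (half + 0.5) * span / 2.0
            x, y = _polar(cx, cy, (r_in + r_out) / 2.0, mid)
            pair = wedge.group[0] + (wedge.nearest_group or "?")[0]
            label = pair.upper() if wedge.sample_label == la else pair.lower()
            _text(root, x, y + 4, label, size=12, fill="#c03030",
                  family=style.font_family)

    # grayscale legend with numeric ticks
    lx, ly, lw, lh = w * 0.15, h - 50.0, w * 0.7, 14.0
    steps = 50
    for s in range(steps):
        ET.SubElement(root, "rect", {
            "x": _f(lx + s * lw / steps), "y": _f(ly),
            "width": _f(lw / steps + 0.5), "height": _f(lh),
            "fill": _gray(s / (steps - 1)), "class": "legend",
        })
    ET.SubElement(root, "rect", {
        "x": _f(lx), "y": _f(ly), "width": _f(lw), "height": _f(lh),
        "fill": "none", "stroke": "#000000", "stroke-width": "1",
    })
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        _text(root, lx + frac * lw, ly + lh + 14, _f(frac), size=10,
              family=style.font_family)
    _text(root, cx, 24, f"{la} vs {lb} — {model.pattern}", size=14,
          family=style.font_family)

    _write(root, path)
    _sidecar(path, {
        "pattern": model.pattern,
        "inner": [w_.to_dict() for w_ in model.inner_wedges],
        "outer": [w_.to_dict() for w_ in model.outer_wedges],
    })
    return Path(path)


def render_pca_scatter(
    pca: PCAResult,
    sample_of: dict[str, str],
    group_of: dict[str, str],
    style: Optional[PlotStyle] = None,
    path: str | Path = "pca_scatter.svg",
) -> Path:
    """PC1 vs PC2 scatter; colour = group, marker fill = sample
    (solid boxes for the first sample label, empty for the second)."""
    if pca.n_components < 2:
        raise ConfigurationError("scatter needs at least 2 fitted components")
    style = style or PlotStyle()
    w, h = style.figure_size
    root = _svg_root(w, h)
    m = 60.0
    xs, ys = pca.scores[:, 0], pca.scores[:, 1]
    x0, x1 = float(xs.min()), float(xs.max())
    y0, y1 = float(ys.min()), float(ys.max())
    dx = (x1 - x0) or 1.0
    dy = (y1 - y0) or 1.0

    groups = sorted({group_of[r] for r in pca.read_ids if r in group_of})
    samples = sorted({sample_of[r] for r in pca.read_ids if r in sample_of})
    colors = style.colors_for(groups)

    ET.SubElement(root, "rect", {
        "x": _f(m), "y": _f(m), "width": _f(w - 2 * m), "height": _f(h - 2 * m),
        "fill": "none", "stroke": "#000000", "stroke-width": "1",
    })
    for rid, x, y in zip(pca.read_ids, xs, ys):
        if rid not in group_of or rid not in sample_of:
            continue
        px = m + (x - x0) / dx * (w - 2 * m)
        py = h - m - (y - y0) / dy * (h - 2 * m)
        solid = sample_of[rid] == samples[0]
        c = colors[group_of[rid]]
        ET.SubElement(root, "rect", {
            "x": _f(px - 2.5), "y": _f(py - 2.5), "width": "5", "height": "5",
            "fill": c if solid else "none",
            "stroke": c, "stroke-width": "1",
            "class": "point",
        })
    vx, vy = 100.0 * pca.variance_explained[0], 100.0 * pca.variance_explained[1]
    _text(root, w / 2, h - m / 3, f"PC1 ({vx:.1f}%)", family=style.font_family)
    _text(root, m / 3, h / 2, f"PC2 ({vy:.1f}%)", family=style.font_family,
          transform=f"rotate(-90 {_f(m / 3)} {_f(h / 2)})")
    for i, g in enumerate(groups):
        y = m + 16 + 16 * i
        ET.SubElement(root, "rect", {
            "x": _f(w - m - 110), "y": _f(y - 8), "width": "8", "height": "8",
            "fill": colors[g], "class": "legend-entry",
        })
        _text(root, w - m - 96, y, g, size=11, anchor="start",
              family=style.font_family)
    _write(root, path)
    _sidecar(path, {
        "variance_explained": [float(v) for v in pca.variance_explained],
        "groups": groups,
        "samples": samples,
        "n_points": len(pca.read_ids),
    })
    return Path(path)


def render_load_histogram(
    report: LoadFactorReport,
    style: Optional[PlotStyle] = None,
    path: str | Path = "load_histogram.svg",
) -> Path:
    """2m load-factor bars (positive block then negative block), coloured
    strictly by GC class, with word labels."""
    if not report.entries:
        raise ConfigurationError("empty load-factor report")
    style = style or PlotStyle()
    w, h = style.figure_size
    root = _svg_root(w, h)
    m = 60.0
    n = len(report.entries)
    vmax = max(abs(e.load_factor) for e in report.entries) or 1.0
    y_mid = h / 2.0
    scale = (h / 2.0 - m) / vmax
    bw = (w - 2 * m) / n
    for i, e in enumerate(report.entries):
        x = m + i * bw
        height = abs(e.load_factor) * scale
        y = y_mid - height if e.load_factor >= 0 else y_mid
        ET.SubElement(root, "rect", {
            "x": _f(x + 0.1 * bw), "y": _f(y),
            "width": _f(0.8 * bw), "height": _f(height),
            "fill": GC_CLASS_COLORS[e.gc_class],
            "class": "bar",
            "id": f"bar-{i}-{e.word}",
        })
        ly = y_mid + (12 if e.load_factor >= 0 else -6)
        _text(root, x + bw / 2, ly, e.word, size=7,
              family=style.font_family,
              transform=f"rotate(-90 {_f(x + bw / 2)} {_f(ly)})")
    ET.SubElement(root, "line", {
        "x1": _f(m), "y1": _f(y_mid), "x2": _f(w - m), "y2": _f(y_mid),
        "stroke": "#000000", "stroke-width": "1",
    })
    _text(root, w / 2, m / 2,
          f"PC{report.component + 1} load factors (top/bottom {report.m})",
          family=style.font_family)
    _write(root, path)
    _sidecar(path, {"entries": [
        {"word": e.word, "load_factor": e.load_factor, "gc_class": e.gc_class}
        for e in report.entries]})
    return Path(path)


def render_gc_distribution(
    histograms: Sequence[GCHistogram],
    style: Optional[PlotStyle] = None,
    path: str | Path = "gc_distribution.svg",
) -> Path:
    """Overlaid per-sample GC% frequency curves with annotated modes."""
    if not histograms:
        raise ConfigurationError("need at least one GC histogram")
    style = style or PlotStyle()
    w, h = style.figure_size
    root = _svg_root(w, h)
    m = 60.0
    cmax = max(int(hist.counts.max()) for hist in histograms) or 1
    curve_colors = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd"]

    ET.SubElement(root, "rect", {
        "x": _f(m), "y": _f(m), "width": _f(w - 2 * m), "height": _f(h - 2 * m),
        "fill": "none", "stroke": "#000000", "stroke-width": "1",
    })
    for hi, hist in enumerate(histograms):
        pts = []
        for c, v in zip(hist.bin_centers, hist.counts):
            px = m + c / 100.0 * (w - 2 * m)
            py = h - m - (v / cmax) * (h - 2 * m)
            pts.append(f"{_f(px)},{_f(py)}")
        color = curve_colors[hi % len(curve_colors)]
        ET.SubElement(root, "polyline", {
            "points": " ".join(pts),
            "fill": "none", "stroke": color, "stroke-width": "1.5",
            "class": "curve", "id": f"curve-{hist.sample_label}",
        })
        mx = m + hist.modal_bin_center / 100.0 * (w - 2 * m)
        ET.SubElement(root, "circle", {
            "cx": _f(mx), "cy": _f(m + 12 + 14 * hi), "r": "3",
            "fill": color, "class": "mode-marker",
        })
        _text(root, mx + 8, m + 16 + 14 * hi,
              f"{hist.sample_label}: mode {hist.modal_bin_center:.2f}%",
              size=10, anchor="start", family=style.font_family)
    _text(root, w / 2, h - m / 3, "GC content (%)", family=style.font_family)
    _write(root, path)
    _sidecar(path, {"series": [
        {"sample": hist.sample_label,
         "modal_bin_center": hist.modal_bin_center,
         "bin_centers": [float(c) for c in hist.bin_centers],
         "counts": [int(c) for c in hist.counts]}
        for hist in histograms]})
    return Path(path)
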