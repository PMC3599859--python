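"""Render SBGN maps to SVG and build side-by-side comparison pages.

Every glyph class is drawn natively as an SVG shape or path following
the SBGN reference cards (rounded rectangles for macromolecules, circles
for simple chemicals, cut-corner boxes for complexes, small squares for
processes, hexagons for phenotypes, ...), and every arc class gets its
class-specific terminal decoration (filled triangle for production,
open triangle for stimulation, bar for inhibition, circle for catalysis,
bar+triangle for necessary stimulation, doubled marks for the absolute
classes, ...).

Two style profiles are provided: ``sbgn`` (terminal decorations filled
white, the reference-card style) and ``cytoscape`` (decorations filled
black, reproducing the look of Cytoscape edge renderers).  Compartments
are always drawn first with transparent fill, so enclosed glyphs stay
visible and z-order is deterministic back-to-front.

Output is deterministic: the same map and style always produce the same
bytes.
"""

from __future__ import annotations

import html
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .core_model import Arc, Glyph, SbgnMap
from .errors import StructuralError

__all__ = ["StyleProfile", "SBGN_STYLE", "CYTOSCAPE_STYLE", "render_svg",
           "compare_matrix"]


@dataclass(frozen=True)
class StyleProfile:
    """Colours and strokes for one rendering style."""

    name: str
    arrowhead_fill: str           # terminal decoration fill, all arc classes
    compartment_transparent: bool = True
    stroke: str = "#000000"
    node_fill: str = "#ffffff"
    font_family: str = "sans-serif"
    font_size: float = 11.0


SBGN_STYLE = StyleProfile(name="sbgn", arrowhead_fill="#ffffff")
CYTOSCAPE_STYLE = StyleProfile(name="cytoscape", arrowhead_fill="#000000")

_STYLES = {"sbgn": SBGN_STYLE, "cytoscape": CYTOSCAPE_STYLE}


def style_by_name(name: str) -> StyleProfile:
    try:
        return _STYLES[name]
    except KeyError:
        raise ValueError(f"unknown style profile {name!r} "
                         f"(choose from {sorted(_STYLES)})")


def _esc(s: str) -> str:
    return html.escape(s, quote=True)


def _num(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# Glyph shapes

def _rect(b, rx=0.0, fill="#ffffff", stroke="#000000", dash=None) -> str:
    extra = f' rx="{_num(rx)}"' if rx else ""
    if dash:
        extra += f' stroke-dasharray="{dash}"'
    return (f'<rect x="{_num(b.x)}" y="{_num(b.y)}" width="{_num(b.w)}" '
            f'height="{_num(b.h)}" fill="{fill}" stroke="{stroke}"{extra}/>')


def _ellipse(b, fill, stroke) -> str:
    cx, cy = b.center
    return (f'<ellipse cx="{_num(cx)}" cy="{_num(cy)}" rx="{_num(b.w / 2)}" '
            f'ry="{_num(b.h / 2)}" fill="{fill}" stroke="{stroke}"/>')


def _polygon(points, fill, stroke) -> str:
    pts = " ".join(f"{_num(x)},{_num(y)}" for x, y in points)
    return f'<polygon points="{pts}" fill="{fill}" stroke="{stroke}"/>'


def _hexagon(b):
    inset = min(b.w * 0.2, b.h)
    return [(b.x + inset, b.y), (b.x + b.w - inset, b.y),
            (b.x + b.w, b.y + b.h / 2), (b.x + b.w - inset, b.y + b.h),
            (b.x + inset, b.y + b.h), (b.x, b.y + b.h / 2)]


def _cut_rect(b, cut):
    return [(b.x + cut, b.y), (b.x + b.w - cut, b.y), (b.x + b.w, b.y + cut),
            (b.x + b.w, b.y + b.h - cut), (b.x + b.w - cut, b.y + b.h),
            (b.x + cut, b.y + b.h), (b.x, b.y + b.h - cut), (b.x, b.y + cut)]


def _tag_shape(b, orientation):
    point = min(b.w * 0.25, b.h / 2)
    if orientation == "left":
        return [(b.x + b.w, b.y), (b.x + point, b.y), (b.x, b.y + b.h / 2),
                (b.x + point, b.y + b.h), (b.x + b.w, b.y + b.h)]
    return [(b.x, b.y), (b.x + b.w - point, b.y), (b.x + b.w, b.y + b.h / 2),
            (b.x + b.w - point, b.y + b.h), (b.x, b.y + b.h)]


def _glyph_shape(g: Glyph, style: StyleProfile) -> list[str]:
    b = g.bbox
    fill, stroke = style.node_fill, style.stroke
    cls = g.cls
    out: list[str] = []
    if cls == "compartment":
        comp_fill = "none" if style.compartment_transparent else fill
        out.append(_rect(b, rx=min(12.0, b.h / 4), fill=comp_fill,
                         stroke=stroke))
    elif cls in ("macromolecule", "macromolecule multimer",
                 "biological activity", "annotation"):
        out.append(_rect(b, rx=8.0 if cls != "biological activity" else 0.0,
                         fill=fill, stroke=stroke))
    elif cls in ("simple chemical", "simple chemical multimer"):
        out.append(_ellipse(b, fill, stroke))
    elif cls in ("unspecified entity", "outcome", "interaction", "delay",
                 "and", "or", "not", "implicit xor", "existence", "location"):
        out.append(_ellipse(b, fill if cls != "outcome" else stroke, stroke))
        text = {"and": "AND", "or": "OR", "not": "NOT", "delay": "τ",
                "implicit xor": "XOR"}.get(cls)
        if text:
            cx, cy = b.center
            out.append(f'<text x="{_num(cx)}" y="{_num(cy + 3)}" '
                       f'text-anchor="middle" font-size="10">{text}</text>')
    elif cls in ("nucleic acid feature", "nucleic acid feature multimer"):
        r = min(10.0, b.h / 3)
        d = (f"M {_num(b.x)} {_num(b.y)} H {_num(b.x + b.w)} "
             f"V {_num(b.y + b.h - r)} Q {_num(b.x + b.w)} {_num(b.y + b.h)} "
             f"{_num(b.x + b.w - r)} {_num(b.y + b.h)} H {_num(b.x + r)} "
             f"Q {_num(b.x)} {_num(b.y + b.h)} {_num(b.x)} {_num(b.y + b.h - r)} Z")
        out.append(f'<path d="{d}" fill="{fill}" stroke="{stroke}"/>')
    elif cls in ("complex", "complex multimer"):
        out.append(_polygon(_cut_rect(b, min(10.0, b.h / 4)), fill, stroke))
    elif cls in ("process", "omitted process", "uncertain process"):
        out.append(_rect(b, fill=fill, stroke=stroke))
        mark = {"omitted process": "\\\\", "uncertain process": "?"}.get(cls)
        if mark:
            cx, cy = b.center
            out.append(f'<text x="{_num(cx)}" y="{_num(cy + 4)}" '
                       f'text-anchor="middle" font-size="12">{_esc(mark)}</text>')
    elif cls == "association":
        out.append(_ellipse(b, stroke, stroke))
    elif cls == "dissociation":
        cx, cy = b.center
        out.append(_ellipse(b, "none", stroke))
        out.append(f'<circle cx="{_num(cx)}" cy="{_num(cy)}" '
                   f'r="{_num(min(b.w, b.h) / 4)}" fill="none" '
                   f'stroke="{stroke}"/>')
    elif cls == "source and sink":
        cx, cy = b.center
        r = min(b.w, b.h) / 2
        out.append(f'<circle cx="{_num(cx)}" cy="{_num(cy)}" r="{_num(r)}" '
                   f'fill="none" stroke="{stroke}"/>')
        out.append(f'<line x1="{_num(cx - r)}" y1="{_num(cy + r)}" '
                   f'x2="{_num(cx + r)}" y2="{_num(cy - r)}" '
                   f'stroke="{stroke}"/>')
    elif cls in ("phenotype",):
        out.append(_polygon(_hexagon(b), fill, stroke))
    elif cls in ("perturbing agent", "perturbation"):
        inset = min(b.w * 0.2, b.h / 2)
        pts = [(b.x, b.y), (b.x + b.w, b.y), (b.x + b.w - inset, b.y + b.h / 2),
               (b.x + b.w, b.y + b.h), (b.x, b.y + b.h),
               (b.x + inset, b.y + b.h / 2)]
        out.append(_polygon(pts, fill, stroke))
    elif cls in ("tag", "terminal"):
        out.append(_polygon(_tag_shape(b, g.orientation or "right"),
                            fill, stroke))
    elif cls == "submap":
        out.append(_rect(b, fill=fill, stroke=stroke, dash="4 2"))
    elif cls in ("state variable", "variable value"):
        out.append(_ellipse(b, fill, stroke))
    elif cls in ("unit of information", "cardinality"):
        out.append(_rect(b, fill=fill, stroke=stroke))
    else:  # unreachable for catalog classes; safe fallback for extensions
        out.append(_rect(b, fill=fill, stroke=stroke, dash="2 2"))

    multimer = cls.endswith("multimer")
    if multimer:
        shadow = f'<rect x="{_num(b.x + 5)}" y="{_num(b.y + 5)}" ' \
                 f'width="{_num(b.w)}" height="{_num(b.h)}" fill="none" ' \
                 f'stroke="{stroke}"/>'
        out.insert(0, shadow)
    if g.clone:
        band_h = b.h * 0.25
        out.append(f'<rect x="{_num(b.x)}" y="{_num(b.y + b.h - band_h)}" '
                   f'width="{_num(b.w)}" height="{_num(band_h)}" '
                   f'fill="#666666" stroke="none"/>')
    if g.label and cls not in ("and", "or", "not"):
        cx, cy = b.center
        out.append(f'<text x="{_num(cx)}" y="{_num(cy + style.font_size / 3)}" '
                   f'text-anchor="middle" font-family="{style.font_family}" '
                   f'font-size="{_num(style.font_size)}">{_esc(g.label)}</text>')
    return out


# ---------------------------------------------------------------------------
# Arc terminals

def _unit(dx: float, dy: float) -> tuple[float, float]:
    n = math.hypot(dx, dy) or 1.0
    return dx / n, dy / n

def _terminal(cls: str, end: tuple[float, float], frm: tuple[float, float],
              style: StyleProfile) -> list[str]:
    """Terminal decoration drawn at ``end`` for an arc arriving from ``frm``."""
    ux, uy = _unit(end[0] - frm[0], end[1] - frm[1])
    px, py = -uy, ux  # perpendicular
    ex, ey = end
    s = 8.0  # decoration size
    fill = style.arrowhead_fill
    stroke = style.stroke

    def tri(tip, back_offset):
        bx, by = tip[0] - ux * s - ux * back_offset, \
            tip[1] - uy * s - uy * back_offset
        return [(tip[0] - ux * back_offset, tip[1] - uy * back_offset),
                (bx + px * s / 2, by + py * s / 2),
                (bx - px * s / 2, by - py * s / 2)]

    def bar(offset):
        bx, by = ex - ux * offset, ey - uy * offset
        return (f'<line x1="{_num(bx + px * s / 2)}" y1="{_num(by + py * s / 2)}" '
                f'x2="{_num(bx - px * s / 2)}" y2="{_num(by - py * s / 2)}" '
                f'stroke="{stroke}" stroke-width="1.5"/>')

    out: list[str] = []
    if cls in ("production", "assignment"):
        out.append(_polygon(tri((ex, ey), 0), stroke, stroke))
    elif cls in ("stimulation", "positive influence"):
        out.append(_polygon(tri((ex, ey), 0), fill, stroke))
    elif cls == "absolute stimulation":
        out.append(_polygon(tri((ex, ey), 0), fill, stroke))
        out.append(_polygon(tri((ex - ux * (s + 2), ey - uy * (s + 2)), 0),
                            fill, stroke))
    elif cls in ("inhibition", "negative influence"):
        out.append(bar(0))
    elif cls == "absolute inhibition":
        out.append(bar(0))
        out.append(bar(4))
    elif cls == "catalysis":
        r = s / 2
        out.append(f'<circle cx="{_num(ex - ux * r)}" cy="{_num(ey - uy * r)}" '
                   f'r="{_num(r)}" fill="{fill}" stroke="{stroke}"/>')
    elif cls in ("modulation",):
        half = s / 2
        pts = [(ex, ey), (ex - ux * half + px * half, ey - uy * half + py * half),
               (ex - ux * s, ey - uy * s),
               (ex - ux * half - px * half, ey - uy * half - py * half)]
        out.append(_polygon(pts, fill, stroke))
    elif cls == "necessary stimulation":
        out.append(_polygon(tri((ex, ey), 0), fill, stroke))
        out.append(bar(s + 3))
    elif cls in ("unknown influence", "interaction"):
        half = s / 2
        pts = [(ex, ey), (ex - ux * half + px * half, ey - uy * half + py * half),
               (ex - ux * s, ey - uy * s),
               (ex - ux * half - px * half, ey - uy * half - py * half)]
        out.append(_polygon(pts, "none" if cls == "interaction" else fill,
                            stroke))
    # consumption, logic arc, equivalence arc: plain line, no decoration
    return out


def _render_arc(a: Arc, style: StyleProfile) -> str:
    points = [a.start] + list(a.bends) + [a.end]
    pts = " ".join(f"{_num(x)},{_num(y)}" for x, y in points)
    parts = [f'<polyline points="{pts}" fill="none" stroke="{style.stroke}"/>']
    parts += _terminal(a.cls, a.end, points[-2], style)
    if a.cardinality is not None:
        mx = (a.start[0] + a.end[0]) / 2
        my = (a.start[1] + a.end[1]) / 2
        parts.append(f'<text x="{_num(mx)}" y="{_num(my - 4)}" '
                     f'text-anchor="middle" font-size="9">'
                     f'{a.cardinality}</text>')
    body = "\n    ".join(parts)
    return (f'  <g id="arc_{_esc(a.id)}" class="{_esc(a.cls.replace(" ", "-"))}">'
            f'\n    {body}\n  </g>')


# ---------------------------------------------------------------------------
# Document assembly

def _render_glyph_group(g: Glyph, style: StyleProfile,
                        coverage: Optional[dict], indent: str = "  ") -> str:
    if coverage is not None:
        coverage[g.cls] = coverage.get(g.cls, 0) + 1
    shapes = "\n".join(f"{indent}  {s}" for s in _glyph_shape(g, style))
    children = "\n".join(
        _render_glyph_group(c, style, coverage, indent + "  ")
        for c in g.children)
    body = shapes + (("\n" + children) if children else "")
    return (f'{indent}<g id="glyph_{_esc(g.id)}" '
            f'class="{_esc(g.cls.replace(" ", "-"))}">\n'
            f'{body}\n{indent}</g>')


def render_svg(map: SbgnMap, style: StyleProfile = SBGN_STYLE,
               coverage: Optional[dict] = None) -> str:
    """Render a map to an SVG 1.1 document string.

    One ``<g>`` per glyph (id ``glyph_<id>``) and per arc (``arc_<id>``);
    compartments are emitted first (backmost, largest first), then the
    remaining glyphs in document order, then arcs.  ``coverage``, when
    given, is a dict counter updated with every glyph and arc class
    drawn.
    """
    zero = [g.id for g in map.iter_glyphs()
            if g.bbox.w <= 0 or g.bbox.h <= 0]
    if zero:
        raise StructuralError(
            "glyphs with non-positive extent cannot be rendered: "
            + ", ".join(sorted(zero)))

    xs, ys, x2s, y2s = [0.0], [0.0], [100.0], [100.0]
    for g in map.iter_glyphs():
        xs.append(g.bbox.x); ys.append(g.bbox.y)
        x2s.append(g.bbox.x + g.bbox.w); y2s.append(g.bbox.y + g.bbox.h)
    pad = 20.0
    width, height = max(x2s) + pad, max(y2s) + pad

    compartments = sorted(
        (g for g in map.glyphs if g.cls == "compartment"),
        key=lambda g: (-g.bbox.w * g.bbox.h, g.id))
    rest = [g for g in map.glyphs if g.cls != "compartment"]

    groups = [_render_glyph_group(g, style, coverage)
              for g in compartments + rest]
    if coverage is not None:
        for a in map.arcs:
            coverage[a.cls] = coverage.get(a.cls, 0) + 1
    arcs = [_render_arc(a, style) for a in map.arcs]

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_num(width)}" height="{_num(height)}" '
        f'viewBox="0 0 {_num(width)} {_num(height)}">',
        f'  <title>{_esc(map.language.value)} map</title>',
    ]
    parts += groups + arcs + ["</svg>"]
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Comparison matrix

def compare_matrix(cases: dict[str, SbgnMap], out_dir,
                   reference_dir=None,
                   tool_dirs: Optional[dict[str, os.PathLike]] = None,
                   style: StyleProfile = SBGN_STYLE) -> Path:
    """Write fresh SVG renders plus a side-by-side comparison HTML page.

    One row per test case, one column per image source: the reference
    drawing first, one column per external tool, and this package's
    fresh render last.  Cells whose image file does not exist are marked
    "missing", never omitted.  Returns the path of the HTML page.
    """
    out = Path(out_dir)
    renders = out / "renders"
    renders.mkdir(parents=True, exist_ok=True)
    tool_dirs = dict(tool_dirs or {})

    columns = ["reference"] + sorted(tool_dirs) + ["sbgngraph"]

    def cell(directory, name: str) -> str:
        if directory is None:
            return '<td class="missing">missing</td>'
        for ext in (".svg", ".png"):
            p = Path(directory) / f"{name}{ext}"
            if p.exists():
                rel = os.path.relpath(p, out)
                return f'<td><img src="{_esc(rel)}" alt="{_esc(name)}"/></td>'
        return '<td class="missing">missing</td>'

    rows = []
    for name in sorted(cases):
        svg_path = renders / f"{name}.svg"
        svg_path.write_text(render_svg(cases[name], style))
        cells = [cell(reference_dir, name)]
        cells += [cell(tool_dirs[t], name) for t in sorted(tool_dirs)]
        rel = os.path.relpath(svg_path, out)
        cells.append(f'<td><img src="{_esc(rel)}" alt="{_esc(name)}"/></td>')
        rows.append(f'  <tr><th>{_esc(name)}</th>' + "".join(cells) + "</tr>")

    header = "".join(f"<th>{_esc(c)}</th>" for c in columns)
    page = "\n".join([
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8"/>',
        "<title>SBGN rendering comparison</title>",
        "<style>td,th{border:1px solid #999;padding:4px;} "
        "td.missing{color:#a00;} img{max-width:260px;}</style>",
        "</head><body>",
        "<h1>SBGN rendering comparison</h1>",
        '<table><tr><th>case</th>' + header + "</tr>",
        *rows,
        "</table></body></html>",
    ]) + "\n"
    out_path = out / "comparison.html"
    out_path.write_text(page)
    return out_path
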