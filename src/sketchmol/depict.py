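"""SVG depiction of a connection table.

Renders the way a depiction-only structure viewer draws: black bonds on a
white canvas, carbon vertices bare, heteroatoms/charged/isolated atoms as
text labels, double and triple bonds as parallel lines, wedge (filled
triangle) and hash (ladder of shortening strokes) stereo bonds, and
move/zoom through an offset and a zoom factor on top of an automatic
fit-to-canvas transform.

Output is deterministic: identical molecule and options give byte-identical
SVG.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from xml.etree import ElementTree as ET

from . import geometry
from .model import Molecule, SketchError, Stereo, atom_label

# Visual constants, as fractions of the reference bond length.
FONT_SIZE_FACTOR = 0.6
DOUBLE_BOND_OFFSET = 0.18
WEDGE_HALF_WIDTH = 0.15
LABEL_CLEARANCE = 0.35
HASH_COUNT = 6

_SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class RenderOptions:
    width: float = 400.0
    height: float = 300.0
    margin: float = 20.0
    zoom: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)


def _fmt(v: float) -> str:
    return f"{v + 0.0:.2f}"  # +0.0 folds -0.0 into 0.0


def reference_bond_length(mol: Molecule) -> float:
    """Median drawn bond length, or the standard length if there are no
    bonds — the yardstick for fonts, offsets and wedges."""
    lengths = []
    for b in mol.bonds:
        a1, a2 = mol.atom(b.a1), mol.atom(b.a2)
        d = math.dist((a1.x, a1.y), (a2.x, a2.y))
        if d > 0:
            lengths.append(d)
    return statistics.median(lengths) if lengths else geometry.BOND_LENGTH


def fit_transform(
    mol: Molecule, width: float, height: float, margin: float
) -> tuple[float, tuple[float, float]]:
    """Scale and offset mapping model coordinates into the canvas.

    Screen position is ``(scale*x + ox, -scale*y + oy)`` — the y axis flips
    because model y grows upwards and SVG y grows downwards.  The bounding
    box lands centred inside the margin, aspect ratio preserved; a single
    atom (degenerate box) is centred at unit scale.
    """
    atoms = mol.atoms
    if not atoms:
        raise SketchError("cannot fit an empty molecule")
    xs = [a.x for a in atoms]
    ys = [a.y for a in atoms]
    bw, bh = max(xs) - min(xs), max(ys) - min(ys)
    avail_w, avail_h = width - 2 * margin, height - 2 * margin
    if avail_w <= 0 or avail_h <= 0:
        raise SketchError("margin leaves no drawing area")
    if bw <= 0 and bh <= 0:
        scale = 1.0
    else:
        sx = avail_w / bw if bw > 0 else math.inf
        sy = avail_h / bh if bh > 0 else math.inf
        scale = min(sx, sy)
    cx, cy = (max(xs) + min(xs)) / 2, (max(ys) + min(ys)) / 2
    return scale, (width / 2 - scale * cx, height / 2 + scale * cy)


def render_svg(mol: Molecule, options: RenderOptions | None = None, **kwargs) -> str:
    """Render a molecule to SVG 1.1 text.

    Keyword arguments override individual :class:`RenderOptions` fields.
    An empty molecule renders a valid empty canvas.
    """
    if options is None:
        options = RenderOptions(**kwargs)
    elif kwargs:
        raise TypeError("pass either options or keyword overrides, not both")
    if options.width <= 0 or options.height <= 0:
        raise SketchError("canvas dimensions must be positive")
    if options.zoom <= 0:
        raise SketchError("zoom must be positive")

    root = ET.Element(
        "svg",
        {
            "xmlns": _SVG_NS,
            "version": "1.1",
            "width": _fmt(options.width),
            "height": _fmt(options.height),
            "viewBox": f"0 0 {_fmt(options.width)} {_fmt(options.height)}",
        },
    )
    ET.SubElement(
        root,
        "rect",
        {
            "x": "0",
            "y": "0",
            "width": _fmt(options.width),
            "height": _fmt(options.height),
            "fill": "white",
        },
    )
    if len(mol) > 0:
        _render_body(root, mol, options)
    return ET.tostring(root, encoding="unicode") + "\n"


def _render_body(root, mol: Molecule, options: RenderOptions) -> None:
    fit_scale, (ox, oy) = fit_transform(
        mol, options.width, options.height, options.margin
    )
    scale = fit_scale * options.zoom
    # zoom about the canvas centre, then apply the user pan offset
    zc = 1 - options.zoom
    ox = options.zoom * ox + zc * options.width / 2 + options.offset[0]
    oy = options.zoom * oy + zc * options.height / 2 + options.offset[1]

    def to_screen(x: float, y: float) -> tuple[float, float]:
        return (scale * x + ox, -scale * y + oy)

    ref = reference_bond_length(mol) * scale  # reference length in pixels
    font_size = FONT_SIZE_FACTOR * ref
    labels = {a.id: atom_label(mol, a.id) for a in mol.atoms}

    stroke = max(1.0, 0.04 * ref)
    bonds_group = ET.SubElement(
        root,
        "g",
        {
            "class": "bonds",
            "stroke": "black",
            "stroke-width": _fmt(stroke),
            "stroke-linecap": "round",
        },
    )
    for bond in mol.bonds:
        a1, a2 = mol.atom(bond.a1), mol.atom(bond.a2)
        p1, p2 = to_screen(a1.x, a1.y), to_screen(a2.x, a2.y)
        p1 = _shorten(p1, p2, LABEL_CLEARANCE * ref if labels[a1.id] else 0.0)
        p2 = _shorten(p2, p1, LABEL_CLEARANCE * ref if labels[a2.id] else 0.0)
        group = ET.SubElement(
            bonds_group,
            "g",
            {
                "class": "bond",
                "data-order": str(bond.order),
                "data-stereo": bond.stereo.name.lower(),
            },
        )
        if bond.stereo is Stereo.UP:
            _wedge(group, p1, p2, WEDGE_HALF_WIDTH * ref)
        elif bond.stereo is Stereo.DOWN:
            _hash_wedge(group, p1, p2, WEDGE_HALF_WIDTH * ref)
        elif bond.order == 1:
            _line(group, p1, p2)
        elif bond.order == 2:
            half = DOUBLE_BOND_OFFSET * ref / 2
            _line(group, *_offset_pair(p1, p2, half))
            _line(group, *_offset_pair(p1, p2, -half))
        else:  # triple
            _line(group, p1, p2)
            off = DOUBLE_BOND_OFFSET * ref
            _line(group, *_offset_pair(p1, p2, off))
            _line(group, *_offset_pair(p1, p2, -off))

    labelled = [a for a in mol.atoms if labels[a.id]]
    if labelled:
        text_group = ET.SubElement(
            root,
            "g",
            {
                "class": "labels",
                "font-family": "Helvetica, Arial, sans-serif",
                "font-size": _fmt(font_size),
                "fill": "black",
                "text-anchor": "middle",
            },
        )
        for a in labelled:
            px, py = to_screen(a.x, a.y)
            el = ET.SubElement(
                text_group,
                "text",
                {
                    "x": _fmt(px),
                    "y": _fmt(py),
                    "dominant-baseline": "central",
                    "data-atom": str(a.id),
                },
            )
            el.text = labels[a.id]


def _shorten(p: tuple[float, float], towards: tuple[float, float], by: float):
    """Pull ``p`` towards the other endpoint to clear a text label."""
    if by <= 0:
        return p
    d = math.dist(p, towards)
    if d <= by * 2:
        return p
    t = by / d
    return (p[0] + (towards[0] - p[0]) * t, p[1] + (towards[1] - p[1]) * t)


def _offset_pair(p1, p2, offset):
    d = math.dist(p1, p2)
    if d == 0:
        return p1, p2
    nx, ny = -(p2[1] - p1[1]) / d, (p2[0] - p1[0]) / d
    return (
        (p1[0] + nx * offset, p1[1] + ny * offset),
        (p2[0] + nx * offset, p2[1] + ny * offset),
    )


def _line(group, p1, p2):
    ET.SubElement(
        group,
        "line",
        {
            "x1": _fmt(p1[0]),
            "y1": _fmt(p1[1]),
            "x2": _fmt(p2[0]),
            "y2": _fmt(p2[1]),
        },
    )


def _wedge(group, narrow, wide, half_width):
    """Filled wedge: apex at the bond's first atom, wide at the second."""
    (w1x, w1y), (w2x, w2y) = _wedge_flanks(narrow, wide, half_width)
    points = (
        f"{_fmt(narrow[0])},{_fmt(narrow[1])} "
        f"{_fmt(w1x)},{_fmt(w1y)} {_fmt(w2x)},{_fmt(w2y)}"
    )
    ET.SubElement(group, "polygon", {"points": points, "fill": "black"})


def _hash_wedge(group, narrow, wide, half_width):
    """Hashed wedge: perpendicular strokes widening towards the far atom."""
    for k in range(1, HASH_COUNT + 1):
        t = k / HASH_COUNT
        cx = narrow[0] + (wide[0] - narrow[0]) * t
        cy = narrow[1] + (wide[1] - narrow[1]) * t
        h = half_width * t
        d = math.dist(narrow, wide)
        if d == 0:
            continue
        nx, ny = -(wide[1] - narrow[1]) / d, (wide[0] - narrow[0]) / d
        _line(group, (cx - nx * h, cy - ny * h), (cx + nx * h, cy + ny * h))


def _wedge_flanks(narrow, wide, half_width):
    d = math.dist(narrow, wide)
    if d == 0:
        return (wide, wide)
    nx, ny = -(wide[1] - narrow[1]) / d, (wide[0] - narrow[0]) / d
    return (
        (wide[0] + nx * half_width, wide[1] + ny * half_width),
        (wide[0] - nx * half_width, wide[1] - ny * half_width),
    )
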