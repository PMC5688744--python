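"""Reading and writing layouts: native TSV, VARNA-style SVG and PS.

The native template exchange format is a plain TSV document: comment
headers carrying the geometry constants, then one record per residue
(0-based index, letter, x, y, partner index or -1, status code).  A
minimal VARNA-flavoured SVG reader is provided for interoperability:
residue letters and coordinates are taken from ``text`` elements in
document order (5'->3'), base pairs from ``line`` elements whose
endpoints are matched to the nearest residue centers.

All writers are deterministic: identical inputs produce byte-identical
files (floats use shortest 6-significant-digit formatting).  The SVG
writer flips y to the screen-down convention; the PS writer keeps y up.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from lxml import etree

from .layout_engine import (
    INSERTED,
    RELABELED,
    SHIFTED,
    UNCHANGED,
    Geometry,
    Layout,
    TemplateDocument,
    document_from_layout,
)
from .structure_model import ParseError, SecondaryStructure

__all__ = [
    "read_layout_tsv",
    "write_layout_tsv",
    "read_varna_svg",
    "write_svg",
    "write_ps",
]

_STATUSES = (UNCHANGED, INSERTED, RELABELED, SHIFTED)
_COLORS = {
    INSERTED: "#FF0000",
    RELABELED: "#008000",
    SHIFTED: "#0000FF",
    UNCHANGED: "#000000",
}
_OVERLAP_COLOR = "#FF00FF"


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


# ----------------------------------------------------------------------
# native TSV layout


def write_layout_tsv(doc: TemplateDocument, path: str | Path) -> None:
    lay = doc.layout
    g = doc.geom
    lines = [
        "# rnalayout layout v1",
        f"# backbone_step {_fmt(g.backbone_step)}",
        f"# pair_step {_fmt(g.pair_step)}",
        f"# bond_length {_fmt(g.bond_length)}",
        "# index letter x y partner status",
    ]
    partner = doc.structure.partner()
    for k in range(doc.structure.length):
        p = partner[k] if partner[k] is not None else -1
        lines.append(
            f"{k}\t{doc.structure.sequence[k]}\t{_fmt(lay.coords[k, 0])}\t"
            f"{_fmt(lay.coords[k, 1])}\t{p}\t{lay.status[k]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout_tsv(path: str | Path) -> TemplateDocument:
    """Read a native layout document; structure, tree and layout are
    built and cross-validated.  Errors cite the offending line."""
    text = Path(path).read_text()
    geom_kw: dict[str, float] = {}
    rows: list[tuple[int, int, str, float, float, int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] in (
                "backbone_step",
                "pair_step",
                "bond_length",
            ):
                try:
                    geom_kw[parts[0]] = float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad geometry value") from exc
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(
                f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}"
            )
        try:
            idx = int(parts[0])
            x, y = float(parts[2]), float(parts[3])
            partner = int(parts[4])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed number: {exc}") from exc
        if parts[5] not in _STATUSES:
            raise ParseError(f"line {lineno}: unknown status {parts[5]!r}")
        rows.append((lineno, idx, parts[1], x, y, partner, parts[5]))
    if not rows:
        raise ParseError("no residues")
    indices = [r[1] for r in rows]
    if indices != list(range(len(rows))):
        raise ParseError(
            f"line {rows[0][0]}: residue indices must be contiguous from 0"
        )
    line_of = {r[1]: r[0] for r in rows}
    pairs: set[tuple[int, int]] = set()
    for _, idx, _, _, _, p, _ in rows:
        if p == -1:
            continue
        if not 0 <= p < len(rows):
            raise ParseError(f"line {line_of[idx]}: partner {p} out of range")
        if rows[p][5] != idx:
            raise ParseError(
                f"partner asymmetry between line {line_of[idx]} and line {line_of[p]}"
            )
        pairs.add((min(idx, p), max(idx, p)))
    ss = SecondaryStructure(tuple(r[2] for r in rows), frozenset(pairs))
    if not ss.is_crossing_free():
        raise ParseError("layout contains crossing pairs; de-knot the template first")
    coords = np.array([[r[3], r[4]] for r in rows])
    status = [r[6] for r in rows]
    return document_from_layout(ss, coords, Geometry(**geom_kw), status)


# ----------------------------------------------------------------------
# SVG


_SVG_NS = "http://www.w3.org/2000/svg"
_GLYPH_GAP = 2.5  # backbone connectors stop short of glyph centers


def _svg_body(doc: TemplateDocument, colored: bool, overlaps: bool) -> str:
    from . import postprocess

    lay = doc.layout
    pts = lay.coords.copy()
    pts[:, 1] = -pts[:, 1]  # screen convention: y down
    margin = 2 * doc.geom.backbone_step
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shift = -lo
    pts = pts + shift
    w, h = hi - lo

    hot: set[tuple[int, int]] = set()
    if overlaps:
        rep = postprocess.count_overlaps(doc)
        for a, b in rep.crossings:
            hot.add((a.i, a.j))
            hot.add((b.i, b.j))

    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    out.write(
        f'<svg xmlns="{_SVG_NS}" version="1.1" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">\n'
    )

    def seg_color(i: int, j: int) -> str:
        return _OVERLAP_COLOR if (i, j) in hot else "#808080"

    # backbone connectors, shortened around the glyphs
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        d = b - a
        L = float(np.hypot(*d))
        if L < 2 * _GLYPH_GAP:
            continue
        u = d / L
        p1 = a + u * _GLYPH_GAP
        p2 = b - u * _GLYPH_GAP
        out.write(
            f'<line x1="{_fmt(p1[0])}" y1="{_fmt(p1[1])}" x2="{_fmt(p2[0])}" '
            f'y2="{_fmt(p2[1])}" stroke="{seg_color(k, k + 1)}" stroke-width="1"/>\n'
        )
    for i, j in sorted(doc.structure.pairs):
        a, b = pts[i], pts[j]
        d = b - a
        L = float(np.hypot(*d))
        if L < 2 * _GLYPH_GAP:
            continue
        u = d / L
        p1 = a + u * _GLYPH_GAP
        p2 = b - u * _GLYPH_GAP
        color = _OVERLAP_COLOR if (i, j) in hot else "#000000"
        out.write(
            f'<line class="bp" x1="{_fmt(p1[0])}" y1="{_fmt(p1[1])}" '
            f'x2="{_fmt(p2[0])}" y2="{_fmt(p2[1])}" stroke="{color}" '
            'stroke-width="1"/>\n'
        )
    for k in range(len(pts)):
        color = _COLORS[lay.status[k]] if colored else "#000000"
        out.write(
            f'<text x="{_fmt(pts[k][0])}" y="{_fmt(pts[k][1])}" fill="{color}" '
            'font-family="monospace" font-size="7" text-anchor="middle" '
            f'dominant-baseline="middle">{doc.structure.sequence[k]}</text>\n'
        )
    out.write("</svg>\n")
    return out.getvalue()


def write_svg(
    doc: TemplateDocument,
    path: str | Path,
    colored: bool = False,
    overlaps: bool = False,
) -> None:
    """Write an SVG 1.1 drawing: one text glyph per residue, one line
    per base pair, short backbone connectors with a gap around glyphs.

    With ``colored``, residues are tinted by status (inserted red,
    relabeled green, shifted blue); with ``overlaps``, crossing
    segments are highlighted.
    """
    Path(path).write_text(_svg_body(doc, colored, overlaps))


def read_varna_svg(path: str | Path, geom: Geometry | None = None) -> TemplateDocument:
    """Read a minimal VARNA-dialect SVG template.

    Residues come from ``text`` elements in document order; base pairs
    from ``line`` elements (class "bp" or any line both of whose
    endpoints lie within half a backbone step of residue centers, as
    VARNA draws plain pair bonds between the glyphs).  The y axis is
    flipped back to y-up.
    """
    geom = geom or Geometry()
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not an SVG document: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "svg":
        raise ParseError("not an SVG document: root element is not <svg>")
    texts = root.findall(f".//{{{_SVG_NS}}}text")
    if not texts:
        raise ParseError("no residue glyphs found")
    letters: list[str] = []
    pts: list[list[float]] = []
    for t in texts:
        letters.append((t.text or "N").strip() or "N")
        pts.append([float(t.get("x")), float(t.get("y"))])
    coords = np.array(pts)
    pairs: set[tuple[int, int]] = set()
    tol = 0.5 * geom.backbone_step
    for ln in root.findall(f".//{{{_SVG_NS}}}line"):
        p1 = np.array([float(ln.get("x1")), float(ln.get("y1"))])
        p2 = np.array([float(ln.get("x2")), float(ln.get("y2"))])
        d1 = np.hypot(*(coords - p1).T)
        d2 = np.hypot(*(coords - p2).T)
        i, j = int(np.argmin(d1)), int(np.argmin(d2))
        near = d1[i] <= tol and d2[j] <= tol
        if ln.get("class") == "bp":
            if not near:
                raise ParseError(
                    "base-pair line endpoint too far from any residue glyph"
                )
            pairs.add((min(i, j), max(i, j)))
        elif near and abs(i - j) > 1:
            pairs.add((min(i, j), max(i, j)))
    coords[:, 1] = -coords[:, 1]
    ss = SecondaryStructure(tuple(letters), frozenset(pairs))
    if not ss.is_crossing_free():
        raise ParseError("SVG template encodes crossing pairs")
    doc = document_from_layout(ss, coords, geom)
    # remove the global placement offset the writer added
    return doc


# ----------------------------------------------------------------------
# PostScript


def write_ps(doc: TemplateDocument, path: str | Path, colored: bool = False) -> None:
    """PostScript (level 1) mirror of the SVG writer, y up."""
    lay = doc.layout
    pts = lay.coords.copy()
    margin = 2 * doc.geom.backbone_step
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    pts = pts - lo
    w, h = hi - lo
    out = io.StringIO()
    out.write("%!PS-Adobe-3.0 EPSF-3.0\n")
    out.write(f"%%BoundingBox: 0 0 {int(np.ceil(w))} {int(np.ceil(h))}\n")
    out.write("/Courier findfont 7 scalefont setfont\n")

    def rgb(color: str) -> str:
        r = int(color[1:3], 16) / 255
        g = int(color[3:5], 16) / 255
        b = int(color[5:7], 16) / 255
        return f"{_fmt(r)} {_fmt(g)} {_fmt(b)} setrgbcolor"

    out.write("0.5 setlinewidth\n")
    out.write(rgb("#808080") + "\n")
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        out.write(
            f"newpath {_fmt(a[0])} {_fmt(a[1])} moveto "
            f"{_fmt(b[0])} {_fmt(b[1])} lineto stroke\n"
        )
    out.write(rgb("#000000") + "\n")
    for i, j in sorted(doc.structure.pairs):
        a, b = pts[i], pts[j]
        out.write(
            f"newpath {_fmt(a[0])} {_fmt(a[1])} moveto "
            f"{_fmt(b[0])} {_fmt(b[1])} lineto stroke\n"
        )
    for k in range(len(pts)):
        color = _COLORS[lay.status[k]] if colored else "#000000"
        out.write(rgb(color) + "\n")
        out.write(
            f"{_fmt(pts[k][0])} {_fmt(pts[k][1])} moveto "
            f"({doc.structure.sequence[k]}) show\n"
        )
    out.write("showpage\n")
    Path(path).write_text(out.getvalue())
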