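"""Layout polishing: stem straightening, top-level special cases and
clash handling.

After the edit script has been replayed the drawing can contain locally
inconsistent geometry — curved stems (the parent/grandparent insertion
direction is only a local estimate), ragged spacing between the
top-level elements hanging off the artificial root (their parent has no
position to guide them), and 2D steric clashes when target and template
are dissimilar.  The operations here repair those; all are conservative
(they never touch what is already consistent, and the clash resolver
never increases the overlap count).

An overlap is a proper crossing between two drawn segments — hydrogen
bond lines between paired residues or backbone links between
consecutive residues — that share no residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import perp, rotate_about, unit
from .layout_engine import (
    INSERTED,
    SHIFTED,
    UNCHANGED,
    TemplateDocument,
    _flag,
    _mid,
    _non_leaf_children,
    _rotate_subtree,
    _set_coord,
    _stem_axis,
    shift_subtree,
)
from .structure_model import LEAF, PAIR, ROOT, TreeNode

__all__ = [
    "Segment",
    "OverlapReport",
    "straighten_stems",
    "count_overlaps",
    "resolve_clashes",
    "normalize_top_level",
    "insert_pair_top_level",
    "DEFAULT_ROTATIONS",
]

_TOL = 1e-9

#: candidate rotations (radians) tried when untangling a clashing
#: subtree; one pass outermost-first, best-of wins
DEFAULT_ROTATIONS = tuple(
    math.radians(a) for a in (5, -5, 10, -10, 15, -15, 20, -20, 30, -30, 45, -45, 60, -60)
)


# ----------------------------------------------------------------------
# stems


def _stems(doc: TemplateDocument) -> list[list[TreeNode]]:
    """Maximal runs of stacked pairs: chains where each pair's only
    child is the next pair."""
    stems = []
    for nd in doc.tree.preorder():
        if nd.kind != PAIR:
            continue
        p = nd.parent
        if p is not None and p.kind == PAIR and len(p.children) == 1:
            continue  # interior of a stem, not a start
        chain = [nd]
        while len(chain[-1].children) == 1 and chain[-1].children[0].kind == PAIR:
            chain.append(chain[-1].children[0])
        if len(chain) >= 2:
            stems.append(chain)
    return stems


def straighten_stems(doc: TemplateDocument) -> None:
    """Project every stem onto a straight line.

    The stem's outermost (closest-to-root) pair anchors the line; the
    axis runs from the first to the last pair midpoint; subsequent pair
    midpoints are re-spaced at uniform pair steps with the two residues
    of each pair symmetric about the axis at the bond length.  The
    subtree below the stem is translated along.  Idempotent.
    """
    g = doc.geom
    for chain in _stems(doc):
        first = chain[0]
        axis_v = _mid(chain[-1]) - _mid(first)
        axis = unit(axis_v) if np.hypot(*axis_v) > _TOL else _stem_axis(doc, first)
        u = perp(axis)
        # keep each pair's 5' residue on its current side of the axis
        sgn = 1.0 if float(np.dot(first.coords[0] - _mid(first), u)) <= 0 else -1.0
        half = 0.5 * g.bond_length
        base = _mid(first)
        last_delta = np.zeros(2)
        for k, nd in enumerate(chain[1:], start=1):
            new_mid = base + axis * (k * g.pair_step)
            last_delta = new_mid - _mid(nd)
            _set_coord(nd, 0, new_mid - u * (sgn * half), None)
            _set_coord(nd, 1, new_mid + u * (sgn * half), None)
        for c in chain[-1].children:
            shift_subtree(doc, c, last_delta)


# ----------------------------------------------------------------------
# overlaps


@dataclass(frozen=True)
class Segment:
    """Drawn line: residue index pair plus kind (backbone or bond)."""

    i: int
    j: int
    kind: str  # "backbone" | "bond"


@dataclass
class OverlapReport:
    crossings: list[tuple[Segment, Segment]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.crossings)

    def residues(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.crossings:
            out.update((a.i, a.j, b.i, b.j))
        return out


def _segments(doc: TemplateDocument) -> list[Segment]:
    segs = [
        Segment(k, k + 1, "backbone") for k in range(doc.structure.length - 1)
    ]
    segs.extend(Segment(i, j, "bond") for i, j in sorted(doc.structure.pairs))
    return segs


def count_overlaps(doc: TemplateDocument) -> OverlapReport:
    """Brute-force all-pairs crossing count over bond and backbone
    segments.  A crossing is a proper (interior) intersection of two
    closed segments; collinear overlapping segments count as one
    crossing; pairs sharing a residue are never counted."""
    segs = _segments(doc)
    pts = doc.layout.coords
    P = np.array([[pts[s.i], pts[s.j]] for s in segs])  # (S, 2, 2)
    S = len(segs)
    report = OverlapReport()
    if S < 2:
        return report
    A, B = P[:, 0], P[:, 1]
    ia = np.array([s.i for s in segs])
    ja = np.array([s.j for s in segs])

    def cross(o, p, q):
        return (p[..., 0] - o[..., 0]) * (q[..., 1] - o[..., 1]) - (
            p[..., 1] - o[..., 1]
        ) * (q[..., 0] - o[..., 0])

    for k in range(S - 1):
        a1, b1 = A[k], B[k]
        a2, b2 = A[k + 1 :], B[k + 1 :]
        d1 = cross(a2, b2, a1[None, :])
        d2 = cross(a2, b2, b1[None, :])
        d3 = cross(a1[None, :], b1[None, :], a2)
        d4 = cross(a1[None, :], b1[None, :], b2)
        strict = (d1 * d2 < 0) & (d3 * d4 < 0)
        share = (
            (ia[k + 1 :] == ia[k])
            | (ia[k + 1 :] == ja[k])
            | (ja[k + 1 :] == ia[k])
            | (ja[k + 1 :] == ja[k])
        )
        coll = (
            (np.abs(d1) < _TOL)
            & (np.abs(d2) < _TOL)
            & (np.abs(d3) < _TOL)
            & (np.abs(d4) < _TOL)
        )
        hits = np.nonzero((strict | (coll & _collinear_overlap(a1, b1, a2, b2))) & ~share)[0]
        for h in hits:
            report.crossings.append((segs[k], segs[k + 1 + h]))
    return report


def _collinear_overlap(a1, b1, a2, b2):
    """1D overlap (more than a point) of collinear segments, projected
    on the longer axis of segment 1."""
    d = b1 - a1
    axis = 0 if abs(d[0]) >= abs(d[1]) else 1
    lo1, hi1 = sorted((a1[axis], b1[axis]))
    lo2 = np.minimum(a2[..., axis], b2[..., axis])
    hi2 = np.maximum(a2[..., axis], b2[..., axis])
    return (np.minimum(hi1, hi2) - np.maximum(lo1, lo2)) > _TOL


# ----------------------------------------------------------------------
# clash resolution


def resolve_clashes(
    doc: TemplateDocument, rotations: tuple[float, ...] = DEFAULT_ROTATIONS
) -> OverlapReport:
    """Try to rotate clashing subtrees to minimize the overlap count.

    Walks subtrees outermost-first; for each stem-rooted subtree that
    participates in a clash with the rest of the drawing, tries the
    candidate rotations about the subtree's anchor pair midpoint and
    keeps the best.  A rotated subtree is not revisited (prevents
    oscillation); the global overlap count never increases.  Returns
    the final overlap report.
    """
    report = count_overlaps(doc)
    if report.count == 0:
        return report
    idx_of: dict[int, set[int]] = {}
    for nd in doc.tree.preorder():
        if nd.kind == PAIR:
            idx_of[id(nd)] = {
                n.indices[s]
                for n in nd.subtree()
                for s in range(n.n_residues)
            }
    done: set[int] = set()
    stack = [c for c in reversed(doc.tree.root.children) if c.kind == PAIR]
    while stack:
        nd = stack.pop()
        if id(nd) in done:
            continue
        inside = idx_of[id(nd)]
        boundary = [
            (a, b)
            for a, b in report.crossings
            if ({a.i, a.j} <= inside) != ({b.i, b.j} <= inside)
            and ({a.i, a.j} | {b.i, b.j}) & inside
        ]
        if boundary:
            center = _mid(nd)
            best_angle, best_count = 0.0, report.count
            for ang in rotations:
                _rotate_subtree(nd, center, ang, flag=False)
                c = count_overlaps(doc).count
                _rotate_subtree(nd, center, -ang, flag=False)
                if c < best_count:
                    best_angle, best_count = ang, c
            if best_angle != 0.0:
                _rotate_subtree(nd, center, best_angle, flag=True)
                report = count_overlaps(doc)
                done.update(id(x) for x in nd.subtree())
                if report.count == 0:
                    return report
                continue
        stack.extend(c for c in reversed(_non_leaf_children(nd)))
    return report


# ----------------------------------------------------------------------
# top level (children of the artificial root)


def _element_endpoints(nd: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    return nd.coords[0], nd.coords[nd.n_residues - 1]


def normalize_top_level(doc: TemplateDocument, dirty: set[int] | None = None) -> None:
    """Re-space the top-level chain.

    The elements hanging off the artificial root have no positioned
    parent, so indels among them leave gaps or pile-ups.  Walking
    5'->3', whenever a consecutive backbone gap falls outside the
    configured band around the backbone step, the downstream tail of
    the chain is translated rigidly (whole branches included) to close
    it to one backbone step.  Elements already in band are untouched.

    When ``dirty`` (a set of ``id()`` of top-level nodes) is given,
    only gaps ending at a dirty element are considered — the transform
    pipeline uses this to repair edit sites without re-spacing gaps the
    template drew wide on purpose.
    """
    g = doc.geom
    lo, hi = g.squeeze_spacing
    kids = [c for c in doc.tree.root.children if c.coords is not None]
    prev_end: np.ndarray | None = None
    for k, c in enumerate(kids):
        start, _ = _element_endpoints(c)
        if prev_end is not None and (dirty is None or id(c) in dirty):
            gap = start - prev_end
            d = float(np.hypot(*gap))
            if d < lo * g.backbone_step or d > hi * g.backbone_step:
                dirv = unit(gap) if d > _TOL else np.array([1.0, 0.0])
                delta = prev_end + dirv * g.backbone_step - start
                for tail in kids[k:]:
                    shift_subtree(doc, tail, delta)
        prev_end = _element_endpoints(c)[1]


def insert_pair_top_level(doc: TemplateDocument, node: TreeNode) -> None:
    """Place a PAIR inserted directly under the artificial root.

    Case 1 — the pair extends an existing top-level stem (its sole
    adopted child is a positioned pair): the new pair takes the old
    stem-start coordinates and the old stem shifts one pair step
    inward.  Case 2 — the pair roots a brand-new branch: it is placed
    on the top-level chain with its bond perpendicular to the local
    chain direction, and the downstream siblings shift along the chain
    by bond length + backbone step to make room.
    """
    g = doc.geom
    root = node.parent
    kids = [c for c in node.children if c.kind == PAIR and c.coords is not None]
    if len(node.children) == 1 and len(kids) == 1:
        old = kids[0]
        a, b = old.coords[0].copy(), old.coords[1].copy()
        if len(old.children) == 1 and old.children[0].kind == PAIR:
            axis = unit(_mid(old.children[0]) - _mid(old))
        else:
            pts = [
                q
                for c in root.children
                if c is not node and c.coords is not None
                for q in c.coords[: c.n_residues]
            ]
            if pts:
                center = np.mean(np.array(pts), axis=0)
                d = _mid(old) - center
                axis = unit(d) if np.hypot(*d) > _TOL else unit(perp(b - a))
            else:
                axis = unit(perp(b - a))
        _set_coord(node, 0, a, INSERTED)
        _set_coord(node, 1, b, INSERTED)
        shift_subtree(doc, old, axis * g.pair_step)
        return
    # case 2: new branch
    k = root.children.index(node)
    prev_pt = next_pt = None
    for c in reversed(root.children[:k]):
        if c.coords is not None:
            prev_pt = c.coords[c.n_residues - 1]
            break
    for c in root.children[k + 1 :]:
        if c.coords is not None:
            next_pt = c.coords[0]
            break
    if prev_pt is not None and next_pt is not None:
        d = next_pt - prev_pt
        chain = unit(d) if np.hypot(*d) > _TOL else np.array([1.0, 0.0])
        at = prev_pt + chain * g.backbone_step
    elif prev_pt is not None:
        chain = np.array([1.0, 0.0])
        at = prev_pt + chain * g.backbone_step
    elif next_pt is not None:
        chain = np.array([1.0, 0.0])
        at = next_pt - chain * (g.bond_length + g.backbone_step)
    else:
        chain = np.array([1.0, 0.0])
        at = np.zeros(2)
    u = perp(chain)  # bond perpendicular to the local chain direction
    half = 0.5 * g.bond_length
    _set_coord(node, 0, at - u * half, INSERTED)
    _set_coord(node, 1, at + u * half, INSERTED)
    for c in node.children:
        ref = next((n for n in c.subtree() if n.coords is not None), None)
        if ref is not None:
            shift_subtree(doc, c, at + chain * g.pair_step - ref.coords[0])
    for c in root.children[k + 1 :]:
        shift_subtree(doc, c, chain * (g.bond_length + g.backbone_step))
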