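"""Replay of an edit script as local modifications of a template layout.

The working object is a tree whose PAIR/LEAF nodes carry 2D coordinates
(one point per residue) plus a per-residue status flag.  Deletions are
applied first (post-order), then insertions (pre-order), then letter
updates; each structural operation triggers the corresponding geometric
modification:

* base-pair insertion into a stem shifts the descendants one pair step
  along the stem axis (direction given by parent and grandparent);
* leaf insertion into an existing loop redistributes the loop arc on a
  circle between its fixed anchors;
* leaf insertion between two stacked pairs opens a new bulge by
  shifting the sibling subtree one backbone step;
* deletions are the exact geometric inverses;
* loops with at least two emanating stems (multibranch loops) are
  squeezed locally when only a few residues change and rebuilt on a
  fresh circle — with every branch rigidly re-anchored — otherwise.

The guiding principle is to interfere with the template drawing as
little as possible: untouched parts of the template keep their exact
coordinates, and a target identical to the template is returned
byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import arc_circle, distribute_on_circle, perp, rotate_about, unit
from .structure_model import (
    LEAF,
    PAIR,
    ROOT,
    OrderedTree,
    SecondaryStructure,
    TreeNode,
    build_tree,
    remove_pseudoknots,
)
from .tree_edit import CostScheme, EditScript, ted

__all__ = [
    "Geometry",
    "Layout",
    "TemplateDocument",
    "shift_subtree",
    "insert_pair_node",
    "insert_leaf_into_loop",
    "insert_leaf_new_bulge",
    "delete_node",
    "multibranch_update",
    "transform",
]

UNCHANGED = "unchanged"
SHIFTED = "shifted"
RELABELED = "relabeled"
INSERTED = "inserted"
_RANK = {UNCHANGED: 0, SHIFTED: 1, RELABELED: 2, INSERTED: 3}
_TOL = 1e-9


@dataclass(frozen=True)
class Geometry:
    """Layout spacing constants (layout units).

    backbone_step: distance between consecutive residues along the
    backbone; pair_step: distance between consecutive base pairs along
    a stem; bond_length: distance between the two residues of a pair.
    """

    backbone_step: float = 8.0
    pair_step: float = 8.0
    bond_length: float = 8.0
    squeeze_max_indels: int = 2
    squeeze_spacing: tuple[float, float] = (0.5, 2.0)


@dataclass
class Layout:
    """Flat per-residue view of a drawing: (L, 2) coordinates plus a
    status flag per residue (unchanged / inserted / relabeled /
    shifted)."""

    coords: np.ndarray
    status: list[str]
    geom: Geometry = field(default_factory=Geometry)

    def count(self, status: str) -> int:
        return sum(1 for s in self.status if s == status)

    @property
    def n_residues(self) -> int:
        return len(self.status)


@dataclass
class TemplateDocument:
    """A secondary structure, its tree and its layout, kept consistent.

    The tree's nodes carry the coordinates; ``layout`` extracts the
    flat per-residue view in 5'->3' order.
    """

    structure: SecondaryStructure
    tree: OrderedTree
    geom: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        n = sum(nd.n_residues for nd in self.tree.preorder())
        if n != self.structure.length:
            raise ValueError(
                f"tree carries {n} residues but structure has {self.structure.length}"
            )

    @property
    def layout(self) -> Layout:
        order = self.tree.residue_order()
        coords = np.array([nd.coords[slot] for nd, slot in order], dtype=float)
        status = [
            (nd.status[slot] if nd.status else UNCHANGED) for nd, slot in order
        ]
        return Layout(coords=coords, status=status, geom=self.geom)

    def refresh(self) -> None:
        """Reindex residues and rebuild the structure from the tree."""
        self.tree.reindex()
        self.structure = self.tree.to_secondary_structure()

    def copy(self) -> "TemplateDocument":
        return TemplateDocument(self.structure, self.tree.copy(), self.geom)


def document_from_layout(
    ss: SecondaryStructure,
    coords: np.ndarray,
    geom: Geometry | None = None,
    status: list[str] | None = None,
) -> TemplateDocument:
    """Build a consistent document from a structure and per-residue
    coordinates (pseudoknot-free structure required)."""
    geom = geom or Geometry()
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (ss.length, 2):
        raise ValueError(f"coords must be ({ss.length}, 2), got {coords.shape}")
    tree = build_tree(ss)
    for nd in tree.preorder():
        if nd.kind == ROOT:
            continue
        nd.coords = [coords[i].copy() for i in nd.indices]
        nd.status = [
            (status[i] if status is not None else UNCHANGED) for i in nd.indices
        ]
    return TemplateDocument(ss, tree, geom)


# ----------------------------------------------------------------------
# small helpers


def _mid(nd: TreeNode) -> np.ndarray:
    return 0.5 * (nd.coords[0] + nd.coords[1])


def _flag(nd: TreeNode, slot: int, status: str) -> None:
    if nd.status is None:
        nd.status = [UNCHANGED] * nd.n_residues
    if _RANK[status] > _RANK[nd.status[slot]]:
        nd.status[slot] = status


def _set_coord(nd: TreeNode, slot: int, p: np.ndarray, status: str | None) -> None:
    if nd.coords is None:
        nd.coords = [np.zeros(2) for _ in range(nd.n_residues)]
        nd.status = [UNCHANGED] * nd.n_residues
    moved = float(np.hypot(*(nd.coords[slot] - p))) > _TOL
    nd.coords[slot] = np.asarray(p, dtype=float)
    if status is not None:
        _flag(nd, slot, status)
    elif moved:
        _flag(nd, slot, SHIFTED)


def _non_leaf_children(nd: TreeNode) -> list[TreeNode]:
    return [c for c in nd.children if c.kind == PAIR]


def _splice_out(nd: TreeNode) -> int:
    p = nd.parent
    k = p.children.index(nd)
    for c in nd.children:
        c.parent = p
    p.children[k : k + 1] = nd.children
    return k


def shift_subtree(
    doc: TemplateDocument, root_node: TreeNode, vector: np.ndarray, flag: bool = True
) -> None:
    """Translate every residue of root_node's subtree (Algorithm-2
    style rigid shift); residues that actually move are flagged
    `shifted` unless flag is False."""
    v = np.asarray(vector, dtype=float)
    moved = float(np.hypot(*v)) > _TOL
    for nd in root_node.subtree():
        if nd.coords is None:
            continue
        for s in range(nd.n_residues):
            nd.coords[s] = nd.coords[s] + v
            if flag and moved:
                _flag(nd, s, SHIFTED)


def _rotate_subtree(
    root_node: TreeNode,
    center: np.ndarray,
    angle: float,
    include_anchor: bool = False,
    flag: bool = True,
) -> None:
    for nd in root_node.subtree():
        if nd.coords is None or (nd is root_node and not include_anchor):
            continue
        for s in range(nd.n_residues):
            p = rotate_about(nd.coords[s], center, angle)
            if flag and float(np.hypot(*(p - nd.coords[s]))) > _TOL:
                _flag(nd, s, SHIFTED)
            nd.coords[s] = p


def _rigid_map_subtree(
    root_node: TreeNode,
    old_a: np.ndarray,
    old_b: np.ndarray,
    new_a: np.ndarray,
    new_b: np.ndarray,
) -> None:
    """Rigidly move a subtree so the segment old_a->old_b lands on
    new_a->new_b (rotation + translation, no reflection)."""
    dv_old = old_b - old_a
    dv_new = new_b - new_a
    ang = math.atan2(dv_new[1], dv_new[0]) - math.atan2(dv_old[1], dv_old[0])
    c, s = math.cos(ang), math.sin(ang)
    R = np.array([[c, -s], [s, c]])
    for nd in root_node.subtree():
        if nd.coords is None:
            continue
        for k in range(nd.n_residues):
            p = new_a + R @ (nd.coords[k] - old_a)
            if float(np.hypot(*(p - nd.coords[k]))) > _TOL:
                _flag(nd, k, SHIFTED)
            nd.coords[k] = p


def _stem_axis(doc: TemplateDocument, nd: TreeNode) -> np.ndarray:
    """Direction of the stem at PAIR node nd, pointing away from the
    root: grandparent-midpoint -> parent-midpoint rule, with the
    enclosing-loop-center fallback for stems of length 1."""
    p = nd.parent
    if p is not None and p.kind == PAIR:
        d = _mid(nd) - _mid(p)
        if np.hypot(*d) > _TOL:
            return unit(d)
    # no positioned grandparent: the stem continuation above nd gives
    # the exact axis (first positioned descendant pair)
    mids = []
    for c in nd.children:
        sub = next(
            (m for m in c.subtree() if m.kind == PAIR and m.coords is not None),
            None,
        )
        if sub is not None:
            mids.append(_mid(sub))
    if not mids:
        # hairpin: loop leaves are symmetric about the stem axis, so
        # their centroid pins it exactly
        leaves = [
            m.coords[0]
            for c in nd.children
            for m in c.subtree()
            if m.kind == LEAF and m.coords is not None
        ]
        if leaves:
            mids.append(np.mean(np.array(leaves), axis=0))
    if mids:
        d = np.mean(np.array(mids), axis=0) - _mid(nd)
        if np.hypot(*d) > _TOL:
            return unit(d)
    # degenerate: away from the centroid of the enclosing loop /
    # top-level chain
    anchor = p if p is not None and p.kind == PAIR else nd.parent
    pts = []
    for c in (anchor.children if anchor is not None else []):
        if c.coords is not None:
            pts.extend(c.coords[: c.n_residues])
    if anchor is not None and anchor.kind == PAIR:
        pts.extend(anchor.coords)
    if len(pts) >= 2:
        center = np.mean(np.array(pts), axis=0)
        d = _mid(nd) - center
        if np.hypot(*d) > _TOL:
            return unit(d)
    # last resort: perpendicular of the pair bond
    return unit(perp(nd.coords[1] - nd.coords[0]))


# ----------------------------------------------------------------------
# loop arcs


@dataclass
class _Arc:
    """Maximal run of unpaired residues of a loop between two fixed
    anchor points (closing-pair residues or branch anchor residues)."""

    a: np.ndarray
    b: np.ndarray
    leaves: list[TreeNode]
    side: np.ndarray


def _loop_anchor_points(loop: TreeNode) -> list[np.ndarray]:
    pts = []
    if loop.kind == PAIR:
        pts.extend(loop.coords)
    for c in loop.children:
        if c.kind == PAIR and c.coords is not None:
            pts.extend(c.coords)
    return pts


def _loop_center(doc: TemplateDocument, loop: TreeNode) -> np.ndarray:
    pts = _loop_anchor_points(loop)
    if len(pts) > 2:
        return np.mean(np.array(pts), axis=0)
    # hairpin: step back along the stem axis from the pair midpoint
    axis = _stem_axis(doc, loop)
    return _mid(loop) - axis * doc.geom.pair_step


def _loop_arcs(doc: TemplateDocument, loop: TreeNode) -> list[_Arc]:
    """Split a loop's leaf children into arcs between fixed anchors, in
    5'->3' order.  Works for hairpins, internal loops/bulges and
    multibranch loops alike."""
    center = _loop_center(doc, loop)
    arcs: list[_Arc] = []
    if loop.kind == PAIR:
        cur_a = loop.coords[0]
    else:
        raise ValueError("top-level chain is not handled as a loop")
    run: list[TreeNode] = []
    for c in loop.children:
        if c.kind == PAIR:
            arcs.append(_Arc(cur_a, c.coords[0] if c.coords else cur_a, run, center))
            run = []
            cur_a = c.coords[1] if c.coords else cur_a
        else:
            run.append(c)
    arcs.append(_Arc(cur_a, loop.coords[1], run, center))
    for arc in arcs:
        chord_mid = 0.5 * (arc.a + arc.b)
        d = chord_mid - center
        if np.hypot(*d) > 1e-7:
            arc.side = unit(d)
        else:
            with_pts = [l.coords[0] for l in arc.leaves if l.coords is not None]
            if with_pts:
                d2 = np.mean(np.array(with_pts), axis=0) - chord_mid
                arc.side = unit(d2) if np.hypot(*d2) > _TOL else unit(perp(arc.b - arc.a))
            else:
                arc.side = unit(perp(arc.b - arc.a))
    return arcs


def _redistribute_arc(doc: TemplateDocument, arc: _Arc) -> None:
    n = len(arc.leaves)
    if n == 0:
        return
    pts = distribute_on_circle(arc.a, arc.b, n, arc.side, doc.geom.backbone_step)
    for leaf, pt in zip(arc.leaves, pts):
        was_new = leaf.coords is None
        _set_coord(leaf, 0, pt, INSERTED if was_new else None)


def _arc_of(doc: TemplateDocument, loop: TreeNode, leaf: TreeNode) -> _Arc:
    for arc in _loop_arcs(doc, loop):
        if any(l is leaf for l in arc.leaves):
            return arc
    raise ValueError("leaf not found in any arc of its loop")


# ----------------------------------------------------------------------
# elementary operations (node already structurally in place)


def insert_pair_node(doc: TemplateDocument, node: TreeNode) -> None:
    """Place a newly inserted PAIR inside a stem (Fig-3a style).

    The new pair goes one pair step beyond its parent pair along the
    grandparent->parent direction; the adopted descendant subtree is
    shifted by the same amount so the stem grows without distortion.
    Top-level insertions (parent is the artificial root) are handled by
    the postprocessing module instead.
    """
    parent = node.parent
    if parent is None or parent.kind != PAIR:
        raise ValueError("insert_pair_node requires a PAIR parent")
    axis = _stem_axis(doc, parent)
    new_mid = _mid(parent) + axis * doc.geom.pair_step
    u = unit(parent.coords[1] - parent.coords[0])
    half = 0.5 * doc.geom.bond_length
    children = list(node.children)
    node.coords = None
    _set_coord(node, 0, new_mid - u * half, INSERTED)
    _set_coord(node, 1, new_mid + u * half, INSERTED)
    for c in children:
        shift_subtree(doc, c, axis * doc.geom.pair_step)


def insert_leaf_into_loop(doc: TemplateDocument, node: TreeNode) -> None:
    """Place a newly inserted LEAF in an existing simple loop by
    redrawing the loop arc on a circle between its fixed anchors."""
    loop = node.parent
    if loop is None or loop.kind != PAIR:
        raise ValueError("insert_leaf_into_loop requires a PAIR parent")
    if len(_non_leaf_children(loop)) > 1:
        raise ValueError("multibranch loop: use multibranch_update")
    _redistribute_arc(doc, _arc_of(doc, loop, node))


def insert_leaf_new_bulge(doc: TemplateDocument, node: TreeNode) -> None:
    """Open a new bulge for a LEAF inserted between two stacked pairs:
    shift the sibling stem one backbone step to create space, then
    place the leaf on the freed arc (Fig-3b style)."""
    loop = node.parent
    sibs = _non_leaf_children(loop)
    if loop.kind != PAIR or len(sibs) != 1:
        raise ValueError("new-bulge insertion needs a single stacked sibling pair")
    sib = sibs[0]
    axis = unit(_mid(sib) - _mid(loop))
    shift_subtree(doc, sib, axis * doc.geom.backbone_step)
    _redistribute_arc(doc, _arc_of(doc, loop, node))


def delete_node(doc: TemplateDocument, node: TreeNode) -> None:
    """Remove a node and undo the geometry of the matching insertion:
    stem-pair removal shifts the descendants back one pair step;
    loop-leaf removal shrinks the loop circle; removing the last leaf
    of a bulge collapses the bulge and un-shifts the sibling stem."""
    parent = node.parent
    if parent is None:
        raise ValueError("cannot delete the root")
    if node.kind == PAIR:
        if parent.kind == PAIR and len(_non_leaf_children(parent)) >= 2:
            _splice_out(node)
            multibranch_update(doc, parent)
            return
        if parent.kind == PAIR and node.coords is not None:
            d = _mid(node) - _mid(parent)
            _splice_out(node)
            if np.hypot(*d) > _TOL:
                v = -unit(d) * doc.geom.pair_step
                for c in node.children:
                    shift_subtree(doc, c, v)
        else:  # top-level branch root: spacing fixed by normalization
            _splice_out(node)
        return
    # LEAF
    if parent.kind == ROOT:
        _splice_out(node)
        return
    if len(_non_leaf_children(parent)) >= 2:
        multibranch_update(doc, parent, deleted=(node,))
        return
    arc = _arc_of(doc, parent, node)
    _splice_out(node)
    arc.leaves.remove(node)
    if not arc.leaves:
        sibs = _non_leaf_children(parent)
        arcs = _loop_arcs(doc, parent)
        other_occupied = any(a.leaves for a in arcs)
        if sibs and not other_occupied:
            # bulge collapsed: pull the sibling stem back in line
            sib = sibs[0]
            axis = unit(_mid(sib) - _mid(parent))
            shift_subtree(doc, sib, -axis * doc.geom.backbone_step)
        return
    _redistribute_arc(doc, arc)


# ----------------------------------------------------------------------
# multibranch loops


def multibranch_update(
    doc: TemplateDocument,
    loop_node: TreeNode,
    inserted: tuple[TreeNode, ...] = (),
    deleted: tuple[TreeNode, ...] = (),
) -> None:
    """Update a loop with >= 2 emanating stems after leaf/branch indels.

    When the net change is small (at most ``squeeze_max_indels``
    residues) and the affected arcs keep a reasonable spacing, only the
    unpaired residues between the neighbouring branches are re-spaced
    and the branch anchors stay fixed (squeeze/expand).  Otherwise the
    whole loop is rebuilt: every residue and branch anchor pair is
    placed on one circle, and each branch subtree is rigidly
    rotated+translated onto its new anchor, the transform propagating
    to all descendants.

    `inserted` leaves must already be attached to the loop (without
    coordinates); `deleted` leaves are still attached and are removed
    here.
    """
    geom = doc.geom
    dirty_idx: set[int] = set()
    if deleted:
        before = _loop_arcs(doc, loop_node)
        for i, arc in enumerate(before):
            if any(l in arc.leaves for l in deleted):
                dirty_idx.add(i)
    for leaf in deleted:
        _splice_out(leaf)
    # a brand-new branch anchor changes the loop fundamentally: the
    # squeeze path cannot place it, so rebuild
    new_branch = any(
        c.kind == PAIR and c.coords is None for c in loop_node.children
    )
    net = len(inserted) - len(deleted)
    if not new_branch and abs(net) <= geom.squeeze_max_indels:
        arcs = _loop_arcs(doc, loop_node)
        dirty = [
            arc
            for i, arc in enumerate(arcs)
            if i in dirty_idx or any(l.coords is None for l in arc.leaves)
        ]
        lo, hi = geom.squeeze_spacing
        ok = True
        for arc in dirty:
            if not arc.leaves:
                continue
            d = float(np.hypot(*(arc.b - arc.a)))
            spacing = d / (len(arc.leaves) + 1)
            if spacing > hi * geom.backbone_step or d < lo * geom.backbone_step:
                ok = False
                break
        if ok:
            for arc in dirty:
                _redistribute_arc(doc, arc)
            return
    _rebuild_multibranch(doc, loop_node)


def _rebuild_multibranch(doc: TemplateDocument, loop: TreeNode) -> None:
    geom = doc.geom
    slots = sum(2 if c.kind == PAIR else 1 for c in loop.children)
    if slots == 0:
        return
    side = _stem_axis(doc, loop)
    _, _, pts = arc_circle(
        loop.coords[0], loop.coords[1], slots, side, geom.backbone_step
    )
    center = np.mean(np.array([loop.coords[0], loop.coords[1]] + pts), axis=0)
    k = 0
    for c in loop.children:
        if c.kind == PAIR:
            new_a, new_b = pts[k], pts[k + 1]
            k += 2
            if c.coords is not None:
                old_a, old_b = c.coords[0].copy(), c.coords[1].copy()
                if np.hypot(*(old_b - old_a)) > _TOL:
                    _rigid_map_subtree(c, old_a, old_b, new_a, new_b)
                else:  # degenerate anchor: translate only
                    shift_subtree(doc, c, 0.5 * (new_a + new_b) - old_a)
            else:
                _set_coord(c, 0, new_a, INSERTED)
                _set_coord(c, 1, new_b, INSERTED)
                mid = 0.5 * (new_a + new_b)
                axis = unit(mid - center)
                for ch in c.children:
                    if any(n.coords is not None for n in ch.subtree()):
                        ref = next(
                            n.coords[0] for n in ch.subtree() if n.coords is not None
                        )
                        shift_subtree(doc, ch, mid + axis * geom.pair_step - ref)
        else:
            was_new = c.coords is None
            _set_coord(c, 0, pts[k], INSERTED if was_new else None)
            k += 1


# ----------------------------------------------------------------------
# the transform pipeline


def _insert_leaf_top_level(doc: TemplateDocument, node: TreeNode) -> None:
    root = node.parent
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
    bs = doc.geom.backbone_step
    if prev_pt is not None and next_pt is not None:
        d = next_pt - prev_pt
        dirv = unit(d) if np.hypot(*d) > _TOL else np.array([1.0, 0.0])
        pt = prev_pt + dirv * bs
    elif prev_pt is not None:
        pt = prev_pt + np.array([bs, 0.0])
        dirv = np.array([1.0, 0.0])
    elif next_pt is not None:
        pt = next_pt - np.array([bs, 0.0])
        dirv = np.array([1.0, 0.0])
    else:
        pt = np.zeros(2)
        dirv = np.array([1.0, 0.0])
    _set_coord(node, 0, pt, INSERTED)
    for c in root.children[k + 1 :]:
        shift_subtree(doc, c, dirv * bs)


def _kind_change_geometry(doc: TemplateDocument, nd: TreeNode, new_kind: str) -> None:
    """Geometric part of a PAIR<->LEAF update."""
    if new_kind == LEAF:
        p = _mid(nd)
        nd.kind = LEAF
        nd.coords = None
        nd.indices = ()
        _set_coord(nd, 0, p, RELABELED)
    else:
        p = nd.coords[0].copy()
        parent = nd.parent
        if parent is not None and parent.kind == PAIR:
            dirv = p - _mid(parent)
            dirv = unit(dirv) if np.hypot(*dirv) > _TOL else np.array([0.0, 1.0])
        else:
            dirv = np.array([0.0, 1.0])
        u = perp(dirv)
        half = 0.5 * doc.geom.bond_length
        nd.kind = PAIR
        nd.coords = None
        nd.indices = ()
        _set_coord(nd, 0, p - u * half, RELABELED)
        _set_coord(nd, 1, p + u * half, RELABELED)


def _dispatch_insert(doc: TemplateDocument, nd: TreeNode) -> None:
    from . import postprocess  # local import: postprocess builds on this module

    parent = nd.parent
    if nd.kind == PAIR:
        if parent.kind == ROOT:
            postprocess.insert_pair_top_level(doc, nd)
        elif len(_non_leaf_children(parent)) >= 2:
            multibranch_update(doc, parent, inserted=(nd,))
        else:
            insert_pair_node(doc, nd)
        return
    # LEAF
    if parent.kind == ROOT:
        _insert_leaf_top_level(doc, nd)
    elif len(_non_leaf_children(parent)) >= 2:
        multibranch_update(doc, parent, inserted=(nd,))
    else:
        arc = _arc_of(doc, parent, nd)
        if len(arc.leaves) == 1 and _non_leaf_children(parent):
            insert_leaf_new_bulge(doc, nd)
        else:
            insert_leaf_into_loop(doc, nd)


def transform(
    template_doc: TemplateDocument,
    target_ss: SecondaryStructure,
    costs: CostScheme | None = None,
    postprocess_layout: bool = True,
    precomputed: EditScript | None = None,
) -> tuple[Layout, EditScript]:
    """Produce a layout for the target structure from the template.

    Runs the tree edit distance between the template and target trees
    and replays the resulting edit script geometrically, followed by
    the polishing pipeline (stem straightening, top-level
    normalization, clash-rotation minimization).  Returns the target
    layout (with per-residue status flags) and the edit script.

    A target with crossing pairs is de-knotted internally.  A target
    identical to the template returns the template coordinates
    unchanged.
    """
    if not target_ss.is_crossing_free():
        target_ss = remove_pseudoknots(target_ss)
    target_tree = build_tree(target_ss)
    if precomputed is not None:
        script = precomputed
    else:
        _, script = ted(template_doc.tree, target_tree, costs)

    structural = any(op.op in ("DEL", "INS") for op in script.ops)
    kind_changes = []
    relabels = []
    tpl_nodes = {f"T{k}": n for k, n in enumerate(template_doc.tree.preorder())}
    for op in script.ops:
        if op.op == "UPD":
            src = tpl_nodes[op.node]
            if src.kind != op.kind:
                kind_changes.append(op)
            elif src.letters != op.letters:
                relabels.append(op)

    if not structural and not kind_changes:
        # identity-shaped mapping: template coordinates pass through
        lay = template_doc.layout
        coords = lay.coords.copy()
        status = [UNCHANGED] * len(lay.status)
        for op in relabels:
            src = tpl_nodes[op.node]
            for s in range(src.n_residues):
                if src.letters[s] != op.letters[s]:
                    status[src.indices[s]] = RELABELED
        return Layout(coords, status, template_doc.geom), script

    doc = template_doc.copy()
    registry: dict[str, TreeNode] = {
        f"T{k}": n for k, n in enumerate(doc.tree.preorder())
    }
    for nd in doc.tree.preorder():
        if nd.status is None and nd.kind != ROOT:
            nd.status = [UNCHANGED] * nd.n_residues

    dels = [op for op in script.ops if op.op == "DEL"]
    inss = [op for op in script.ops if op.op == "INS"]
    upds = [op for op in script.ops if op.op == "UPD"]

    top_dirty: set[int] = set()
    for op in dels:
        nd = registry.pop(op.node)
        if nd.parent is not None and nd.parent.kind == ROOT:
            sibs = nd.parent.children
            k = sibs.index(nd)
            nxt = next((c for c in sibs[k + 1 :] if c is not nd), None)
            if nxt is not None:
                top_dirty.add(id(nxt))
            top_dirty.update(id(c) for c in nd.children)
        delete_node(doc, nd)
    for op in upds:  # kind changes first: inserts may hang below them
        nd = registry[op.node]
        if nd.kind != op.kind:
            _kind_change_geometry(doc, nd, op.kind)
            nd.letters = op.letters
    for op in inss:
        parent = registry[op.parent]
        nd = TreeNode(op.kind, (), op.letters)
        nd.parent = parent
        nd.children = parent.children[op.pos : op.pos + op.n_adopt]
        for c in nd.children:
            c.parent = nd
        parent.children[op.pos : op.pos + op.n_adopt] = [nd]
        registry[op.node] = nd
        _dispatch_insert(doc, nd)
    for op in upds:
        nd = registry[op.node]
        if nd.kind == op.kind and nd.letters != op.letters:
            for s in range(nd.n_residues):
                if nd.letters[s] != op.letters[s]:
                    _flag(nd, s, RELABELED)
            nd.letters = op.letters

    doc.refresh()
    if postprocess_layout:
        from . import postprocess

        postprocess.straighten_stems(doc)
        postprocess.normalize_top_level(doc, dirty=top_dirty)
        postprocess.resolve_clashes(doc)

    lay = doc.layout
    if not np.all(np.isfinite(lay.coords)):  # pragma: no cover - safety net
        raise AssertionError("transform produced non-finite coordinates")
    if lay.n_residues != target_ss.length:
        raise AssertionError("layout residue count does not match the target")
    return lay, script
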