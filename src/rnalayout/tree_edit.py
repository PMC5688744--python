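"""Ordered tree edit distance and minimal edit scripts.

The mapper phase: given template and target trees, compute the minimal
tree edit distance (TED) with the Zhang–Shasha keyroot decomposition
(O(m^2 n^2) time, O(mn) memory) and backtrace a full valid mapping —
a partial injection from template nodes to target nodes that preserves
ancestry and left-to-right sibling order.  The mapping is turned into an
ordered edit script (deletes in post-order, inserts in pre-order,
updates last) which, applied to the template tree, reproduces the
target tree; the layout engine replays the same script geometrically.

A brute-force enumerator over all valid mappings serves as an
independent oracle for small trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .structure_model import LEAF, PAIR, ROOT, OrderedTree, TreeNode

__all__ = [
    "CostScheme",
    "EditOp",
    "EditScript",
    "ted",
    "ted_bruteforce",
    "apply_script",
    "trees_isomorphic",
    "serialize_script",
    "parse_script",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CostScheme:
    """Edit operation costs.

    Defaults: unit insert/delete; update is free when node kinds match
    (PAIR<->PAIR, LEAF<->LEAF) regardless of nucleotide letters — the
    layout transfer cares about shape, and letter-only changes are
    recorded as relabels for color coding — and 1 when kinds differ.
    """

    insert_cost: float = 1.0
    delete_cost: float = 1.0
    update: Callable[[TreeNode, TreeNode], float] | None = None

    def update_cost(self, a: TreeNode, b: TreeNode) -> float:
        if self.update is not None:
            return self.update(a, b)
        return 0.0 if a.kind == b.kind else 1.0


@dataclass
class EditOp:
    """One edit operation.

    op is ``DEL`` (template node id), ``INS`` (target node id, parent
    reference, child position, number of adopted children, new kind and
    letters) or ``UPD`` (template id, target id, target kind/letters).
    Node ids are ``T<k>``/``Q<k>`` with k the pre-order index in the
    template/target tree.
    """

    op: str
    node: str = ""
    target: str = ""
    parent: str = ""
    pos: int = 0
    n_adopt: int = 0
    kind: str = ""
    letters: tuple[str, ...] = ()


@dataclass
class EditScript:
    ops: list[EditOp]
    mapping: list[tuple[str, str]]
    cost: float
    distance: float

    @property
    def n_inserts(self) -> int:
        return sum(1 for o in self.ops if o.op == "INS")

    @property
    def n_deletes(self) -> int:
        return sum(1 for o in self.ops if o.op == "DEL")

    def inserted_residue_count(self) -> int:
        """Residues created by INSERT ops (2 per PAIR, 1 per LEAF)."""
        return sum(
            {PAIR: 2, LEAF: 1, ROOT: 0}[o.kind] for o in self.ops if o.op == "INS"
        )


# ----------------------------------------------------------------------
# tree annotation helpers


def _annotate(tree: OrderedTree):
    """1-based post-order node list, leftmost-leaf array, keyroots."""
    post = tree.postorder()
    index = {id(n): k + 1 for k, n in enumerate(post)}
    m = len(post)
    lml = [0] * (m + 1)
    for k, n in enumerate(post, start=1):
        lml[k] = k if not n.children else lml[index[id(n.children[0])]]
    keyroots = [k for k in range(1, m + 1) if not any(lml[j] == lml[k] for j in range(k + 1, m + 1))]
    return post, lml, keyroots


def _ids(tree: OrderedTree, prefix: str) -> dict[int, str]:
    return {id(n): f"{prefix}{k}" for k, n in enumerate(tree.preorder())}


# ----------------------------------------------------------------------
# Zhang–Shasha with backtrace


def ted(
    template: OrderedTree,
    target: OrderedTree,
    costs: CostScheme | None = None,
) -> tuple[float, EditScript]:
    """Minimal tree edit distance plus a full edit script.

    Zhang–Shasha keyroot dynamic programming with a recomputing
    backtrace.  Tie-breaking is deterministic: matches (updates) are
    preferred over delete+insert, and the backtrace walks right-to-left
    preferring the diagonal, which maps earlier template nodes first
    among equal-cost alternatives.
    """
    costs = costs or CostScheme()
    po1, l1, kr1 = _annotate(template)
    po2, l2, kr2 = _annotate(target)
    m, n = len(po1), len(po2)
    DEL, INS = costs.delete_cost, costs.insert_cost

    def upd(i: int, j: int) -> float:
        return costs.update_cost(po1[i - 1], po2[j - 1])

    td = [[0.0] * (n + 1) for _ in range(m + 1)]

    def forest_table(k1: int, k2: int) -> tuple[list[list[float]], int, int]:
        li, lj = l1[k1], l2[k2]
        mm, nn = k1 - li + 1, k2 - lj + 1
        fd = [[0.0] * (nn + 1) for _ in range(mm + 1)]
        for di in range(1, mm + 1):
            fd[di][0] = fd[di - 1][0] + DEL
        for dj in range(1, nn + 1):
            fd[0][dj] = fd[0][dj - 1] + INS
        for di in range(1, mm + 1):
            i = li + di - 1
            whole_i = l1[i] == li
            for dj in range(1, nn + 1):
                j = lj + dj - 1
                if whole_i and l2[j] == lj:
                    fd[di][dj] = min(
                        fd[di - 1][dj] + DEL,
                        fd[di][dj - 1] + INS,
                        fd[di - 1][dj - 1] + upd(i, j),
                    )
                    td[i][j] = fd[di][dj]
                else:
                    fd[di][dj] = min(
                        fd[di - 1][dj] + DEL,
                        fd[di][dj - 1] + INS,
                        fd[l1[i] - li][l2[j] - lj] + td[i][j],
                    )
        return fd, li, lj

    for k1 in kr1:
        for k2 in kr2:
            forest_table(k1, k2)

    distance = td[m][n]

    # --- backtrace (recompute forest tables along the traced path) ----
    mapping_idx: list[tuple[int, int]] = []

    def trace(i0: int, j0: int) -> None:
        fd, li, lj = forest_table(i0, j0)
        di, dj = i0 - li + 1, j0 - lj + 1
        while di > 0 or dj > 0:
            if di > 0 and dj > 0:
                i, j = li + di - 1, lj + dj - 1
                if l1[i] == li and l2[j] == lj:
                    if abs(fd[di][dj] - (fd[di - 1][dj - 1] + upd(i, j))) < _EPS:
                        mapping_idx.append((i, j))
                        di, dj = di - 1, dj - 1
                        continue
                else:
                    if abs(
                        fd[di][dj] - (fd[l1[i] - li][l2[j] - lj] + td[i][j])
                    ) < _EPS:
                        trace(i, j)
                        di, dj = l1[i] - li, l2[j] - lj
                        continue
            if di > 0 and abs(fd[di][dj] - (fd[di - 1][dj] + DEL)) < _EPS:
                di -= 1
                continue
            if dj > 0 and abs(fd[di][dj] - (fd[di][dj - 1] + INS)) < _EPS:
                dj -= 1
                continue
            raise AssertionError("backtrace failed")  # pragma: no cover

    trace(m, n)

    script = _build_script(template, target, mapping_idx, po1, po2, costs, distance)
    return distance, script


def _build_script(
    template: OrderedTree,
    target: OrderedTree,
    mapping_idx: list[tuple[int, int]],
    po1: list[TreeNode],
    po2: list[TreeNode],
    costs: CostScheme,
    distance: float,
) -> EditScript:
    tid = _ids(template, "T")
    qid = _ids(target, "Q")
    mapped_t = {id(po1[i - 1]): po2[j - 1] for i, j in mapping_idx}
    mapped_q = {id(po2[j - 1]): po1[i - 1] for i, j in mapping_idx}

    tgt_pre = target.preorder()
    tpre = {id(n): k for k, n in enumerate(tgt_pre)}
    tsize = {id(n): sum(1 for _ in n.subtree()) for n in tgt_pre}

    ops: list[EditOp] = []
    # deletes: unmapped template nodes, post-order (children first)
    for nd in template.postorder():
        if id(nd) not in mapped_t:
            ops.append(EditOp("DEL", node=tid[id(nd)]))

    # simulate on a working shadow of the template to place inserts
    class _W:
        __slots__ = ("ref", "t_img", "children", "parent")

        def __init__(self, ref, t_img):
            self.ref = ref
            self.t_img = t_img
            self.children: list[_W] = []
            self.parent: _W | None = None

    def shadow(n: TreeNode) -> _W:
        w = _W(tid[id(n)], mapped_t.get(id(n)))
        for c in n.children:
            cw = shadow(c)
            cw.parent = w
            w.children.append(cw)
        return w

    wroot = shadow(template.root)
    # delete unmapped shadows (post-order: children spliced first)
    def prune(w: _W) -> None:
        for c in list(w.children):
            prune(c)
        if w.t_img is None and w.parent is not None:
            p = w.parent
            k = p.children.index(w)
            for c in w.children:
                c.parent = p
            p.children[k : k + 1] = w.children

    prune(wroot)
    if wroot.t_img is None:
        raise AssertionError("roots must map under the default cost scheme")

    wimg: dict[int, _W] = {id(w.t_img): w for w in _iter_w(wroot)}

    def in_subtree(q: TreeNode, anc: TreeNode) -> bool:
        return tpre[id(anc)] < tpre[id(q)] < tpre[id(anc)] + tsize[id(anc)]

    for q in tgt_pre:
        if id(q) in mapped_q:
            continue
        p_t = q.parent
        pw = wimg[id(p_t)] if id(p_t) in wimg else None
        if pw is None:  # parent inserted earlier in pre-order
            raise AssertionError("insert parent missing")  # pragma: no cover
        adopt = [k for k, c in enumerate(pw.children) if in_subtree(c.t_img, q)]
        if adopt:
            assert adopt == list(range(adopt[0], adopt[0] + len(adopt)))
            pos, n_adopt = adopt[0], len(adopt)
        else:
            pos = sum(
                1 for c in pw.children if tpre[id(c.t_img)] < tpre[id(q)]
            )
            n_adopt = 0
        ops.append(
            EditOp(
                "INS",
                node=qid[id(q)],
                parent=pw.ref,
                pos=pos,
                n_adopt=n_adopt,
                kind=q.kind,
                letters=q.letters,
            )
        )
        nw = _W(qid[id(q)], q)
        nw.parent = pw
        nw.children = pw.children[pos : pos + n_adopt]
        for c in nw.children:
            c.parent = nw
        pw.children[pos : pos + n_adopt] = [nw]
        wimg[id(q)] = nw

    # updates: every mapped pair, target pre-order
    upd_cost = 0.0
    for q in tgt_pre:
        t = mapped_q.get(id(q))
        if t is None:
            continue
        upd_cost += costs.update_cost(t, q)
        ops.append(
            EditOp(
                "UPD",
                node=tid[id(t)],
                target=qid[id(q)],
                kind=q.kind,
                letters=q.letters,
            )
        )

    cost = (
        sum(1 for o in ops if o.op == "DEL") * costs.delete_cost
        + sum(1 for o in ops if o.op == "INS") * costs.insert_cost
        + upd_cost
    )
    mapping = sorted(
        (tid[id(po1[i - 1])], qid[id(po2[j - 1])]) for i, j in mapping_idx
    )
    assert abs(cost - distance) < _EPS, "script cost must equal the distance"
    return EditScript(ops=ops, mapping=mapping, cost=cost, distance=distance)


def _iter_w(w):
    stack = [w]
    while stack:
        x = stack.pop()
        yield x
        stack.extend(x.children)


# ----------------------------------------------------------------------
# script application


def apply_script(template: OrderedTree, script: EditScript) -> OrderedTree:
    """Replay an edit script on (a copy of) the template tree.

    Returns the resulting tree; with a script produced by :func:`ted`
    this is ordered-isomorphic to the target tree.  Raises ``KeyError``
    on references to unknown nodes.
    """
    work = template.copy()
    registry: dict[str, TreeNode] = {
        f"T{k}": n for k, n in enumerate(work.preorder())
    }
    for op in script.ops:
        if op.op == "DEL":
            nd = registry.pop(op.node)
            p = nd.parent
            if p is None:
                raise KeyError("cannot delete the root")
            k = p.children.index(nd)
            for c in nd.children:
                c.parent = p
            p.children[k : k + 1] = nd.children
        elif op.op == "INS":
            p = registry[op.parent]
            nd = TreeNode(op.kind, (), op.letters)
            nd.parent = p
            nd.children = p.children[op.pos : op.pos + op.n_adopt]
            for c in nd.children:
                c.parent = nd
            p.children[op.pos : op.pos + op.n_adopt] = [nd]
            registry[op.node] = nd
        elif op.op == "UPD":
            nd = registry[op.node]
            nd.kind = op.kind
            nd.letters = op.letters
            nd.indices = ()
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op.op}")
    out = OrderedTree(work.root)
    out.reindex()
    return out


def trees_isomorphic(a: OrderedTree, b: OrderedTree) -> bool:
    """Ordered labelled isomorphism (kind, letters, child order)."""

    def eq(x: TreeNode, y: TreeNode) -> bool:
        return (
            x.kind == y.kind
            and x.letters == y.letters
            and len(x.children) == len(y.children)
            and all(eq(cx, cy) for cx, cy in zip(x.children, y.children))
        )

    return eq(a.root, b.root)


# ----------------------------------------------------------------------
# brute-force oracle


def ted_bruteforce(
    t1: OrderedTree, t2: OrderedTree, costs: CostScheme | None = None
) -> float:
    """Exact TED by exhaustive enumeration of all valid mappings.

    A valid mapping is an injective node correspondence preserving both
    the ancestor relation and left-to-right order.  Intended as a test
    oracle; refuses trees above 10 nodes.
    """
    costs = costs or CostScheme()
    n1, n2 = t1.n_nodes, t2.n_nodes
    if n1 > 10 or n2 > 10:
        raise ValueError("brute-force oracle limited to trees of <= 10 nodes")

    def annot(tree):
        pre = {id(n): k for k, n in enumerate(tree.preorder())}
        post = {id(n): k for k, n in enumerate(tree.postorder())}
        return list(tree.preorder()), pre, post

    A, preA, postA = annot(t1)
    B, preB, postB = annot(t2)

    def rel(pre, post, x, y) -> str:
        if pre[id(x)] < pre[id(y)] and post[id(x)] > post[id(y)]:
            return "anc"
        if pre[id(x)] > pre[id(y)] and post[id(x)] < post[id(y)]:
            return "desc"
        return "left" if post[id(x)] < post[id(y)] else "right"

    best = n1 * costs.delete_cost + n2 * costs.insert_cost

    def recurse(k: int, chosen: list[tuple[TreeNode, TreeNode]], used: set[int], cost: float):
        nonlocal best
        if cost >= best:
            return
        if k == len(A):
            total = cost + (n2 - len(chosen)) * costs.insert_cost
            best = min(best, total)
            return
        a = A[k]
        # option: delete a
        recurse(k + 1, chosen, used, cost + costs.delete_cost)
        # option: map a to some compatible b
        for b in B:
            if id(b) in used:
                continue
            ok = all(
                rel(preA, postA, a2, a) == rel(preB, postB, b2, b)
                for a2, b2 in chosen
            )
            if ok:
                chosen.append((a, b))
                used.add(id(b))
                recurse(k + 1, chosen, used, cost + costs.update_cost(a, b))
                used.discard(id(b))
                chosen.pop()

    recurse(0, [], set(), 0.0)
    return best


# ----------------------------------------------------------------------
# serialization (line-oriented; enables the two-phase mapper/visualizer
# split: `map` writes this, `draw` can consume it)


def serialize_script(script: EditScript) -> str:
    lines = ["# rnalayout edit-script v1", f"DIST {script.distance:g}"]
    for t, q in script.mapping:
        pass  # mapping is implied by the UPD lines
    for op in script.ops:
        if op.op == "DEL":
            lines.append(f"DEL {op.node}")
        elif op.op == "INS":
            lines.append(
                f"INS {op.node} {op.parent} {op.pos} {op.n_adopt} "
                f"{op.kind} {' '.join(op.letters)}".rstrip()
            )
        else:
            lines.append(
                f"UPD {op.node} {op.target} {op.kind} {' '.join(op.letters)}".rstrip()
            )
    return "\n".join(lines) + "\n"


def parse_script(text: str) -> EditScript:
    ops: list[EditOp] = []
    mapping: list[tuple[str, str]] = []
    distance = 0.0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if parts[0] == "DIST":
                distance = float(parts[1])
            elif parts[0] == "DEL":
                ops.append(EditOp("DEL", node=parts[1]))
            elif parts[0] == "INS":
                ops.append(
                    EditOp(
                        "INS",
                        node=parts[1],
                        parent=parts[2],
                        pos=int(parts[3]),
                        n_adopt=int(parts[4]),
                        kind=parts[5],
                        letters=tuple(parts[6:]),
                    )
                )
            elif parts[0] == "UPD":
                ops.append(
                    EditOp(
                        "UPD",
                        node=parts[1],
                        target=parts[2],
                        kind=parts[3],
                        letters=tuple(parts[4:]),
                    )
                )
                mapping.append((parts[1], parts[2]))
            else:
                raise ValueError(f"unknown directive {parts[0]!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"edit-script line {lineno}: {exc}") from exc
    return EditScript(ops=ops, mapping=sorted(mapping), cost=distance, distance=distance)
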