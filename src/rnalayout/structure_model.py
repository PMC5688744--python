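"""Secondary-structure parsing and the ordered rooted tree view.

An RNA secondary structure is a sequence of residues plus a set of base
pairs.  When the pair set is non-crossing (pseudoknot-free) it maps onto
an ordered rooted tree: every base pair becomes an inner ``PAIR`` node,
every unpaired residue a ``LEAF``, and an artificial ``ROOT`` tops the
tree unconditionally so that structures whose outermost elements are not
enclosed by a single pair still form a tree rather than a forest.

All residue indexing in this package is 0-based; intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ParseError",
    "SecondaryStructure",
    "TreeNode",
    "OrderedTree",
    "ROOT",
    "PAIR",
    "LEAF",
    "parse_dotbracket",
    "remove_pseudoknots",
    "build_tree",
]

ROOT = "ROOT"
PAIR = "PAIR"
LEAF = "LEAF"

#: bracket alphabets stack-matched independently; layer 0 is the
#: pseudoknot-free layer, the rest encode crossing (pseudoknot) layers.
BRACKET_LAYERS: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
)


class ParseError(ValueError):
    """Raised for malformed dot-bracket or layout input."""


def _pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


@dataclass(frozen=True)
class SecondaryStructure:
    """Residue sequence plus a base-pair set (0-based, i < j).

    Crossing pairs are permitted at construction time (the parser keeps
    all bracket layers); :func:`remove_pseudoknots` produces the nested
    structure the tree model requires.
    """

    sequence: tuple[str, ...]
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < L):
                raise ValueError(f"pair ({i},{j}) out of range for length {L}")
            if i in seen or j in seen:
                raise ValueError(f"residue participates in more than one pair: ({i},{j})")
            seen.add(i)
            seen.add(j)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner(self) -> list[int | None]:
        """Partner index per residue, ``None`` when unpaired."""
        out: list[int | None] = [None] * self.length
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def is_crossing_free(self) -> bool:
        ps = sorted(self.pairs)
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                if _pairs_cross(ps[a], ps[b]):
                    return False
        return True

    def to_dotbracket(self) -> str:
        """Dot-bracket string; crossing pairs are pushed to higher
        bracket layers greedily by opening index."""
        chars = ["."] * self.length
        layers: list[list[tuple[int, int]]] = []
        for p in sorted(self.pairs):
            for layer in layers:
                if not any(_pairs_cross(p, q) for q in layer):
                    layer.append(p)
                    break
            else:
                layers.append([p])
        if len(layers) > len(BRACKET_LAYERS):
            raise ValueError("structure needs more bracket layers than supported")
        for (op, cl), layer in zip(BRACKET_LAYERS, layers):
            for i, j in layer:
                chars[i] = op
                chars[j] = cl
        return "".join(chars)


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a Vienna/DBN document.

    Expected layout: an optional ``>`` header line, one sequence line,
    one structure line of equal length.  Structure alphabet: ``.`` for
    unpaired plus the bracket layers ``()``, ``[]``, ``{}``, ``<>``,
    each stack-matched independently (so crossing pairs survive here).

    Raises :class:`ParseError` on unbalanced brackets (naming the index
    of the offending bracket), length mismatch, or unknown characters.
    """
    lines = [ln.rstrip("\r\n\t ") for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError("expected a sequence line and a structure line")
    seq, struct = lines[0], lines[1]
    if len(seq) != len(struct):
        raise ParseError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    openers = {op: k for k, (op, _) in enumerate(BRACKET_LAYERS)}
    closers = {cl: k for k, (_, cl) in enumerate(BRACKET_LAYERS)}
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(struct):
        if ch == ".":
            continue
        if ch in openers:
            stacks[openers[ch]].append(idx)
        elif ch in closers:
            st = stacks[closers[ch]]
            if not st:
                raise ParseError(f"unbalanced bracket at index {idx}")
            pairs.add((st.pop(), idx))
        else:
            raise ParseError(f"unknown structure character {ch!r} at index {idx}")
    leftovers = [st[0] for st in stacks if st]
    if leftovers:
        raise ParseError(f"unbalanced bracket at index {min(leftovers)}")
    return SecondaryStructure(tuple(seq), frozenset(pairs))


def remove_pseudoknots(ss: SecondaryStructure) -> SecondaryStructure:
    """Return a structure keeping a maximum-cardinality crossing-free
    subset of the input pairs; residues of removed pairs become unpaired.

    Interval dynamic programming over the paired positions only.  Ties
    are broken by preferring the pair with the smaller opening index.
    """
    if ss.is_crossing_free():
        return ss
    pos = sorted({i for p in ss.pairs for i in p})
    comp = {p: k for k, p in enumerate(pos)}
    partner = ss.partner()
    pc: list[int | None] = []
    for p in pos:
        q = partner[p]
        pc.append(comp[q] if q is not None and q > p else None)
    M = len(pos)
    # best[i][j] = max nested pairs using compressed positions i..j-1
    best = [[0] * (M + 1) for _ in range(M + 1)]
    for span in range(2, M + 1):
        for i in range(0, M - span + 1):
            j = i + span
            b = best[i + 1][j]
            k = pc[i]
            if k is not None and k < j:
                cand = 1 + best[i + 1][k] + best[k + 1][j]
                if cand >= b:  # prefer keeping the smaller opening index
                    b = cand
            best[i][j] = b

    kept: set[tuple[int, int]] = set()

    def reconstruct(i: int, j: int) -> None:
        stack = [(i, j)]
        while stack:
            i, j = stack.pop()
            while i < j:
                k = pc[i]
                if (
                    k is not None
                    and k < j
                    and 1 + best[i + 1][k] + best[k + 1][j] >= best[i + 1][j]
                ):
                    kept.add((pos[i], pos[k]))
                    stack.append((k + 1, j))
                    j = k
                    i += 1
                else:
                    i += 1

    reconstruct(0, M)
    return SecondaryStructure(ss.sequence, frozenset(kept))


@dataclass(eq=False)
class TreeNode:
    """Node of the ordered tree.  PAIR nodes carry two residue indices
    and letters, LEAF nodes one, ROOT none.

    ``coords`` (one 2D point per carried residue) and ``status`` are
    populated by the layout engine; structural code ignores them.
    """

    kind: str
    indices: tuple[int, ...] = ()
    letters: tuple[str, ...] = ()
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    coords: list | None = None
    status: list | None = None

    @property
    def n_residues(self) -> int:
        return {ROOT: 0, PAIR: 2, LEAF: 1}[self.kind]

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def subtree(self) -> Iterator["TreeNode"]:
        """Pre-order iteration over this node and its descendants."""
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.kind}, idx={self.indices}, kids={len(self.children)})"


class OrderedTree:
    """Rooted ordered tree for a pseudoknot-free secondary structure.

    Inner nodes are base pairs, leaves are unpaired residues, and an
    artificial root is installed unconditionally; a left-to-right
    depth-first traversal visits residue indices in increasing 5'->3'
    order (a PAIR contributes its opening index on entry and its closing
    index on exit).
    """

    def __init__(self, root: TreeNode):
        if root.kind != ROOT:
            raise ValueError("tree must be topped by a ROOT node")
        self.root = root

    # ------------------------------------------------------------------
    def preorder(self) -> list[TreeNode]:
        return list(self.root.subtree())

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.preorder())

    def residue_order(self) -> list[tuple[TreeNode, int]]:
        """(node, slot) per residue in 5'->3' order; slot is 0 for the
        opening residue of a PAIR, 1 for the closing one."""
        out: list[tuple[TreeNode, int]] = []

        def walk(n: TreeNode) -> None:
            if n.kind == PAIR:
                out.append((n, 0))
            elif n.kind == LEAF:
                out.append((n, 0))
            for c in n.children:
                walk(c)
            if n.kind == PAIR:
                out.append((n, 1))

        walk(self.root)
        return out

    def reindex(self) -> None:
        """Reassign residue indices by 5'->3' traversal order."""
        order = self.residue_order()
        fresh: dict[int, list[int]] = {}
        for idx, (node, slot) in enumerate(order):
            fresh.setdefault(id(node), [0, 0])
            if node.kind == PAIR:
                lst = list(node.indices) if len(node.indices) == 2 else [0, 0]
                lst[slot] = idx
                node.indices = tuple(lst)
            else:
                node.indices = (idx,)
        _ = fresh

    def to_secondary_structure(self) -> SecondaryStructure:
        seq: list[str] = []
        pairs: set[tuple[int, int]] = set()
        open_at: dict[int, int] = {}
        for node, slot in self.residue_order():
            idx = len(seq)
            seq.append(node.letters[slot])
            if node.kind == PAIR:
                if slot == 0:
                    open_at[id(node)] = idx
                else:
                    pairs.add((open_at.pop(id(node)), idx))
        return SecondaryStructure(tuple(seq), frozenset(pairs))

    def copy(self) -> "OrderedTree":
        """Deep structural copy (coordinates and statuses included)."""

        def clone(n: TreeNode) -> TreeNode:
            c = TreeNode(
                n.kind,
                n.indices,
                n.letters,
                coords=None if n.coords is None else [p.copy() for p in n.coords],
                status=None if n.status is None else list(n.status),
            )
            for ch in n.children:
                c.add(clone(ch))
            return c

        return OrderedTree(clone(self.root))


def build_tree(ss: SecondaryStructure) -> OrderedTree:
    """Build the ordered tree for a pseudoknot-free structure.

    Raises ``ValueError`` if crossing pairs are present (run
    :func:`remove_pseudoknots` first).
    """
    if not ss.is_crossing_free():
        raise ValueError(
            "structure contains crossing pairs; run remove_pseudoknots first"
        )
    partner = ss.partner()
    root = TreeNode(ROOT)

    def build_span(lo: int, hi: int, parent: TreeNode) -> None:
        k = lo
        while k <= hi:
            j = partner[k]
            if j is not None and j > k:
                node = TreeNode(PAIR, (k, j), (ss.sequence[k], ss.sequence[j]))
                parent.add(node)
                build_span(k + 1, j - 1, node)
                k = j + 1
            else:
                parent.add(TreeNode(LEAF, (k,), (ss.sequence[k],)))
                k += 1

    build_span(0, ss.length - 1, root)
    tree = OrderedTree(root)
    # traversal-order invariant: indices strictly increasing 5'->3'
    idxs = [n.indices[slot] for n, slot in tree.residue_order()]
    assert idxs == sorted(idxs) and len(set(idxs)) == len(idxs)
    return tree
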