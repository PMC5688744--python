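"""Synthetic structures and baseline template layouts.

Everything the pipeline needs for testing is manufactured here: random
pseudoknot-free secondary structures (hairpin loops of at least three
residues, configurable stem/loop size distributions and branching),
de-novo radial template drawings in the habitual style (straight stems,
loop residues on circles, branches directed outward), and controlled
stem/loop perturbations with known ground truth for round-trip
experiments.

One integer seed drives one documented pseudorandom stream; no global
generator state is touched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .geometry import arc_circle, perp, rotate_about, unit
from .layout_engine import Geometry, TemplateDocument, UNCHANGED
from .structure_model import (
    LEAF,
    PAIR,
    ROOT,
    OrderedTree,
    SecondaryStructure,
    TreeNode,
    build_tree,
)

__all__ = [
    "GeneratorConfig",
    "random_structure",
    "baseline_layout",
    "perturb_structure",
    "random_pair",
]

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_MIN_HAIRPIN = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random structure generator.

    stem_len / loop_len are inclusive (min, max) ranges; branch_prob is
    the probability of opening a new stem when there is room for one.
    The same seed and config always produce the same structure.
    """

    seed: int = 0
    length: int = 80
    stem_len: tuple[int, int] = (2, 6)
    loop_len: tuple[int, int] = (3, 7)
    branch_prob: float = 0.35


def random_structure(cfg: GeneratorConfig) -> SecondaryStructure:
    """Random pseudoknot-free structure of exactly cfg.length residues.

    Hairpin loops always contain at least three unpaired residues.
    Raises ``ValueError`` for infeasible configurations (length < 4).
    """
    if cfg.length < 4:
        raise ValueError("length must be at least 4")
    rng = random.Random(cfg.seed)
    smin, smax = cfg.stem_len
    lmin, lmax = cfg.loop_len
    if smin < 1 or lmin < 0:
        raise ValueError("stem_len/loop_len must be positive ranges")

    def region(n: int) -> str:
        out: list[str] = []
        while n > 0:
            min_helix = 2 * smin + _MIN_HAIRPIN
            if n >= min_helix and rng.random() < cfg.branch_prob:
                sl = rng.randint(smin, min(smax, (n - _MIN_HAIRPIN) // 2))
                inner = rng.randint(_MIN_HAIRPIN, n - 2 * sl)
                out.append("(" * sl + region_interior(inner) + ")" * sl)
                n -= 2 * sl + inner
            else:
                run = rng.randint(1, min(n, max(1, lmax)))
                out.append("." * run)
                n -= run
        return "".join(out)

    def region_interior(m: int) -> str:
        s = region(m)
        assert len(s) == m
        return s

    db = region(cfg.length)
    seq = _letters_for(db, rng)
    ss = SecondaryStructure(tuple(seq), _pairs_of(db))
    assert ss.is_crossing_free()
    return ss


def _pairs_of(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            pairs.add((stack.pop(), k))
    return frozenset(pairs)


def _letters_for(db: str, rng: random.Random) -> list[str]:
    seq = [""] * len(db)
    stack: list[int] = []
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            i = stack.pop()
            seq[i] = rng.choice("GCAU")
            seq[k] = _COMPLEMENT[seq[i]]
        else:
            seq[k] = rng.choice("GCAU")
    return seq


# ----------------------------------------------------------------------
# baseline radial drawing


def baseline_layout(
    ss: SecondaryStructure, geom: Geometry | None = None
) -> TemplateDocument:
    """De-novo radial drawing used to manufacture template layouts.

    Follows the habitual conventions: stems straight with uniform pair
    spacing, every loop's residues and branch anchors on one circle,
    branches directed radially outward from their loop, top-level
    branches spread along a horizontal chain far enough apart that
    their bounding boxes cannot collide.
    """
    geom = geom or Geometry()
    tree = build_tree(ss)
    bs, ps, bl = geom.backbone_step, geom.pair_step, geom.bond_length

    def layout_pair(nd: TreeNode, a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> None:
        nd.coords = [a.copy(), b.copy()]
        nd.status = [UNCHANGED, UNCHANGED]
        mid = 0.5 * (a + b)
        kids = nd.children
        if not kids:
            return
        pair_kids = [c for c in kids if c.kind == PAIR]
        if len(pair_kids) == 1:
            # stacked pair, bulge or internal loop: the stem continues
            # straight, unpaired residues bow out on side arcs
            child = pair_kids[0]
            ci = kids.index(child)
            n1 = ci
            n2 = len(kids) - ci - 1
            # bond perpendicular to the stem axis (straightened form),
            # sign matched to the anchor bond direction
            u = -perp(axis) if float(np.dot(-perp(axis), b - a)) >= 0 else perp(axis)
            adv = max(ps, 0.6 * bs * (max(n1, n2) + 1))
            cm = mid + axis * adv
            ca, cb = cm - u * (bl / 2), cm + u * (bl / 2)
            for leaves, an1, an2, sgn in (
                (kids[:ci], a, ca, -1.0),
                (kids[ci + 1 :], cb, b, 1.0),
            ):
                if not leaves:
                    continue
                _, _, pts = arc_circle(an1, an2, len(leaves), u * sgn, bs)
                for leaf, pt in zip(leaves, pts):
                    leaf.coords = [pt.copy()]
                    leaf.status = [UNCHANGED]
            layout_pair(child, ca, cb, axis)
            return
        slots = sum(2 if c.kind == PAIR else 1 for c in kids)
        center, _, pts = arc_circle(a, b, slots, axis, bs)
        loop_center = np.mean(np.array([a, b] + pts), axis=0)
        k = 0
        for c in kids:
            if c.kind == PAIR:
                ca, cb = pts[k], pts[k + 1]
                k += 2
                cmid = 0.5 * (ca + cb)
                cax = cmid - loop_center
                cax = unit(cax) if np.hypot(*cax) > 1e-9 else axis
                # lean branches away from the loop mouth so long stems
                # near the mouth cannot sweep back across the chain
                max_lean = np.radians(75.0)
                ang = np.arctan2(
                    axis[0] * cax[1] - axis[1] * cax[0], np.dot(axis, cax)
                )
                if abs(ang) > max_lean:
                    cax = unit(rotate_about(axis, np.zeros(2), np.sign(ang) * max_lean))
                layout_pair(c, ca, cb, cax)
            else:
                c.coords = [pts[k].copy()]
                c.status = [UNCHANGED]
                k += 1

    def bbox(nd: TreeNode) -> tuple[float, float]:
        xs = [
            q[0]
            for n in nd.subtree()
            if n.coords is not None
            for q in n.coords[: n.n_residues]
        ]
        return (min(xs), max(xs)) if xs else (0.0, 0.0)

    up = np.array([0.0, 1.0])
    cursor = 0.0
    first = True
    for c in tree.root.children:
        if c.kind == LEAF:
            if not first:
                cursor += bs
            c.coords = [np.array([cursor, 0.0])]
            c.status = [UNCHANGED]
            first = False
        else:
            # lay out at origin, then shift clear of everything placed
            layout_pair(c, np.array([0.0, 0.0]), np.array([bl, 0.0]), up)
            lo, hi = bbox(c)
            dx = (cursor + (bs if not first else 0.0)) - lo
            for n in c.subtree():
                if n.coords is not None:
                    for s in range(n.n_residues):
                        n.coords[s] = n.coords[s] + np.array([dx, 0.0])
            cursor = hi + dx
            first = False
    doc = TemplateDocument(ss, tree, geom)
    # rare residual clashes (long stems leaning over the chain) are
    # cleaned with the package's own rotation heuristic; statuses are
    # reset so the template starts pristine
    from . import postprocess

    if postprocess.count_overlaps(doc).count:
        postprocess.resolve_clashes(doc)
        for n in tree.preorder():
            if n.status is not None:
                n.status = [UNCHANGED] * n.n_residues
    return doc


# ----------------------------------------------------------------------
# controlled perturbations


def perturb_structure(
    ss: SecondaryStructure,
    ops: list[tuple[str, int, int]],
    seed: int = 0,
) -> SecondaryStructure:
    """Apply stem/loop indels with known ground truth.

    Each op is ``(kind, opening_index, delta)``:

    * ``("stem", i, -k)`` — remove the k innermost pairs of the stem
      whose outermost pair opens at residue i (residues deleted);
    * ``("stem", i, +k)`` — add k pairs at the innermost end of that
      stem (complementary letters drawn from the seeded rng);
    * ``("loop", i, ±k)`` — grow/shrink the unpaired run that starts
      just inside the pair opening at residue i.

    Reversing the deltas on the perturbed structure restores the
    original structure (pair pattern and length; deleted letters are
    not recoverable).  Raises ``ValueError`` for infeasible ops.
    """
    rng = random.Random(seed)
    seq = list(ss.sequence)
    db = list(ss.to_dotbracket())
    for kind, i, delta in sorted(ops, key=lambda o: -o[1]):
        partner = _partner_map(db)
        if kind == "stem":
            if i not in partner or partner[i] < i:
                raise ValueError(f"no pair opening at index {i}")
            s = 1
            j = partner[i]
            while i + s in partner and partner[i + s] == j - s:
                s += 1
            if delta < 0:
                k = -delta
                if k >= s:
                    raise ValueError(f"stem at {i} has only {s} pairs")
                for off in range(k):
                    del seq[j - s + 1 + k - 1 - off]
                    del db[j - s + 1 + k - 1 - off]
                for off in range(k):
                    del seq[i + s - 1 - off]
                    del db[i + s - 1 - off]
            else:
                opens = [rng.choice("GCAU") for _ in range(delta)]
                closes = [_COMPLEMENT[a] for a in reversed(opens)]
                seq[j - s + 1 : j - s + 1] = closes
                db[j - s + 1 : j - s + 1] = [")"] * delta
                seq[i + s : i + s] = opens
                db[i + s : i + s] = ["("] * delta
        elif kind == "loop":
            if i not in partner or partner[i] < i:
                raise ValueError(f"no pair opening at index {i}")
            run = 0
            while db[i + 1 + run] == ".":
                run += 1
            if delta < 0:
                if run + delta < 0:
                    raise ValueError(f"loop at {i} has only {run} unpaired residues")
                del seq[i + 1 : i + 1 - delta]
                del db[i + 1 : i + 1 - delta]
            else:
                for _ in range(delta):
                    seq.insert(i + 1, rng.choice("GCAU"))
                    db.insert(i + 1, ".")
        else:
            raise ValueError(f"unknown perturbation kind {kind!r}")
    return SecondaryStructure(tuple(seq), _pairs_of("".join(db)))


def _partner_map(db: list[str]) -> dict[int, int]:
    stack: list[int] = []
    out: dict[int, int] = {}
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            i = stack.pop()
            out[i] = k
            out[k] = i
    return out


def clash_fixture(tilt_deg: float = 30.0) -> TemplateDocument:
    """Two adjacent hairpins with the second tilted into the first.

    A constructed 2D steric collision that a single rigid rotation from
    the clash resolver's candidate set undoes completely.
    """
    from .layout_engine import _mid, _rotate_subtree, shift_subtree
    from .structure_model import parse_dotbracket

    ss = parse_dotbracket(
        "GGGGAAAACCCCGGGGAAAACCCC\n((((....))))((((....))))\n"
    )
    doc = baseline_layout(ss)
    b1, b2 = doc.tree.root.children
    base1, base2 = b1.coords[0], b2.coords[0]
    shift_subtree(
        doc, b2, np.array([(base1[0] + 24.0) - base2[0], 0.0]), flag=False
    )
    _rotate_subtree(b2, _mid(b2), np.radians(tilt_deg), flag=False)
    doc.refresh()
    return doc


def random_pair(
    seed: int,
    length: int = 60,
    max_indels: int = 5,
) -> tuple[TemplateDocument, SecondaryStructure]:
    """Seeded (template document, target structure) fixture pair.

    Draws a random structure, lays it out with the baseline layouter
    and applies up to max_indels feasible stem/loop perturbations to
    obtain the target.
    """
    rng = random.Random(seed)
    ss = random_structure(GeneratorConfig(seed=rng.randrange(2**31), length=length))
    doc = baseline_layout(ss)
    target = ss
    n_ops = rng.randint(1, max_indels)
    for _ in range(n_ops):
        partner = _partner_map(list(target.to_dotbracket()))
        opens = sorted(i for i, j in partner.items() if j > i)
        if not opens:
            break
        i = rng.choice(opens)
        db = target.to_dotbracket()
        kind = rng.choice(["stem", "loop"])
        try:
            if kind == "stem":
                delta = rng.choice([-1, 1])
                target = perturb_structure(target, [("stem", i, delta)], seed=rng.randrange(2**31))
            else:
                delta = rng.choice([-1, 1, 2])
                target = perturb_structure(target, [("loop", i, delta)], seed=rng.randrange(2**31))
        except ValueError:
            continue
    return doc, target
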