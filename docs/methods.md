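# Methods

## Model

An RNA secondary structure is a residue sequence plus a set of base
pairs; the package assumes (or enforces, see *pseudoknots*) that the
pair set is non-crossing, so the structure is an ordered rooted tree:
PAIR nodes for base pairs, LEAF nodes for unpaired residues, child
order following the 5'→3' backbone.  An artificial ROOT is installed
unconditionally, not only when the outermost residues are unpaired.
Uniform rooting removes a case split: both trees share the same
constant root, so no pairwise distance between like-rooted trees
changes, and the top-level chain (children of the root) can always be
treated the same way.

Layout transfer is a two-phase computation.  The *mapper* computes the
minimal tree edit distance between the template and target trees and a
full edit mapping; the *visualizer* replays the mapping's operations
as local modifications of the template's 2D drawing.  The phases are
independent: the mapping serializes to a line-oriented script
(`DEL`/`INS`/`UPD`), and a drawing can be regenerated repeatedly from
a stored script.

### Tree edit distance

Zhang–Shasha keyroot decomposition with full backtrace; forest tables
are recomputed along the traced path so memory stays at O(mn).  An
exhaustive enumerator over all order- and ancestry-preserving partial
injections serves as an independent oracle for trees of ≤ 10 nodes and
is never used in the production path.

Costs: insert = delete = 1; update is free between nodes of the same
kind (PAIR↔PAIR, LEAF↔LEAF) regardless of nucleotide letters and 1
between kinds.  Letter-only updates cost nothing because the layout
depends on shape, not sequence; they are still recorded ("relabeled")
for color coding.  Tie-breaking is deterministic — matches preferred
over delete+insert, backtrace walks right-to-left preferring the
diagonal — so identical inputs always yield identical scripts and
hence identical drawings.

Operation order: deletions in post-order (children before parents),
insertions in pre-order (parents first), updates last.  Every
operation therefore acts on an existing, well-positioned
neighbourhood.  One internal exception: kind-changing updates
(PAIR↔LEAF) are applied *geometrically* right after the deletions so
that insertions hanging below a kind-changed node see correct parent
geometry; the structural script keeps the plain order.

### Geometry

Constants (layout units, CLI-configurable): backbone step 8, pair step
8, bond length 8.  Equal spacing matches the habitual drawing style;
the absolute scale is arbitrary.

*Circle placement.*  n residues between two anchors are placed on the
circle through both anchors such that the n+1 arc gaps are equal; the
arc angle θ solves d·sin(θ/(2(n+1))) = s·sin(θ/2) (d anchor distance,
s backbone step), found by bracketing + bisection, making every gap's
chord exactly s.  When no root exists (anchors further apart than
(n+1)·s) the arc falls back to a semicircle and the gaps stretch
equally.

*Stem axis.*  Direction from the grandparent-pair midpoint to the
parent-pair midpoint.  With no positioned grandparent (top-level
stems), the axis is taken from the first positioned descendant pair,
or — for hairpins — from the loop-leaf centroid, which lies exactly on
the axis in any symmetric drawing; the centroid of the enclosing chain
is the last resort.  These fallbacks make insertion the exact inverse
of deletion also at the top level.

*Multibranch loops* (≥ 2 emanating stems).  If at most 2 residues are
added/removed net, the affected arcs between fixed branch anchors are
re-spaced in place (squeeze/expand) provided the resulting spacing
stays within [0.5, 2]× backbone step; otherwise — and always when a
whole new branch appears — the loop is rebuilt: all residues and
branch anchor pairs go onto one circle and each branch subtree is
rigidly rotated+translated onto its new anchor, the transform applied
to every descendant.

### Postprocessing

*Stem straightening* projects every maximal run of stacked pairs onto
the line from its first to its last pair midpoint, anchored at the
outermost pair, uniform pair-step spacing, bonds perpendicular to the
axis.  Idempotent; drawings already straight are untouched byte-wise.

*Top-level normalization* re-spaces the chain hanging off the
artificial root, whose elements have no positioned parent.  Only gaps
at edit sites (tracked during the replay) are adjusted; the downstream
tail translates rigidly.  Deliberately wide template gaps are
preserved — normalising them would break the guarantee that an
identity transform reproduces the template and that an edit can be
undone.

*Clash resolution.*  An overlap is a proper interior crossing between
two drawn segments (pair bond or backbone link) sharing no residue;
collinear overlapping segments count once, endpoint touches never.
Counting is all-pairs (vectorised, still brute force).  Subtrees
participating in boundary crossings are visited outermost-first and
rotated about their anchor pair midpoint by the best of
{±5°, ±10°, ±15°, ±20°, ±30°, ±45°, ±60°}; a rotation is kept only if
it lowers the global count, so the count is monotone non-increasing,
and rotated subtrees are not revisited (prevents oscillation).
Clashes can remain for very dissimilar template/target pairs; that is
accepted rather than attempting global untangling.

### Pseudoknots

Crossing pairs are resolved before tree construction by keeping a
maximum-cardinality crossing-free subset (interval dynamic programming
over paired positions; ties prefer the pair with the smaller opening
index).  The choice of which pairs to drop is a package convention —
any crossing-free subset would do for layout purposes.  Pseudoknot
bonds are not drawn.

## Synthetic data

The fixture generator emulates desk-scale nested RNA structures:
stems of 2–6 pairs, loops of up to 7 residues, hairpin loops of ≥ 3
residues (steric realism), branching probability 0.35, exact target
length.  Paired letters are Watson–Crick complements.  The baseline
layouter draws these in the habitual style (straight stems, loops on
circles, branches leaning outward at most 75° from their parent stem
axis so long stems cannot sweep back across the chain, top-level
branches spaced by bounding box); residual clashes — rare, long-stem
geometries — are removed with the package's own rotation heuristic, so
templates start planar.  Perturbations (stem ± k pairs at the
innermost end, loop ± k residues) have known ground truth and exact
reverses, enabling round-trip experiments: shorten a stem, then
re-derive the original structure from the shortened drawing.

What the synthetic conditions do **not** model: thermodynamic realism,
non-canonical pairs, pseudoknotted templates, and the hand-compacted
irregularity of curated rRNA drawings.  Passing tests therefore
demonstrate the correctness of the mapping and of the local geometric
operations, not fidelity to any specific curated diagram.

## Numerical choices

Float comparisons in the TED backtrace use 1e-9 (costs are small
integers).  Rigid-motion and inverse-operation checks hold to 1e-9;
arc-gap equality to 1e-6 (bisection with 200 iterations).  Status
flags have precedence inserted > relabeled > shifted > unchanged; a
residue moved by less than 1e-9 is not flagged.  Degenerate inputs:
coincident circle anchors raise; zero-length stems and empty hairpins
are drawn but never generated.

## Problem sizes

Test and acceptance runs use structures of 20–120 residues, 200 random
tree pairs (≤ 8 nodes) against the enumeration oracle, 100 script
validity pairs, 200–500 clash-monotonicity fixtures and 100 synthetic
benchmark runs — sizes at which the exhaustive oracles remain exact
and the full suite stays fast.

## Known limitations

* The squeeze threshold (net ≤ 2 indels) and spacing band
  ([0.5, 2]× backbone step) are conventions; no published values exist.
* Top-level insertion of a brand-new branch orients the new bond
  perpendicular to the local chain; the branch then grows along the
  chain direction until straightening re-orients it.
* The VARNA SVG reader recovers coordinates up to the document
  placement offset (SVG stores no model origin) and supports plain
  base pairs only.
* Layout quality degrades gracefully but unavoidably when template
  and target are structurally distant; the clash resolver is a
  heuristic, not an optimiser.
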