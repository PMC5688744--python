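# rnalayout

Template-based drawing of RNA secondary structures.

Secondary-structure diagrams of large RNAs — ribosomal RNAs above all —
are largely habitual: the community expects a particular layout, and
de-novo drawing tools rarely reproduce it.  `rnalayout` sidesteps the
ill-posed optimality problem the way homology modelling does: given a
**target** structure, a **template** structure that is sufficiently
similar, and the template's existing 2D drawing, it transfers the
drawing onto the target while changing it as little as possible.

## How it works

A pseudoknot-free secondary structure maps onto an ordered rooted tree:
base pairs become inner nodes, unpaired residues become leaves, and an
artificial root collects the top-level elements.  For template tree
*T₁* (m nodes) and target tree *T₂* (n nodes) the package computes the
ordered **tree edit distance**

> TED(T₁, T₂) = min over edit scripts of Σ cost(op), op ∈ {insert, delete, update}

with the Zhang–Shasha keyroot dynamic program (O(m²n²) time, O(mn)
memory) and backtraces a full minimal mapping.  Each edit operation has
a geometric counterpart applied to the template drawing:

* **pair inserted in a stem** — the new pair goes one pair step beyond
  its parent along the grandparent→parent direction; the subtree below
  shifts along;
* **residue inserted in a loop** — the loop is redrawn on a circle
  through its fixed anchors with equal arc gaps (chord ≈ backbone
  step);
* **residue inserted between stacked pairs** — the stem below shifts
  one backbone step to open a new bulge;
* **deletions** — exact geometric inverses of the above;
* **multibranch loops** — squeezed/expanded locally when few residues
  change, fully rebuilt on a fresh circle (branches rigidly
  re-anchored) otherwise.

Postprocessing straightens stems, re-spaces the top-level chain at
edit sites, and greedily rotates clashing subtrees to minimise the
number of overlaps (proper crossings between drawn bond/backbone
segments).

## Worked example

Make a template (structure + drawing), shorten one of its stems by two
pairs to get a target, and draw the target from the template:

```sh
rnalayout fixtures generate --seed 11 --length 60 --out-prefix tpl
# template: ...................((((((.......(((....))).))))))...........
# target  : ...................((((.......(((....))).))))...........

rnalayout map --template-structure tpl.dbn --target-structure target.dbn \
              --out target.map
# distance 2

rnalayout draw --template-layout tpl.tsv --target-structure target.dbn \
               --map target.map --out target.svg --colored --overlaps --verbose
# inserted 0 relabeled 0 shifted 18
# distance 2
# overlaps 0
```

`distance 2` is the tree edit distance: the two deleted base pairs.
The 18 `shifted` residues are the hairpin above the shortened stem and
its loop, which slid two pair steps toward the stem base; the drawing
has no remaining overlaps.  In the colored SVG, inserted residues are
red, relabeled ones green and shifted ones blue.  The `map`/`draw`
split lets one mapping be re-visualised repeatedly with different
options; omitting `--map` computes the mapping on the fly and produces
byte-identical output.

Template layouts are plain TSV (one residue per line: index, letter,
x, y, partner, status — see `rnalayout.io_formats`); a minimal
VARNA-dialect SVG reader is also provided, and drawings are written as
SVG and/or PostScript.

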