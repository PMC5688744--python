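"""Geometric layout operations and the transform pipeline."""

import numpy as np
import pytest

from conftest import max_dev, random_doc
from rnalayout.fixtures import GeneratorConfig, baseline_layout, perturb_structure, random_pair, random_structure
from rnalayout.geometry import arc_circle, distribute_on_circle
from rnalayout.layout_engine import (
    document_from_layout,
    shift_subtree,
    transform,
)
from rnalayout.structure_model import PAIR, parse_dotbracket

UP = np.array([0.0, 1.0])


class TestDistributeOnCircle:
    def test_single_point_on_bisector(self):
        (p,) = distribute_on_circle((0, 0), (4, 0), 1, UP, 8.0)
        assert p[0] == pytest.approx(2.0)
        assert p[1] > 0
        assert np.hypot(p[0], p[1]) == pytest.approx(np.hypot(p[0] - 4, p[1]))

    def test_two_points_mirror_symmetric(self):
        p1, p2 = distribute_on_circle((0, 0), (4, 0), 2, UP, 8.0)
        assert p1[0] == pytest.approx(4 - p2[0])
        assert p1[1] == pytest.approx(p2[1])

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 15])
    @pytest.mark.parametrize("d", [3.0, 8.0, 40.0, 250.0])
    def test_equal_arc_gaps(self, n, d):
        a, b = np.zeros(2), np.array([d, 0.0])
        c, r, pts = arc_circle(a, b, n, UP, 8.0)
        chain = [a] + pts + [b]
        gaps = [float(np.hypot(*(chain[k + 1] - chain[k]))) for k in range(n + 1)]
        assert max(gaps) / min(gaps) == pytest.approx(1.0, abs=1e-6)
        rads = [float(np.hypot(*(q - c))) for q in chain]
        assert max(rads) - min(rads) < 1e-6

    def test_degenerate_inputs(self):
        assert distribute_on_circle((0, 0), (4, 0), 0, UP) == []
        with pytest.raises(ValueError, match="coincide"):
            distribute_on_circle((1, 1), (1, 1), 2, UP)


class TestShiftSubtree:
    def test_rigid_translation(self, branched_doc):
        doc = branched_doc
        multibranch = doc.tree.root.children[0].children[0]
        branch = [c for c in multibranch.children if c.kind == PAIR][0]
        res = [
            (n, s) for n in branch.subtree() for s in range(n.n_residues)
        ]
        before = np.array([n.coords[s] for n, s in res])
        d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        outside = doc.layout.coords.copy()
        v = np.array([3.7, -1.2])
        shift_subtree(doc, branch, v)
        after = np.array([n.coords[s] for n, s in res])
        assert np.allclose(after - before, v, atol=1e-12)
        d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.allclose(d_before, d_after, atol=1e-9)
        moved_idx = {n.indices[s] for n, s in res}
        still = [k for k in range(len(outside)) if k not in moved_idx]
        assert np.array_equal(doc.layout.coords[still], outside[still])

    def test_zero_vector_sets_no_flags(self, hairpin_doc):
        doc = hairpin_doc
        shift_subtree(doc, doc.tree.root.children[0], np.zeros(2))
        assert doc.layout.count("shifted") == 0


def _roundtrip(doc, target, original_ss, postprocess=False):
    lay1, _ = transform(doc, target, postprocess_layout=postprocess)
    doc1 = document_from_layout(target, lay1.coords, doc.geom)
    lay2, script = transform(doc1, original_ss, postprocess_layout=postprocess)
    return lay2, script


class TestInverseOperations:
    """Insert and delete are exact geometric inverses (through the
    full replay, coordinates recover to 1e-9)."""

    @pytest.mark.parametrize(
        "op", [("stem", -1), ("stem", 1), ("loop", 1), ("loop", -1)]
    )
    def test_indel_then_inverse_recovers_coords(self, op):
        kind, delta = op
        ss = random_structure(GeneratorConfig(seed=11, length=50))
        doc = baseline_layout(ss)
        opens = sorted(i for i, j in ss.pairs)
        target = None
        for i in opens:
            try:
                target = perturb_structure(ss, [(kind, i, delta)])
                break
            except ValueError:
                continue
        assert target is not None
        lay2, _ = _roundtrip(doc, target, ss)
        assert max_dev(lay2.coords, doc.layout.coords) < 1e-9

    def test_new_bulge_opens_and_closes(self):
        # insertion point between stacked pairs: the sibling stem moves
        # exactly one backbone step and comes back on deletion
        ss = parse_dotbracket("GGGGGAAACCCCC\n(((((...)))))\n")
        doc = baseline_layout(ss)
        target = perturb_structure(ss, [("loop", 1, 1)])  # bulge after pair 2
        assert target.to_dotbracket() == "((.(((...)))))"
        lay2, _ = _roundtrip(doc, target, ss)
        assert max_dev(lay2.coords, doc.layout.coords) < 1e-9

    def test_bulge_insertion_keeps_backbone_connected(self):
        ss = parse_dotbracket("GGGGGAAACCCCC\n(((((...)))))\n")
        doc = baseline_layout(ss)
        target = perturb_structure(ss, [("loop", 2, 1)])
        lay, _ = transform(doc, target)
        steps = np.hypot(*np.diff(lay.coords, axis=0).T)
        assert steps.max() < 3 * doc.geom.backbone_step


class TestTransform:
    def test_identity_is_byte_exact(self, branched_doc):
        doc = branched_doc
        lay, script = transform(doc, doc.structure)
        assert script.distance == 0
        assert np.array_equal(lay.coords, doc.layout.coords)
        assert lay.count("inserted") == 0 and lay.count("shifted") == 0

    def test_relabel_only_keeps_coords_and_flags_green(self, hairpin_doc):
        doc = hairpin_doc
        seq = list(doc.structure.sequence)
        seq[5] = "G" if seq[5] != "G" else "C"
        from rnalayout.structure_model import SecondaryStructure

        target = SecondaryStructure(tuple(seq), doc.structure.pairs)
        lay, script = transform(doc, target)
        assert script.distance == 0
        assert np.array_equal(lay.coords, doc.layout.coords)
        assert lay.status[5] == "relabeled"
        assert lay.count("relabeled") == 1

    def test_inserted_flags_match_script(self):
        for seed in range(8):
            doc, target = random_pair(seed, length=50, max_indels=3)
            lay, script = transform(doc, target)
            assert lay.count("inserted") == script.inserted_residue_count()

    def test_all_coordinates_finite_and_distinct(self):
        for seed in range(25):
            doc, target = random_pair(seed, length=60, max_indels=5)
            lay, _ = transform(doc, target)
            assert np.all(np.isfinite(lay.coords))
            d = lay.coords[:, None, :] - lay.coords[None, :, :]
            dist = np.hypot(d[..., 0], d[..., 1])
            np.fill_diagonal(dist, np.inf)
            assert dist.min() > 1e-6

    def test_pseudoknotted_target_is_deknotted(self, hairpin_doc):
        from rnalayout.structure_model import SecondaryStructure

        doc = hairpin_doc
        L = doc.structure.length
        knotted = SecondaryStructure(
            doc.structure.sequence, frozenset({(0, 6), (3, 9)})
        )
        lay, _ = transform(doc, knotted)
        assert lay.n_residues == L

    def test_stem_roundtrip_recovers_template(self):
        """Shorten a stem by two pairs, then re-derive the original
        from the shortened drawing: coordinates recover to within a
        tenth of a backbone step."""
        ss = parse_dotbracket(
            "AGGGGGGAAAACCCCCCAAGGGGAAAACCCCA\n.((((((....))))))..((((....)))).\n"
        )
        doc = baseline_layout(ss)
        short = perturb_structure(ss, [("stem", 1, -2)])
        lay2, script = _roundtrip(doc, short, ss, postprocess=True)
        assert script.n_inserts == 2
        assert max_dev(lay2.coords, doc.layout.coords) <= 0.1 * doc.geom.backbone_step
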