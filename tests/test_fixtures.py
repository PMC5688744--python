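"""Random structure generation, baseline drawings, perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnalayout.fixtures import (
    GeneratorConfig,
    baseline_layout,
    perturb_structure,
    random_pair,
    random_structure,
)
from rnalayout.layout_engine import transform
from rnalayout.postprocess import count_overlaps
from rnalayout.structure_model import build_tree
from rnalayout.tree_edit import ted, ted_bruteforce


class TestRandomStructure:
    def test_seed_repeatability(self):
        cfg = GeneratorConfig(seed=42, length=70)
        a, b = random_structure(cfg), random_structure(cfg)
        assert a.sequence == b.sequence and a.pairs == b.pairs

    def test_infeasible_config(self):
        with pytest.raises(ValueError):
            random_structure(GeneratorConfig(seed=0, length=3))

    @given(st.integers(0, 100_000))
    @settings(max_examples=150, deadline=None)
    def test_invariants_and_min_hairpin(self, seed):
        ss = random_structure(GeneratorConfig(seed=seed, length=60))
        assert ss.length == 60
        assert ss.is_crossing_free()
        partner = ss.partner()
        for i, j in ss.pairs:
            interior = range(i + 1, j)
            if all(partner[k] is None for k in interior):
                assert j - i - 1 >= 3  # hairpin loops hold >= 3 residues


class TestBaselineLayout:
    def test_stems_collinear(self):
        doc = baseline_layout(random_structure(GeneratorConfig(seed=1, length=60)))
        from rnalayout.postprocess import _stems

        for chain in _stems(doc):
            mids = np.array(
                [0.5 * (c.coords[0] + c.coords[1]) for c in chain]
            )
            d = mids[-1] - mids[0]
            axis = d / np.hypot(*d)
            resid = mids - mids[0]
            off = resid - np.outer(resid @ axis, axis)
            assert np.abs(off).max() < 1e-9

    def test_loop_residues_on_circle(self, hairpin_doc):
        loop = hairpin_doc.tree.root.children[0]
        while loop.children and loop.children[0].kind == "PAIR":
            loop = loop.children[0]
        pts = np.array(
            [c.coords[0] for c in loop.children] + list(loop.coords)
        )
        center = None
        # all loop points equidistant from the circumcenter of three
        from rnalayout.geometry import arc_circle

        c, r, _ = arc_circle(
            loop.coords[0], loop.coords[1], len(loop.children),
            np.array([0.0, 1.0]), hairpin_doc.geom.backbone_step,
        )
        rads = np.hypot(*(pts - c).T)
        assert rads.max() - rads.min() < 1e-6

    def test_planar_for_random_structures(self):
        """Radial drawings of desk-scale nested structures are planar."""
        import random

        for seed in range(100):
            L = random.Random(seed).randint(20, 100)
            doc = baseline_layout(random_structure(GeneratorConfig(seed=seed, length=L)))
            assert count_overlaps(doc).count == 0, f"seed {seed}"


def _stem_with(ss, min_pairs):
    partner = ss.partner()
    for i in sorted(i for i, j in ss.pairs):
        if partner[i - 1] == partner[i] + 1 if i > 0 else False:
            continue  # interior of a stem
        j, s = partner[i], 1
        while i + s < ss.length and partner[i + s] == j - s:
            s += 1
        if s >= min_pairs:
            return i
    raise AssertionError("fixture has no stem long enough")


class TestPerturbStructure:
    def test_stem_deletion_count(self):
        ss = random_structure(GeneratorConfig(seed=3, length=60))
        i = _stem_with(ss, 3)
        out = perturb_structure(ss, [("stem", i, -2)])
        assert len(out.pairs) == len(ss.pairs) - 2
        assert out.length == ss.length - 4

    def test_perturb_then_reverse_restores_structure(self):
        ss = random_structure(GeneratorConfig(seed=5, length=60))
        i = _stem_with(ss, 3)
        fwd = perturb_structure(ss, [("stem", i, -2)])
        back = perturb_structure(fwd, [("stem", i, 2)])
        assert back.to_dotbracket() == ss.to_dotbracket()
        fwd = perturb_structure(ss, [("loop", i, 3)])
        back = perturb_structure(fwd, [("loop", i, -3)])
        assert back.to_dotbracket() == ss.to_dotbracket()

    def test_infeasible_ops_raise(self):
        ss = random_structure(GeneratorConfig(seed=2, length=40))
        with pytest.raises(ValueError):
            perturb_structure(ss, [("stem", 999, -1)])
        i = min(i for i, j in ss.pairs)
        with pytest.raises(ValueError):
            perturb_structure(ss, [("stem", i, -99)])

    def test_ted_equals_indel_count_for_stem_shortening(self):
        from rnalayout.structure_model import parse_dotbracket

        ss = parse_dotbracket("GGGGAAAACCCC\n((((....))))\n")
        for k in (1, 2):
            short = perturb_structure(ss, [("stem", 0, -k)])
            t1, t2 = build_tree(ss), build_tree(short)
            d, _ = ted(t1, t2)
            assert d == k == ted_bruteforce(t1, t2)


def test_full_pipeline_smoke():
    """Seeded template/target pairs run end to end: finite coordinates
    and insert-flag bookkeeping consistent with the scripts."""
    for seed in range(50):
        doc, target = random_pair(seed, length=55, max_indels=5)
        lay, script = transform(doc, target)
        assert np.all(np.isfinite(lay.coords))
        assert lay.count("inserted") == script.inserted_residue_count()
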