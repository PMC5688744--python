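import numpy as np
import pytest

from rnalayout.fixtures import GeneratorConfig, baseline_layout, random_structure
from rnalayout.structure_model import parse_dotbracket


@pytest.fixture
def hairpin_doc():
    """Single hairpin: 4-pair stem closing a 4-residue loop."""
    ss = parse_dotbracket("GGGGAAAACCCC\n((((....))))\n")
    return baseline_layout(ss)


@pytest.fixture
def branched_doc():
    """Multibranch: two hairpins inside an enclosing stem."""
    ss = parse_dotbracket(
        "GGAAGGGAAAACCCAAGGGAAAACCCAACC\n((..(((....)))..(((....)))..))\n"
    )
    return baseline_layout(ss)


def random_doc(seed, length=60):
    return baseline_layout(random_structure(GeneratorConfig(seed=seed, length=length)))


def max_dev(a, b):
    return float(np.max(np.hypot(*(np.asarray(a) - np.asarray(b)).T)))
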