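import numpy as np
import pytest

from alphastrand import (
    BackboneSpec,
    ConformationState,
    build_backbone,
    ideal_alpha_strand,
)

R = ConformationState.ALPHA_R
L = ConformationState.ALPHA_L
O = ConformationState.OTHER
U = ConformationState.UNDEFINED


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def vgs_strand():
    """Ideal VGS alpha-strand anchored at author numbers 24-26."""
    return ideal_alpha_strand("VGS", first_res_seq=24)


@pytest.fixture
def helix7():
    """7-residue right-handed helical backbone, (-60, -45) throughout."""
    return build_backbone(BackboneSpec("AAAAAAA", [(-60.0, -45.0, 180.0)] * 7))


def random_backbone_spec(rng, n_res=None, margin=2.0):
    """Random dihedral spec with phi/psi away from quadrant boundaries."""
    if n_res is None:
        n_res = int(rng.integers(4, 10))

    def draw():
        while True:
            v = float(rng.uniform(-180.0, 180.0))
            if min(abs(v), abs(abs(v) - 180.0)) > margin:
                return v

    dihedrals = [(draw(), draw(), 180.0) for _ in range(n_res)]
    return BackboneSpec("A" * n_res, dihedrals)
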