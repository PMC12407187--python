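import pytest

from bifacet.axial_dock import DockPose, score_pose
from bifacet.assembly_builder import build_bifaceted
from bifacet.synthetic_blocks import BlockRecipe, make_crown, make_pseudo_heterotrimer

# Small recipe keeps brute-force O(N^2) oracles fast (<= 600 CA per crown).
SMALL_RECIPE = BlockRecipe(
    n_helices_per_subunit=3, helix_length=8, ring_radius=30.0, seed=11
)

# A dock of the default crown where opposing spokes align across the
# two-fold: contacts without clashes.
ALIGNED_POSE = dict(phi=48.0, z_offset=38.0, truncation=0)


@pytest.fixture(scope="session")
def trimer():
    return make_pseudo_heterotrimer(BlockRecipe(seed=3))


@pytest.fixture(scope="session")
def crown():
    return make_crown(BlockRecipe(seed=3))


@pytest.fixture(scope="session")
def crown_b():
    return make_crown(BlockRecipe(seed=4))


@pytest.fixture(scope="session")
def small_crown():
    return make_crown(SMALL_RECIPE)


@pytest.fixture(scope="session")
def aligned_pose(crown):
    return score_pose(crown, DockPose(**ALIGNED_POSE))


@pytest.fixture(scope="session")
def assembly(crown, crown_b, aligned_pose):
    return build_bifaceted(crown, crown_b, aligned_pose)
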