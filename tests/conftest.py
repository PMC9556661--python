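import numpy as np
import pytest

from cpa.io import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid():
    """An 8x8x8 grid with a 3x3x3 cube mask."""
    idx = np.array([[x, y, z] for x in range(2, 5) for y in range(2, 5)
                    for z in range(2, 5)])
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-8.0, -8.0, -8.0]
    return VoxelGrid(shape=(8, 8, 8), affine=affine, mask_indices=idx)


@pytest.fixture(scope="session")
def tiny_scenario_dir(tmp_path_factory):
    """A small synthetic dataset shared across tests in one session.

    Uses a reduced grid and fewer subjects/frames than the default
    scenario so unit tests stay fast; planted effects keep the default
    structure.
    """
    from cpa.synthdata import PlantedRegion, ScenarioConfig, generate_dataset

    root = tmp_path_factory.mktemp("tiny_dataset")
    cfg = ScenarioConfig(
        n_smokers=4, n_nonsmokers=3, n_normative=8,
        n_high_motion_smokers=1, n_high_motion_nonsmokers=1,
        shape=(10, 10, 10), mask_center=(4.5, 4.5, 4.5), mask_radius=2.8,
        n_targets=12, n_frames=120, ladder_step=0.037,
        planted=[
            PlantedRegion((3.2, 4.5, 4.5), 1.3, "gain", 4.0,
                          "abstinent_only"),
            PlantedRegion((6.0, 4.5, 4.5), 1.3, "rank_permutation", 6,
                          "trait"),
        ],
        seed=7)
    records, normative, truth = generate_dataset(cfg, root)
    return root, cfg, records, normative, truth
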