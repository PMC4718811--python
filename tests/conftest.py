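import numpy as np
import pytest

from metconn import BrainMask, BrainVolume, SyntheticConfig, generate_cohort

# coarse analysis grid used throughout the fast tests: twice the default
# voxel spacing, covering the same brain-sized field of view
SMALL_GRID = (20, 24, 8)
SMALL_SPACING = (7.75, 7.75, 15.5)


def small_config(**overrides) -> SyntheticConfig:
    kwargs = dict(grid_shape=SMALL_GRID, voxel_spacing_mm=SMALL_SPACING, seed=0)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """One small-grid cohort with the default three-age design, few subjects."""
    cfg = small_config(group_sizes={"5wk": 6, "10wk": 6, "15wk": 5}, seed=42)
    scansets, truth = generate_cohort(cfg)
    return cfg, scansets, truth


@pytest.fixture()
def small_grid_volume() -> BrainVolume:
    """An empty volume on the standard small test grid (brain-centered origin)."""
    cfg = small_config(group_sizes={"a": 2, "b": 2})
    return BrainVolume(np.zeros(cfg.grid_shape), cfg.voxel_spacing_mm, cfg.origin_mm)


@pytest.fixture()
def ball_mask(small_grid_volume) -> BrainMask:
    vals = np.zeros(small_grid_volume.shape, dtype=bool)
    vals[4:16, 6:18, 2:6] = True
    return BrainMask(vals, small_grid_volume.voxel_spacing_mm, small_grid_volume.origin_mm)
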