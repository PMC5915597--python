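import numpy as np
import pytest

import voxelfc
from voxelfc.synth import RegionSpec, make_toy_atlas


@pytest.fixture(scope="session")
def tiny_atlas():
    """3-voxel seed region + 7-voxel region: 10 brain voxels total."""
    return make_toy_atlas(
        (7, 4, 2),
        [
            RegionSpec(1, "seed", (0, 0, 0), (3, 1, 1)),
            RegionSpec(2, "other", (0, 2, 0), (7, 1, 1)),
        ],
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """Small two-site cohort with the default injected effects, shared across
    tests that only read it."""
    cfg = voxelfc.demo_config(11, n_controls=10, n_patients=10, n_timepoints=80)
    atlas, scans, phen, truth = voxelfc.generate_cohort(cfg)
    pair_index = voxelfc.enumerate_pairs(atlas, cfg.roi_id)
    store = voxelfc.compute_store(scans, pair_index)
    return {
        "config": cfg,
        "atlas": atlas,
        "scans": scans,
        "phenotypes": phen,
        "truth": truth,
        "pair_index": pair_index,
        "store": store,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
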