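import numpy as np
import pytest

from favoxel import CohortConfig, VolumeGrid, make_toy_atlas, region_mask
from favoxel.roi_features import features_from_arrays
from favoxel.synthetic_data import cohort_arrays, generate_cohort


@pytest.fixture(scope="session")
def grid20():
    return VolumeGrid.isotropic((20, 20, 20), 2.5)


@pytest.fixture(scope="session")
def toy_atlas(grid20):
    return make_toy_atlas(grid20)


@pytest.fixture(scope="session")
def default_cohort(toy_atlas):
    """In-memory default synthetic cohort (seed 1): (ids, groups, fa stack)."""
    return cohort_arrays(CohortConfig(seed=1), toy_atlas)


@pytest.fixture(scope="session")
def cingulum_features(toy_atlas, default_cohort):
    ids, groups, fa = default_cohort
    mask = region_mask(toy_atlas, "cingulum_hippocampal")
    return features_from_arrays(fa, ids, groups, mask)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, toy_atlas):
    """Default cohort written to disk: NIfTI volumes + manifest + atlas."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(seed=1)
    generate_cohort(cfg, toy_atlas, out)
    toy_atlas.save(out / "atlas.nii.gz", out / "atlas_regions.json")
    return out
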