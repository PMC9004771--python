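import numpy as np
import pytest

import corrtf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Four-class cohort with planted hierarchy-aligned effects (10/class)."""
    cfg = corrtf.default_cohort_config(n_per_class=10, n_rois=16, seed=11)
    return corrtf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    X, edge_index, roi_ids = corrtf.cohort_features(
        [ts for _, _, ts in small_cohort.subjects]
    )
    y = np.array([label for _, label, _ in small_cohort.subjects], dtype=object)
    return X, y, edge_index, roi_ids


@pytest.fixture()
def band_signal():
    """One band-limited synthetic subject with no kernels (4 ROIs)."""
    cfg = corrtf.SimConfig(
        groups=(corrtf.GroupSpec("NC", 1),), n_rois=4, n_timepoints=130, seed=5
    )
    return corrtf.generate_cohort(cfg).subjects[0][2]
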