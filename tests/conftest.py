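import numpy as np
import pytest

import cppfmri as cf


@pytest.fixture(scope="session")
def small_atlas():
    """Three spherical ROIs on a 16x16x8 grid (fast fixture)."""
    return cf.gen_atlas((16, 16, 8), n_rois=3, roi_radius_vox=1, seed=0)


@pytest.fixture(scope="session")
def full_atlas():
    """The packaged 10-region cortico-limbic atlas."""
    return cf.default_atlas(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fc(z_vals, roi_names, subject="s1", condition="rest_pre"):
    """Build an FcMatrix from upper-triangle Fisher-z values."""
    k = len(roi_names)
    z = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    z[iu] = z_vals
    z[(iu[1], iu[0])] = z_vals
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(z, np.nan)
    return cf.FcMatrix(r, z, list(roi_names), subject, condition)
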