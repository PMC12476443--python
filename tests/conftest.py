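import numpy as np
import pytest

from cathcalib import postprocess as post
from cathcalib import synthetic as syn


@pytest.fixture(scope="session")
def scene0():
    """Default synthetic scene, seed 0."""
    return syn.generate_scene(0)


@pytest.fixture(scope="session")
def rendered0(scene0):
    """Both rendered views + true geometry for the default scene."""
    v1, v2, geom = syn.render_views(scene0)
    return v1, v2, geom


@pytest.fixture(scope="session")
def truth_centerlines(scene0, rendered0):
    """Truth centerlines of both views as CatheterCenterline objects with
    marker landmarks and the 30 mm physical separation."""
    v1, v2, _ = rendered0

    def cl(v):
        return post.CatheterCenterline(
            points=v.truth.centerline_px,
            pixel_spacing=scene0.config.pixel_spacing,
            landmark_indices=tuple(scene0.marker_indices),
            physical_length_mm=scene0.config.marker_separation_mm,
        )

    return cl(v1), cl(v2)


@pytest.fixture(scope="session")
def sequence0(scene0):
    """Default contrast-inflow sequence of the seed-0 scene."""
    return syn.render_sequence(scene0)


@pytest.fixture(scope="session")
def dip_profile():
    """1D profile with an isolated 3-px dip of depth 100 at position 60."""
    rng = np.random.default_rng(7)
    sig = 200.0 + 0.01 * rng.normal(size=128)
    sig[59:62] -= 100.0
    return sig, 60
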