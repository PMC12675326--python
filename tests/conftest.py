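"""Shared fixtures: desk-scale synthetic scenes reused across test modules.

Rendering and DIC run at a reduced image scale (640 x 400 instead of the
full 1920 x 1200 capture size) with proportionally enlarged speckle dots
so dots stay well resolved; all quantitative checks are in physical
units, which the reduced scale leaves meaningful.
"""

import pytest

from stamps3d import (
    DicConfig,
    SpeckleSpec,
    default_stereo_rig,
    make_insole_surface,
    render_stereo_pair,
)


@pytest.fixture(scope="session")
def desk_spec():
    """Speckle spec scaled for the reduced render resolution (~0.54 mm/px)."""
    return SpeckleSpec(dot_diameter_mm=2.2, diameter_variation=0.5,
                       mm_per_px=0.35, seed=3)


@pytest.fixture(scope="session")
def rig640():
    return default_stereo_rig(image_size_px=(640, 400))


@pytest.fixture(scope="session")
def flat_surface(desk_spec):
    return make_insole_surface(spec=desk_spec)


@pytest.fixture(scope="session")
def contoured_surface():
    spec = SpeckleSpec(dot_diameter_mm=2.2, diameter_variation=0.5,
                       mm_per_px=0.35, seed=7)
    return make_insole_surface(contoured=True, arch_height_mm=12.0, spec=spec)


@pytest.fixture(scope="session")
def flat_pre_pair(flat_surface, rig640):
    return render_stereo_pair(flat_surface, None, *rig640)


@pytest.fixture(scope="session")
def dic_config():
    return DicConfig(step_px=12)


@pytest.fixture(scope="session")
def speckle_image(desk_spec):
    from stamps3d import make_speckle_texture

    return make_speckle_texture(desk_spec, (256, 256)).astype(float)
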