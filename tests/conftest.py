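"""Shared fixtures: a miniature phantom exercised by most module tests."""

from __future__ import annotations

import numpy as np
import pytest

from projcomp import phantom as ph


def mini_phantom_spec(seed: int = 11) -> ph.PhantomSpec:
    """Reduced-size phantom for fast tests (8 x 12 x 8 mm brain)."""
    base = ph.PhantomSpec(
        grid_shape=(16, 24, 16),
        voxel_size_um=500.0,
        pixel_size_um=100.0,
        z_interval_um=100.0,
        n_regions=5,
        axons_per_tract=12,
        injection_radius_mm=1.0,
        seed=seed,
    )
    return ph.with_default_tracts(base)


@pytest.fixture(scope="session")
def mini_spec():
    return mini_phantom_spec()


@pytest.fixture(scope="session")
def mini_atlas(mini_spec):
    return ph.build_atlas(mini_spec)


@pytest.fixture(scope="session")
def mini_tracts(mini_spec, mini_atlas):
    return ph.build_tracts(mini_spec, mini_atlas)


@pytest.fixture(scope="session")
def mini_sections(mini_spec, mini_tracts, mini_atlas):
    rng = np.random.default_rng(mini_spec.seed)
    return ph.render_sections(mini_spec, mini_tracts, mini_atlas, rng)


@pytest.fixture(scope="session")
def mini_dwi(mini_tracts, mini_atlas):
    scheme = ph.make_gradient_scheme()
    return ph.synthesize_dwi(mini_tracts, mini_atlas, scheme, noise_sd=0.0)


def straight_tube_assets(
    shape=(40, 12, 12),
    voxel_mm=0.5,
    radius_mm=1.0,
    axis=0,
):
    """A straight tube along one axis: TractSet + all-brain atlas.

    Returns (tract_set, atlas, centerline).  The tube runs through the center
    of the cross-sectional plane.
    """
    extent = np.asarray(shape) * voxel_mm
    center = extent / 2.0
    start = np.where(np.arange(3) == axis, 0.5, center)
    end = np.where(np.arange(3) == axis, extent[axis] - 0.5, center)
    line = np.stack([start, end])
    grids = np.meshgrid(
        *[(np.arange(s) + 0.5) * voxel_mm for s in shape], indexing="ij"
    )
    perp = [i for i in range(3) if i != axis]
    dist = np.sqrt(
        (grids[perp[0]] - center[perp[0]]) ** 2 + (grids[perp[1]] - center[perp[1]]) ** 2
    )
    mask = dist <= radius_mm
    tangents = np.zeros(shape + (3,))
    direction = np.zeros(3)
    direction[axis] = 1.0
    tangents[mask] = direction
    tract_set = ph.TractSet(
        specs=(),
        centerlines_mm=[line],
        tube_masks=[mask],
        tangents=tangents,
        union_mask=mask,
    )
    atlas = ph.AtlasVolume(
        labels=np.ones(shape, dtype=np.int32),
        voxel_size_mm=voxel_mm,
        ap_origin_mm=float(extent[1] / 2.0),
    )
    return tract_set, atlas, line


@pytest.fixture(scope="session")
def straight_tube():
    return straight_tube_assets()
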