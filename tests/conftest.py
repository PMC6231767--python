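import numpy as np
import pytest

import embryocarpet as ec


@pytest.fixture(scope="session")
def small_embryo_spec():
    return ec.EmbryoSpec(semi_axes=(40.0, 12.0, 12.0),
                         voxel_spacing=(1.0, 0.5, 0.5),
                         noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def small_embryo(small_embryo_spec):
    return ec.make_embryo_volume(small_embryo_spec)


@pytest.fixture(scope="session")
def sphere_embryo():
    # near-sphere (AP axis marginally longest to satisfy the spec invariant)
    spec = ec.EmbryoSpec(semi_axes=(25.2, 25.0, 25.0),
                         voxel_spacing=(0.5, 0.5, 0.5),
                         noise_sd=0.0, seed=3)
    return ec.make_embryo_volume(spec)


@pytest.fixture(scope="session")
def sphere_carpet(sphere_embryo):
    """Weighted carpet of the near-sphere surface band (aligned manually
    because a sphere has no usable covariance axis)."""
    from embryocarpet import (align_and_rotate, build_point_cloud,
                              carpet_area_weights, extract_layer,
                              project_carpet, segment_embryo, to_cylindrical)
    stack = sphere_embryo.stack
    mask = segment_embryo(stack)
    shell = extract_layer(mask, 0.0, 3.0)
    pc = build_point_cloud(stack, shell)
    aligned = align_and_rotate(pc, (0.0, 0.0, 1.0), (0.0, 1.0, 0.0))
    cyl = to_cylindrical(aligned)
    carpet = project_carpet(cyl, 0.0, float(cyl.r.max()) + 1.0, 180, 100)
    carpet_area_weights(carpet)
    return carpet


def make_ball_mask(radius_um, spacing):
    """Digital solid sphere helper used across segmentation tests."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.ceil(radius_um / spacing).astype(int) + 2
    shape = 2 * half + 1
    zz, yy, xx = np.indices(shape)
    centers = (np.stack([zz, yy, xx], axis=-1) - half) * spacing
    return (centers ** 2).sum(axis=-1) <= radius_um ** 2
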