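"""Point-cloud construction, alignment and carpet projection contracts."""

import math

import numpy as np
import pytest

import embryocarpet as ec
from embryocarpet.projection import (CylindricalCoords, carpet_area_weights,
                                     project_carpet)


def ellipsoid_cloud(semi_axes, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(0, 1, n) ** (1 / 3)
    pts = dirs * radii[:, None] * np.asarray(semi_axes)
    return ec.PointCloud(coords=pts, intensity=np.ones(n),
                         voxel_index=np.arange(n))


def ellipsoid_grid_cloud(semi_axes, step=4.0):
    """Deterministic, symmetric lattice cloud filling an ellipsoid."""
    ax = np.asarray(semi_axes, dtype=float)
    ranges = [np.arange(-a, a + step / 2, step) for a in ax]
    g = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = ((g / ax) ** 2).sum(axis=1) <= 1.0
    pts = g[inside]
    return ec.PointCloud(coords=pts, intensity=np.ones(len(pts)),
                         voxel_index=np.arange(len(pts)))


class TestBuildPointCloud:
    def test_single_voxel_center(self):
        data = np.zeros((4, 4, 4))
        data[2, 1, 3] = 7.0
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 1, 3] = True
        stack = ec.VolumeStack(data=data, spacing=(2.0, 0.5, 0.25))
        pc = ec.build_point_cloud(stack, mask)
        assert len(pc) == 1
        # physical center: ((i+1/2) sx, (j+1/2) sy, (k+1/2) sz) in xyz
        np.testing.assert_allclose(pc.coords[0], [3.5 * 0.25, 1.5 * 0.5, 2.5 * 2.0])
        assert pc.intensity[0] == 7.0

    def test_counts_and_intensity_sum(self, small_embryo):
        pc = ec.build_point_cloud(small_embryo.stack, small_embryo.shell_mask)
        assert len(pc) == small_embryo.shell_mask.sum()
        assert pc.intensity.sum() == pytest.approx(
            float(small_embryo.stack.data[small_embryo.shell_mask].sum()))

    def test_empty_mask_errors(self, small_embryo):
        with pytest.raises(ValueError, match="empty"):
            ec.build_point_cloud(small_embryo.stack,
                                 np.zeros_like(small_embryo.mask))


class TestPrincipalAxis:
    def test_axis_aligned_ellipsoid(self):
        pc = ellipsoid_grid_cloud((100.0, 60.0, 60.0))
        axis, ratio = ec.principal_axis(pc)
        ang = math.degrees(math.acos(min(1.0, abs(axis[0]))))
        assert ang < 0.5
        assert ratio > 2.0

    def test_rotated_cloud_recovered(self):
        # brute-force oracle: rotate a known cloud, the recovered axis must
        # match the rotated x axis
        ang = math.radians(35)
        rot = np.array([[math.cos(ang), 0, -math.sin(ang)],
                        [0, 1, 0],
                        [math.sin(ang), 0, math.cos(ang)]])
        pc = ellipsoid_cloud((100.0, 60.0, 60.0), seed=1)
        rotated = ec.PointCloud(coords=pc.coords @ rot.T, intensity=pc.intensity,
                                voxel_index=pc.voxel_index)
        axis, _ = ec.principal_axis(rotated)
        expected = rot @ np.array([1.0, 0.0, 0.0])
        ang_err = math.degrees(math.acos(min(1.0, abs(float(axis @ expected)))))
        assert ang_err < 1.0

    def test_spherical_cloud_rejected(self):
        pc = ellipsoid_cloud((50.0, 50.0, 50.0), seed=2)
        with pytest.raises(ValueError, match="degenerate"):
            ec.principal_axis(pc)


class TestAlignAndCylindrical:
    def test_prealigned_identity(self):
        pc = ellipsoid_cloud((100.0, 60.0, 50.0), seed=3)
        centered = ec.PointCloud(coords=pc.coords - pc.coords.mean(axis=0),
                                 intensity=pc.intensity, voxel_index=pc.voxel_index)
        out = ec.align_and_rotate(centered, (0, 0, 1), (0, 1, 0))
        np.testing.assert_allclose(out.coords, centered.coords, atol=1e-9)

    def test_pairwise_distances_preserved(self):
        pc = ellipsoid_cloud((100.0, 60.0, 50.0), n=300, seed=4)
        out = ec.align_and_rotate(pc, (0.3, 0.5, 0.9), (1.0, 0.0, 0.0))
        d0 = np.linalg.norm(pc.coords[:, None] - pc.coords[None], axis=2)
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=2)
        np.testing.assert_allclose(d1, d0, rtol=1e-6, atol=1e-9)

    def test_dorsal_landmark_maps_to_theta_zero(self):
        # the landmark is placed exactly on the dorsal meridian: its offset
        # from the final centroid lies in span(dorsal_perp, axis)
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 20, (500, 3))
        axis = np.array([0.3, 0.2, 0.9])
        axis /= np.linalg.norm(axis)
        dorsal_dir = np.array([0.2, 0.9, 0.1])
        d_perp = dorsal_dir - (dorsal_dir @ axis) * axis
        d_perp /= np.linalg.norm(d_perp)
        landmark = coords.mean(axis=0) + 40.0 * d_perp + 5.0 * axis
        coords = np.vstack([coords, landmark])
        pc = ec.PointCloud(coords=coords, intensity=np.ones(501),
                           voxel_index=np.arange(501))
        aligned = ec.align_and_rotate(pc, axis, dorsal_dir)
        cyl = ec.to_cylindrical(aligned)
        theta = float(cyl.theta[-1])
        assert min(theta, 2 * np.pi - theta) < 1e-6

    def test_parallel_axis_and_dorsal_rejected(self):
        pc = ellipsoid_cloud((100.0, 60.0, 50.0), seed=6)
        with pytest.raises(ValueError, match="parallel"):
            ec.align_and_rotate(pc, (0, 0, 1), (0, 0, -1))

    def test_dorsal_and_ventral_meridians(self):
        pts = np.array([[0.0, 10.0, 3.0],    # dorsal (+y)
                        [0.0, -10.0, 3.0]])  # ventral (-y)
        pc = ec.PointCloud(coords=pts, intensity=np.ones(2),
                           voxel_index=np.arange(2))
        cyl = ec.to_cylindrical(pc)
        assert cyl.theta[0] == pytest.approx(0.0, abs=1e-12)
        assert cyl.theta[1] == pytest.approx(np.pi, abs=1e-12)

    def test_cylindrical_round_trip(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 30, (1000, 3))
        pc = ec.PointCloud(coords=coords, intensity=np.ones(1000),
                           voxel_index=np.arange(1000))
        cyl = ec.to_cylindrical(pc)
        np.testing.assert_allclose(cyl.to_cartesian(), coords, atol=1e-9)


def shell_cylindrical(n=20000, radius=20.0, seed=8, z_extent=40.0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-z_extent / 2, z_extent / 2, n)
    return CylindricalCoords(theta=theta, r=np.full(n, radius), z=z,
                             intensity=np.full(n, 42.0),
                             voxel_index=np.arange(n))


class TestProjectCarpet:
    def test_uniform_shell_uniform_carpet(self):
        cyl = shell_cylindrical()
        carpet = project_carpet(cyl, 10.0, 30.0, 36, 20)
        filled = carpet.image[~carpet.empty]
        assert np.all(filled == 42.0)

    def test_single_bright_point_binning(self):
        cyl = shell_cylindrical(n=5000, seed=9)
        cyl.intensity[:] = 1.0
        theta0, z0 = float(cyl.theta[17]), float(cyl.z[17])
        cyl.intensity[17] = 1000.0
        carpet = project_carpet(cyl, 10.0, 30.0, 36, 20)
        # direct binning oracle
        w = int(theta0 // carpet.dtheta)
        h = int((z0 - carpet.z_data_min) // carpet.dz)
        h = min(h, carpet.shape[1] - 1)
        bright = np.argwhere(carpet.image > 1.0)
        assert len(bright) == 1
        assert tuple(bright[0]) == (w, h)
        # backmap of that pixel returns exactly the bright point's index
        region = np.zeros(carpet.shape, bool)
        region[w, h] = True
        backs = carpet.backmap_region(region)
        assert 17 in backs
        assert len(backs) == carpet.counts[w, h]

    def test_backmap_is_lossless_partition(self):
        cyl = shell_cylindrical(n=3000, seed=10)
        carpet = project_carpet(cyl, 10.0, 30.0, 24, 16)
        seen = []
        for i in range(carpet.shape[0]):
            for j in range(carpet.shape[1]):
                seen.append(carpet.pixel_point_indices(i, j))
        flat = np.concatenate(seen)
        assert len(flat) == len(np.unique(flat)) == 3000

    def test_disjoint_regions_disjoint_voxels(self):
        cyl = shell_cylindrical(n=3000, seed=11)
        carpet = project_carpet(cyl, 10.0, 30.0, 24, 16)
        a = np.zeros(carpet.shape, bool)
        b = np.zeros(carpet.shape, bool)
        a[:12] = True
        b[12:] = True
        va, vb = carpet.backmap_region(a), carpet.backmap_region(b)
        assert len(np.intersect1d(va, vb)) == 0
        whole = carpet.backmap_region(np.ones(carpet.shape, bool))
        assert len(whole) == 3000

    def test_empty_band_errors(self):
        cyl = shell_cylindrical()
        with pytest.raises(ValueError, match="no points"):
            project_carpet(cyl, 100.0, 200.0, 10, 10)

    def test_intensity_conservation(self):
        cyl = shell_cylindrical(n=4000, seed=21)
        rng = np.random.default_rng(22)
        cyl.intensity[:] = rng.uniform(0, 100, 4000)
        carpet = project_carpet(cyl, 10.0, 30.0, 24, 16)
        ok = ~carpet.empty
        count_weighted_mean = float((carpet.image[ok] * carpet.counts[ok]).sum()
                                    / carpet.counts[ok].sum())
        assert count_weighted_mean == pytest.approx(float(cyl.intensity.mean()),
                                                    rel=1e-12)

    def test_rotation_equivariance(self):
        cyl = shell_cylindrical(n=8000, seed=12)
        n_theta = 36
        k = 5
        shift = k * 2 * np.pi / n_theta
        carpet0 = project_carpet(cyl, 10.0, 30.0, n_theta, 16)
        cyl2 = CylindricalCoords(theta=np.mod(cyl.theta + shift, 2 * np.pi),
                                 r=cyl.r, z=cyl.z, intensity=cyl.intensity,
                                 voxel_index=cyl.voxel_index)
        carpet1 = project_carpet(cyl2, 10.0, 30.0, n_theta, 16)
        np.testing.assert_array_equal(np.roll(carpet0.counts, k, axis=0),
                                      carpet1.counts)
        np.testing.assert_allclose(np.roll(carpet0.image, k, axis=0),
                                   carpet1.image, equal_nan=True, rtol=1e-12)


class TestAreaWeights:
    def test_cylinder_weight_exact(self):
        cyl = shell_cylindrical(n=60000, radius=20.0, seed=13)
        carpet = project_carpet(cyl, 10.0, 30.0, 36, 20)
        w = carpet_area_weights(carpet)
        expected = 20.0 * carpet.dtheta * carpet.dz
        interior = ~carpet.pole_flags
        interior[:, [0, -1]] = False  # edge gradients see the data cutoff
        np.testing.assert_allclose(w[interior], expected, rtol=1e-6)

    def test_weights_positive_finite(self, sphere_carpet):
        w = sphere_carpet.area_weight
        ok = ~sphere_carpet.pole_flags
        assert np.all(np.isfinite(w[ok]))
        assert np.all(w[ok] > 0)

    def test_sphere_total_area(self, sphere_carpet, sphere_embryo):
        full = np.ones(sphere_carpet.shape, bool)
        area = ec.region_area(sphere_carpet, full, include_pole_caps=True)
        assert area == pytest.approx(sphere_embryo.mesh.area, rel=0.03)

    def test_all_flagged_errors(self):
        cyl = shell_cylindrical(n=5000, seed=14)
        carpet = project_carpet(cyl, 10.0, 30.0, 12, 10)
        # radius ramp so steep along z that every bin fails the cos floor
        wild = 20.0 + 1000.0 * np.tile(np.arange(10.0), (12, 1))
        with pytest.raises(ValueError, match="flagged"):
            carpet_area_weights(carpet, radius_map=wild)
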