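"""Cell filtering, height, footprint and classification."""

import numpy as np
import pytest

import embryocarpet as ec
from embryocarpet.morphometrics import CellObject, _perimeter_chain


def box_stack(shape, boxes):
    """Binary stack with solid boxes given as (z0, z1, y0, y1, x0, x1)."""
    stack = np.zeros(shape, dtype=bool)
    for z0, z1, y0, y1, x0, x1 in boxes:
        stack[z0:z1, y0:y1, x0:x1] = True
    return stack


def make_cell(indices, spacing=(1.0, 1.0, 1.0)):
    return CellObject(indices=np.asarray(indices), spacing=spacing)


class TestLoadCellObjects:
    def test_size_filter_bounds(self):
        # components of 150, 250 and 10500 voxels: only the 250 one survives
        stack = box_stack((40, 60, 60), [
            (2, 8, 2, 7, 2, 7),       # 6*5*5 = 150
            (2, 12, 20, 25, 20, 25),  # 10*5*5 = 250
            (12, 33, 30, 55, 30, 50),  # 21*25*20 = 10500
        ])
        cells = ec.load_cell_objects(stack, (1.0, 1.0, 1.0))
        assert len(cells) == 1
        assert cells[0].volume_voxels == 250

    def test_inclusive_bounds(self):
        stack = box_stack((30, 30, 30), [(2, 10, 2, 7, 2, 7)])  # 8*5*5 = 200
        cells = ec.load_cell_objects(stack, (1.0, 1.0, 1.0))
        assert len(cells) == 1 and cells[0].volume_voxels == 200

    def test_hollow_cube_with_gap_filled(self):
        stack = np.zeros((24, 24, 24), dtype=bool)
        stack[4:16, 4:16, 4:16] = True
        stack[6:14, 6:14, 6:14] = False  # cavity
        stack[9, 9, 4] = False           # 1-voxel wall gap
        cells = ec.load_cell_objects(stack, (1.0, 1.0, 1.0))
        assert len(cells) == 1
        # cavity filled (the outermost gap voxel may stay open digitally)
        assert cells[0].volume_voxels >= 12 ** 3 - 2
        filled_set = set(map(tuple, cells[0].indices))
        assert (10, 10, 10) in filled_set  # cavity center is solid

    def test_empty_stack(self):
        assert ec.load_cell_objects(np.zeros((10, 10, 10), bool),
                                    (1.0, 1.0, 1.0)) == []

    def test_label_stack_keeps_labels(self):
        stack = np.zeros((20, 30, 30), dtype=np.int32)
        stack[2:12, 2:7, 2:7] = 3     # 250 voxels, label 3
        stack[2:12, 12, 12] = 7       # 10 voxels, dropped
        cells = ec.load_cell_objects(stack, (1.0, 1.0, 1.0))
        assert [c.label for c in cells] == [3]

    def test_continuous_input_rejected(self):
        with pytest.raises(ValueError, match="binary or integer"):
            ec.load_cell_objects(np.random.default_rng(0).random((5, 5, 5)),
                                 (1.0, 1.0, 1.0))


class TestCellHeight:
    def test_column_along_normal(self):
        idx = [(z, 5, 5) for z in range(3, 8)]  # 5 voxels, sz = 1 um
        cell = make_cell(idx)
        assert ec.cell_height(cell, (0, 0, 1)) == pytest.approx(5.0)

    def test_tilted_normal_matches_corner_projection(self):
        # oracle: project all 8 corners of every voxel, take the extent
        idx = [(z, 5, 5) for z in range(3, 8)]
        cell = make_cell(idx, spacing=(1.0, 0.5, 0.5))
        normal = np.array([0.0, np.sin(np.radians(60)), np.cos(np.radians(60))])
        got = ec.cell_height(cell, normal)
        spacing = np.array([1.0, 0.5, 0.5])
        corners = []
        for v in cell.indices:
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        zyx = (np.asarray(v) + [dz, dy, dx]) * spacing
                        corners.append(zyx[::-1] @ normal)
        corners = np.asarray(corners)
        assert got == pytest.approx(float(corners.max() - corners.min()),
                                    abs=1e-9)

    def test_sphere_height_equals_diameter(self):
        rad = 6
        zz, yy, xx = np.indices((15, 15, 15)) - 7
        ball = zz ** 2 + yy ** 2 + xx ** 2 <= rad ** 2
        cell = make_cell(np.argwhere(ball))
        h = ec.cell_height(cell, (0, 0, 1))
        area, _ = ec.footprint_metrics(cell, (0, 0, 1))
        diameter = 2 * np.sqrt(area / np.pi)
        assert abs(h - diameter) <= 1.5  # within ~1 voxel


class TestFootprint:
    def test_cylinder_disc_footprint(self):
        rad_um = 10.0
        yy, xx = np.indices((25, 25)) - 12
        disc = yy ** 2 + xx ** 2 <= rad_um ** 2
        idx = [(z, y, x) for z in range(5) for y, x in np.argwhere(disc)]
        cell = make_cell(idx)
        area, circ = ec.footprint_metrics(cell, (0, 0, 1))
        assert area == pytest.approx(np.pi * rad_um ** 2, rel=0.03)
        assert circ >= 0.95
        assert circ <= 1.05

    def test_bar_circularity_matches_traced_perimeter(self):
        # 40 x 5 um bar, 1 voxel thick; oracle: closed-form chain length of
        # the rasterized rectangle footprint plus the half-pixel offset
        idx = [(0, y, x) for y in range(5) for x in range(40)]
        cell = make_cell(idx)
        area, circ = ec.footprint_metrics(cell, (0, 0, 1))
        raster_h, raster_w = 5, 40
        # all chain steps of a rectangle are axis steps
        perim = 0.948 * (2 * (raster_h - 1) + 2 * (raster_w - 1))
        expected = 4 * np.pi * area / perim ** 2
        assert circ == pytest.approx(expected, abs=1e-6)

    def test_projection_bounded_by_volume(self):
        rng = np.random.default_rng(1)
        idx = np.unique(rng.integers(0, 12, (300, 3)), axis=0)
        cell = make_cell(idx, spacing=(1.0, 0.5, 0.5))
        area, _ = ec.footprint_metrics(cell, (0, 0, 1))
        assert area <= cell.volume_voxels * 0.5 * 0.5 + 1e-9

    def test_disc_maximizes_circularity(self):
        yy, xx = np.indices((21, 21)) - 10
        disc_idx = [(0, y, x) for y, x in np.argwhere(yy ** 2 + xx ** 2 <= 81)]
        bar_idx = [(0, y, x) for y in range(3) for x in range(50)]
        _, c_disc = ec.footprint_metrics(make_cell(disc_idx), (0, 0, 1))
        _, c_bar = ec.footprint_metrics(make_cell(bar_idx), (0, 0, 1))
        assert c_disc > c_bar

    def test_rotation_consistency(self):
        # rotating cell and normal together changes metrics only through
        # rasterization
        rng = np.random.default_rng(2)
        blob = np.zeros((20, 20, 20), bool)
        blob[5:9, 4:16, 6:14] = True
        idx = np.argwhere(blob)
        cell = make_cell(idx)
        # 90-degree rotation about x: (z, y, x) -> (y, 19 - z, x)
        rot_idx = np.column_stack([idx[:, 1], 19 - idx[:, 0], idx[:, 2]])
        cell_rot = make_cell(rot_idx)
        h1 = ec.cell_height(cell, (0, 0, 1))
        h2 = ec.cell_height(cell_rot, (0, 1, 0))
        a1, c1 = ec.footprint_metrics(cell, (0, 0, 1))
        a2, c2 = ec.footprint_metrics(cell_rot, (0, 1, 0))
        assert h2 == pytest.approx(h1, rel=0.02)
        assert a2 == pytest.approx(a1, rel=0.02)
        assert c2 == pytest.approx(c1, rel=0.02)


class TestPerimeterChain:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert _perimeter_chain(m) == pytest.approx(np.pi)

    def test_rectangle_closed_form(self):
        m = np.zeros((20, 30), bool)
        m[4:12, 5:25] = True  # 8 x 20
        assert _perimeter_chain(m) == pytest.approx(0.948 * (2 * 7 + 2 * 19))

    def test_disc_close_to_true_perimeter(self):
        yy, xx = np.indices((41, 41)) - 20
        disc = yy ** 2 + xx ** 2 <= 15 ** 2
        assert _perimeter_chain(disc) == pytest.approx(2 * np.pi * 15, rel=0.04)


def synthetic_population(rng, n, area_mu, height_mu, spread=0.05):
    cells = []
    for _ in range(n):
        c = make_cell([(0, 0, 0)])
        c.footprint_area = float(area_mu * rng.normal(1.0, spread))
        c.height = float(height_mu * rng.normal(1.0, spread))
        cells.append(c)
    return cells


class TestClassifyCells:
    def test_two_populations_separated(self):
        rng = np.random.default_rng(3)
        flat_large = synthetic_population(rng, 20, area_mu=400.0, height_mu=5.0)
        tall_small = synthetic_population(rng, 20, area_mu=60.0, height_mu=25.0)
        cells = flat_large + tall_small
        labels = ec.classify_cells(cells)
        assert labels[:20] == ["extraembryonic"] * 20
        assert labels[20:] == ["ectodermal"] * 20

    def test_identical_cells_unassigned(self):
        cells = synthetic_population(np.random.default_rng(4), 5, 100.0, 10.0,
                                     spread=0.0)
        with pytest.warns(UserWarning):
            labels = ec.classify_cells(cells)
        assert labels == ["unassigned"] * 5

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        cells = (synthetic_population(rng, 10, 400.0, 5.0)
                 + synthetic_population(rng, 10, 60.0, 25.0))
        labels = ec.classify_cells(cells)
        rev = list(reversed(cells))
        labels_rev = ec.classify_cells(rev)
        assert labels_rev == list(reversed(labels))

    def test_single_cell_unassigned(self):
        cells = synthetic_population(np.random.default_rng(6), 1, 100.0, 10.0)
        assert ec.classify_cells(cells) == ["unassigned"]
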