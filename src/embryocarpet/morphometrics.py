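"""Per-cell 3D morphometrics from binary or labeled segmentation stacks.

Connected components are extracted, wall gaps up to a maximal pixel gap are
sealed and interiors filled, and components outside the plausible cell
volume range (200..10000 voxels, inclusive) are discarded as segmentation
artifacts.  Each surviving cell is quantified by centroid, voxel volume,
height along the embryo surface normal, and the area and circularity of its
2D footprint projected along that normal.  A coarse two-class split
separates large flat (extraembryonic) from small round (ectodermal) cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: inclusive voxel-count bounds for a plausible cell object
MIN_CELL_VOXELS = 200
MAX_CELL_VOXELS = 10000
#: maximal wall gap (pixels) sealed before interior filling
MAX_FILL_GAP_PX = 20

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CellObject:
    """One segmented cell: voxel indices (n, 3) zyx, spacing, and metrics."""

    indices: np.ndarray
    spacing: tuple[float, float, float]
    label: int = 0
    height: float | None = None
    footprint_area: float | None = None
    circularity: float | None = None
    class_label: str = "unassigned"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def volume_voxels(self) -> int:
        return len(self.indices)

    @property
    def volume_um3(self) -> float:
        return self.volume_voxels * float(np.prod(self.spacing))

    @property
    def centroid_um(self) -> np.ndarray:
        """Centroid in (x, y, z) um."""
        zyx = (self.indices + 0.5).mean(axis=0) * np.asarray(self.spacing)
        return zyx[::-1]

    def centers_xyz(self) -> np.ndarray:
        zyx = (self.indices + 0.5) * np.asarray(self.spacing)
        return zyx[:, ::-1]


def _fill_component(comp: np.ndarray, gap_px: int) -> np.ndarray:
    """Seal wall gaps up to ``gap_px`` and fill the enclosed interior.

    Morphological closing with a ball of radius ``gap_px / 2`` (in pixels,
    matching the isotropic-pixel gap semantics) bridges openings in the cell
    wall so that hole filling can reach the cavity; the original voxels are
    kept in any case.
    """
    radius = gap_px / 2.0
    margin = int(np.ceil(radius)) + 2
    padded = np.pad(comp, margin)
    d_out = ndimage.distance_transform_edt(~padded)
    dilated = d_out <= radius
    d_in = ndimage.distance_transform_edt(dilated)
    closed = d_in > radius
    filled = ndimage.binary_fill_holes(closed | padded, structure=_STRUCT_26)
    out = padded | filled
    sl = tuple([slice(margin, -margin)] * comp.ndim)
    return out[sl]


def load_cell_objects(stack: np.ndarray, spacing,
                      gap_px: int = MAX_FILL_GAP_PX,
                      min_voxels: int = MIN_CELL_VOXELS,
                      max_voxels: int = MAX_CELL_VOXELS) -> list[CellObject]:
    """Extract filtered cell objects from a binary or label stack.

    Components are 26-connected for binary input; label images keep their
    labels.  After gap closing and hole filling, components outside
    ``[min_voxels, max_voxels]`` (inclusive) are dropped and the number of
    dropped objects is logged.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack")
    if stack.dtype == bool:
        labels, n = ndimage.label(stack, structure=_STRUCT_26)
    elif np.issubdtype(stack.dtype, np.integer):
        labels = stack
        n = int(labels.max())
    elif np.issubdtype(stack.dtype, np.floating) and np.all(stack == stack.astype(np.int64)):
        labels = stack.astype(np.int64)
        n = int(labels.max())
    else:
        raise ValueError("input must be a binary or integer label stack")

    cells: list[CellObject] = []
    dropped = 0
    objects = ndimage.find_objects(labels)
    pad = gap_px // 2 + 2
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        padded = tuple(slice(max(0, s.start - pad), min(dim, s.stop + pad))
                       for s, dim in zip(sl, labels.shape))
        comp = labels[padded] == lab
        filled = _fill_component(comp, gap_px)
        size = int(filled.sum())
        if not (min_voxels <= size <= max_voxels):
            dropped += 1
            continue
        zi, yi, xi = np.nonzero(filled)
        offs = np.array([p.start for p in padded])
        idx = np.column_stack([zi, yi, xi]) + offs
        cells.append(CellObject(indices=idx, spacing=tuple(spacing), label=lab))
    if dropped:
        logger.info("dropped %d objects outside [%d, %d] voxels",
                    dropped, min_voxels, max_voxels)
    return cells


def _voxel_support(normal: np.ndarray, spacing_xyz: np.ndarray) -> float:
    """Extent of one voxel box along ``normal`` (support function of the box)."""
    return float(np.abs(normal * spacing_xyz).sum())


def cell_height(cell: CellObject, normal) -> float:
    """Object length (um) orthogonal to the embryo surface.

    Extent of the voxel-center projections onto the (unit) normal, plus the
    extent of one voxel along the normal; together this equals the exact
    projection extent of the voxel boxes.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    proj = cell.centers_xyz() @ normal
    spacing_xyz = np.asarray(cell.spacing)[::-1]
    height = float(proj.max() - proj.min()) + _voxel_support(normal, spacing_xyz)
    cell.height = height
    return height


def _perimeter_chain(mask: np.ndarray,
                     axis_weight: float = 0.948,
                     diag_weight: float = 1.340) -> float:
    """Perimeter of a 2D footprint by 8-connected boundary-chain tracing.

    Boundary pixels (those with a 4-neighbour outside) are walked with
    Moore-neighbour tracing.  Raw chain lengths (1 per axis step, sqrt(2)
    per diagonal) systematically overestimate smooth contours, so steps are
    weighted with the Vossepoel-Smeulders calibration (0.948 per axis step,
    1.340 per diagonal step), which makes a rasterized disc score within a
    few percent of its true perimeter.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return 0.0
    if mask.sum() == 1:
        return np.pi  # limit of the offset convention for a single pixel
    padded = np.pad(mask, 1)
    cross = ndimage.generate_binary_structure(2, 1)
    boundary = padded & ~ndimage.binary_erosion(padded, structure=cross)
    ys, xs = np.nonzero(boundary)
    bset = set(zip(ys.tolist(), xs.tolist()))
    # Moore-neighbour tracing, clockwise from the top-left boundary pixel
    start = min(bset)
    nbrs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    length = 0.0
    prev_dir = 6  # pretend we arrived moving right-to-left, start scanning up
    cur = start
    visited_steps = 0
    max_steps = 4 * len(bset) + 8
    while True:
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            dy, dx = nbrs[d]
            cand = (cur[0] + dy, cur[1] + dx)
            if cand in bset:
                length += diag_weight if (dy and dx) else axis_weight
                cur = cand
                prev_dir = (d + 4) % 8
                break
        else:
            break  # isolated pixel cluster, no neighbour
        visited_steps += 1
        if cur == start or visited_steps > max_steps:
            break
    return length


def footprint_metrics(cell: CellObject, normal) -> tuple[float, float]:
    """Footprint area (um^2) and circularity of the cell projected along the normal.

    Voxel boxes are projected onto the plane orthogonal to the (unit) normal
    and rasterized at the smallest voxel pitch; the footprint is the union
    of the projected boxes.  Circularity is ``4*pi*A / P^2`` with the
    perimeter from 8-connected boundary tracing.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # in-plane orthonormal basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = helper - np.dot(helper, normal) * normal
    u = u / np.linalg.norm(u)
    v = np.cross(normal, u)

    centers = cell.centers_xyz()
    pu = centers @ u
    pv = centers @ v
    spacing_xyz = np.asarray(cell.spacing)[::-1]
    hu = 0.5 * _voxel_support(u, spacing_xyz)
    hv = 0.5 * _voxel_support(v, spacing_xyz)

    pitch = float(min(cell.spacing))
    lo_u, lo_v = (pu - hu).min(), (pv - hv).min()
    nu = int(np.ceil(((pu + hu).max() - lo_u) / pitch)) + 1
    nv = int(np.ceil(((pv + hv).max() - lo_v) / pitch)) + 1
    raster = np.zeros((nu, nv), dtype=bool)
    iu0 = np.floor((pu - hu - lo_u) / pitch).astype(int)
    iu1 = np.ceil((pu + hu - lo_u) / pitch).astype(int)
    iv0 = np.floor((pv - hv - lo_v) / pitch).astype(int)
    iv1 = np.ceil((pv + hv - lo_v) / pitch).astype(int)
    for a0, a1, b0, b1 in zip(iu0, iu1, iv0, iv1):
        raster[a0:a1, b0:b1] = True

    area = float(raster.sum()) * pitch ** 2
    perim = _perimeter_chain(raster) * pitch
    circ = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
    cell.footprint_area = area
    cell.circularity = circ
    return area, circ


def classify_cells(cells: list[CellObject]) -> list[str]:
    """Split cells into large-flat (extraembryonic) vs small-round (ectodermal).

    Deterministic 2-means on standardized (footprint_area, height): the two
    initial centers are the pair of cells farthest apart in feature space,
    Lloyd iterations run to convergence, and the cluster with the larger
    mean footprint area is labeled ``extraembryonic``.  Returns the labels
    and annotates each cell; degenerate inputs stay ``unassigned``.
    """
    if len(cells) < 2:
        for c in cells:
            c.class_label = "unassigned"
        return [c.class_label for c in cells]
    feats = np.array([[c.footprint_area, c.height] for c in cells], dtype=float)
    if np.any(~np.isfinite(feats)):
        raise ValueError("cells must have footprint_metrics and cell_height computed")
    sd = feats.std(axis=0)
    if np.all(sd == 0):
        warnings.warn("all cells identical; classification degenerate", stacklevel=2)
        for c in cells:
            c.class_label = "unassigned"
        return [c.class_label for c in cells]
    z = (feats - feats.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    # initialize from the most separated pair of points
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = z[[i, j]]
    assign = np.zeros(len(z), dtype=int)
    for _ in range(100):
        dist = ((z[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new_assign = dist.argmin(axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            if np.any(assign == k):
                centers[k] = z[assign == k].mean(axis=0)
    if len(np.unique(assign)) < 2:
        warnings.warn("cells form a single cluster; all left unassigned",
                      stacklevel=2)
        for c in cells:
            c.class_label = "unassigned"
        return [c.class_label for c in cells]

    mean_area = [feats[assign == k, 0].mean() for k in (0, 1)]
    big = int(np.argmax(mean_area))
    names = {big: "extraembryonic", 1 - big: "ectodermal"}
    try:
        from sklearn.metrics import silhouette_score
        sil = float(silhouette_score(z, assign))
        logger.info("cell classification silhouette score: %.3f", sil)
    except Exception:  # pragma: no cover - silhouette is informational only
        pass
    for c, a in zip(cells, assign):
        c.class_label = names[int(a)]
    return [c.class_label for c in cells]


def cells_to_table(cells: list[CellObject]):
    """Tidy per-cell DataFrame (id, centroid, volume, height, footprint, class)."""
    import pandas as pd
    rows = []
    for c in cells:
        cx, cy, cz = c.centroid_um
        rows.append({
            "cell_id": c.label,
            "centroid_x_um": cx, "centroid_y_um": cy, "centroid_z_um": cz,
            "volume_voxels": c.volume_voxels,
            "volume_um3": c.volume_um3,
            "height_um": c.height,
            "footprint_area_um2": c.footprint_area,
            "circularity": c.circularity,
            "class": c.class_label,
        })
    return pd.DataFrame(rows)
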