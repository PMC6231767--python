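"""Point clouds, axis alignment and cylindrical carpet projections.

The masked voxels of a volume become a point cloud in physical (x, y, z)
coordinates.  The cloud is aligned so that the embryo's anterior-posterior
axis (dominant covariance eigenvector) runs along +z and a dorsal reference
direction lies in the +y half-plane; cylindrical coordinates
``(theta, r, z)`` then have ``theta = 0`` on the dorsal meridian and
``theta = pi`` on the ventral meridian.

A *carpet* is the 2D raster of mean intensities over ``(theta, z)`` bins of
all points inside a radial band ``[r_min, r_max)``.  Because the cylindrical
raster distorts areas at the embryo poles and in furrows, each pixel carries
an area weight

    w = r * dtheta * dz / cos(alpha)

where ``alpha`` is the angle between the local outward surface normal and
the radial direction, estimated by finite differences of the smoothed
per-bin mean radius map; this is the first-fundamental-form area element of
the surface ``r = R(theta, z)``.  Pixels where ``cos(alpha)`` falls below a
floor (the projection poles) are flagged as unreliable and excluded from
area sums.  Every pixel keeps the indices of its contributing voxels, so
regions marked on the carpet can be mapped back to the source volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import EmbryoMask, LayerShell
from .volume import VolumeStack

#: pixels with cos(alpha) below this floor are flagged as pole/furrow pixels
POLE_COS_FLOOR = 0.2
#: minimum covariance anisotropy (lambda1/lambda2) for a usable AP axis
MIN_AXIS_ANISOTROPY = 1.1


@dataclass
class PointCloud:
    """Point cloud of masked voxels: coordinates (n, 3) xyz um, intensities,
    and flat voxel indices back into the source volume."""

    coords: np.ndarray
    intensity: np.ndarray
    voxel_index: np.ndarray
    source_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        if len(self.coords) == 0:
            raise ValueError("point cloud is empty")
        if len(np.unique(self.voxel_index)) != len(self.voxel_index):
            raise ValueError("voxel_index entries must be unique")

    def __len__(self) -> int:
        return len(self.coords)


def build_point_cloud(stack: VolumeStack, mask: EmbryoMask | LayerShell | np.ndarray
                      ) -> PointCloud:
    """One point per masked voxel at its physical center, intensity copied."""
    m = mask if isinstance(mask, np.ndarray) else mask.mask
    m = np.asarray(m, dtype=bool)
    if m.shape != stack.data.shape:
        raise ValueError("mask shape does not match stack shape")
    if not m.any():
        raise ValueError("mask is empty")
    zi, yi, xi = np.nonzero(m)
    sz, sy, sx = stack.spacing
    coords = np.column_stack([(xi + 0.5) * sx, (yi + 0.5) * sy, (zi + 0.5) * sz])
    flat = np.ravel_multi_index((zi, yi, xi), stack.data.shape)
    return PointCloud(coords=coords, intensity=stack.data[zi, yi, xi],
                      voxel_index=flat, source_shape=stack.data.shape)


def principal_axis(pc: PointCloud) -> tuple[np.ndarray, float]:
    """Dominant covariance eigenvector of the cloud (the AP axis).

    Returns the unit axis, sign-fixed toward the source volume's +z, and the
    anisotropy ratio lambda1/lambda2.  Raises for near-spherical clouds,
    whose axis is not defined.
    """
    if len(pc) < 3:
        raise ValueError("need at least 3 points")
    centered = pc.coords - pc.coords.mean(axis=0)
    cov = centered.T @ centered / len(pc)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ratio = float(evals[0] / max(evals[1], 1e-300))
    if ratio < MIN_AXIS_ANISOTROPY:
        raise ValueError(
            f"axis degenerate: covariance anisotropy {ratio:.3f} < {MIN_AXIS_ANISOTROPY}")
    axis = evecs[:, 0]
    if axis[2] < 0:
        axis = -axis
    return axis, ratio


def align_and_rotate(pc: PointCloud, axis, dorsal_ref) -> PointCloud:
    """Rigidly move the cloud: centroid to origin, AP axis to +z, dorsal to +y.

    The transform is a pure rotation plus translation, so pairwise distances
    are preserved; after it, the dorsal reference direction lies in the +y
    half-plane, i.e. on the ``theta = 0`` meridian.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    dorsal = np.asarray(dorsal_ref, dtype=float)
    dorsal = dorsal / np.linalg.norm(dorsal)
    if abs(np.dot(axis, dorsal)) > 1.0 - 1e-9:
        raise ValueError("axis and dorsal reference are parallel")
    e3 = axis
    e2 = dorsal - np.dot(dorsal, e3) * e3
    e2 = e2 / np.linalg.norm(e2)
    e1 = np.cross(e2, e3)
    rot = np.vstack([e1, e2, e3])  # rows are the new basis
    centered = pc.coords - pc.coords.mean(axis=0)
    return PointCloud(coords=centered @ rot.T, intensity=pc.intensity,
                      voxel_index=pc.voxel_index, source_shape=pc.source_shape)


@dataclass
class CylindricalCoords:
    """Cylindrical coordinates of an aligned cloud: ``theta`` in [0, 2*pi)
    from the dorsal meridian, radius ``r`` um, ``z`` um along the AP axis."""

    theta: np.ndarray
    r: np.ndarray
    z: np.ndarray
    intensity: np.ndarray | None = None
    voxel_index: np.ndarray | None = None

    def to_cartesian(self) -> np.ndarray:
        x = self.r * np.sin(self.theta)
        y = self.r * np.cos(self.theta)
        return np.column_stack([x, y, self.z])


def to_cylindrical(pc: PointCloud) -> CylindricalCoords:
    """Cartesian (aligned) to cylindrical; theta=0 dorsal (+y), theta=pi ventral."""
    x, y, z = pc.coords.T
    theta = np.mod(np.arctan2(x, y), 2.0 * np.pi)
    r = np.hypot(x, y)
    return CylindricalCoords(theta=theta, r=r, z=z.copy(),
                             intensity=pc.intensity, voxel_index=pc.voxel_index)


@dataclass
class SurfaceCarpet:
    """Cylindrical carpet: mean-intensity raster over (theta, z) bins.

    ``image`` has shape (n_theta, n_z) with row 0 on the dorsal meridian;
    empty bins are NaN in ``image`` and True in ``empty``.  ``area_weight``
    and ``pole_flags`` are filled by :func:`carpet_area_weights`.  The CSR
    arrays (``indptr``, ``point_order``) give, per pixel, the contributing
    point indices; ``voxel_index`` translates them to source-volume voxels.
    """

    image: np.ndarray
    counts: np.ndarray
    radius_map: np.ndarray
    surface_radius_map: np.ndarray
    theta_edges: np.ndarray
    z_edges: np.ndarray
    r_min: float
    r_max: float
    z_data_min: float
    z_data_max: float
    indptr: np.ndarray
    point_order: np.ndarray
    voxel_index: np.ndarray | None = None
    area_weight: np.ndarray | None = None
    pole_flags: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def empty(self) -> np.ndarray:
        return self.counts == 0

    @property
    def dtheta(self) -> float:
        return float(self.theta_edges[1] - self.theta_edges[0])

    @property
    def dz(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    def pixel_point_indices(self, i: int, j: int) -> np.ndarray:
        """Indices (into the projected band's point list) under pixel (i, j)."""
        flat = i * (len(self.z_edges) - 1) + j
        return self.point_order[self.indptr[flat]: self.indptr[flat + 1]]

    def backmap_region(self, region: np.ndarray) -> np.ndarray:
        """Source voxel indices contributing to a 2D carpet region."""
        region = np.asarray(region, dtype=bool)
        if region.shape != self.shape:
            raise ValueError("region shape does not match the carpet")
        flat_bins = np.nonzero(region.ravel())[0]
        if len(flat_bins) == 0:
            return np.empty(0, dtype=np.intp)
        pieces = [self.point_order[self.indptr[b]: self.indptr[b + 1]]
                  for b in flat_bins]
        pts = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.intp)
        if self.voxel_index is None:
            return np.unique(pts)
        return np.unique(self.voxel_index[pts])


def project_carpet(cyl: CylindricalCoords, r_min: float, r_max: float,
                   n_theta: int, n_z: int) -> SurfaceCarpet:
    """Project the radial band ``[r_min, r_max)`` onto a (theta, z) raster.

    Each pixel is the mean intensity of the points in its bin; the per-bin
    mean radius is kept for the area weighting, and the indices of every
    contributing point are stored for back-mapping.
    """
    if r_min >= r_max:
        raise ValueError("need r_min < r_max")
    if n_theta < 2 or n_z < 2:
        raise ValueError("need at least 2 bins per axis")
    band = (cyl.r >= r_min) & (cyl.r < r_max)
    if not band.any():
        raise ValueError(f"no points in radial band [{r_min}, {r_max})")

    theta = cyl.theta[band]
    z = cyl.z[band]
    r = cyl.r[band]
    intensity = (cyl.intensity[band] if cyl.intensity is not None
                 else np.ones(band.sum()))
    vox = cyl.voxel_index[band] if cyl.voxel_index is not None else None

    z_lo, z_hi = float(z.min()), float(z.max())
    theta_edges = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    z_edges = np.linspace(z_lo, z_hi, n_z + 1)
    dth = theta_edges[1] - theta_edges[0]
    dz = z_edges[1] - z_edges[0]

    ti = np.clip((theta / dth).astype(np.intp), 0, n_theta - 1)
    zi = np.clip(((z - z_lo) / dz).astype(np.intp), 0, n_z - 1)
    flat = ti * n_z + zi
    nbins = n_theta * n_z

    counts = np.bincount(flat, minlength=nbins)
    sums = np.bincount(flat, weights=intensity, minlength=nbins)
    rsums = np.bincount(flat, weights=r, minlength=nbins)
    with np.errstate(invalid="ignore"):
        image = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        radius = np.where(counts > 0, rsums / np.maximum(counts, 1), np.nan)
    # outermost point per bin estimates the embryo surface radius there
    rmax = np.full(nbins, -np.inf)
    np.maximum.at(rmax, flat, r)
    rmax = np.where(np.isfinite(rmax), rmax, np.nan)

    order = np.argsort(flat, kind="stable")
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.intp)

    return SurfaceCarpet(
        image=image.reshape(n_theta, n_z),
        counts=counts.reshape(n_theta, n_z),
        radius_map=radius.reshape(n_theta, n_z),
        surface_radius_map=rmax.reshape(n_theta, n_z),
        theta_edges=theta_edges, z_edges=z_edges,
        r_min=float(r_min), r_max=float(r_max),
        z_data_min=z_lo, z_data_max=z_hi,
        indptr=indptr, point_order=order.astype(np.intp),
        voxel_index=vox,
    )


def _nan_mean_3x3(a: np.ndarray) -> np.ndarray:
    """3x3 mean ignoring NaNs, wrapping in theta (axis 0), clamped in z."""
    padded = np.pad(a, ((1, 1), (0, 0)), mode="wrap")
    padded = np.pad(padded, ((0, 0), (1, 1)), mode="edge")
    vals = np.nan_to_num(padded, nan=0.0)
    good = np.isfinite(padded).astype(float)
    ksum = ndimage.uniform_filter(vals, size=3, mode="constant") * 9.0
    kcnt = ndimage.uniform_filter(good, size=3, mode="constant") * 9.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ksum / kcnt
    out[kcnt < 0.5] = np.nan
    return out[1:-1, 1:-1]


def _interp_nan_z(a: np.ndarray) -> np.ndarray:
    """Fill NaN runs along z (axis 1) by linear interpolation per theta row.

    Bins can be empty purely through sampling aliasing (z bins finer than
    the axial voxel spacing); their surface radius is well defined and is
    interpolated from the neighbouring rings.  Leading/trailing NaNs (no
    surface) are left in place.
    """
    out = a.copy()
    idx = np.arange(a.shape[1])
    for row in out:
        good = np.isfinite(row)
        if 0 < good.sum() < len(row):
            lo, hi = np.argmax(good), len(row) - 1 - np.argmax(good[::-1])
            row[lo:hi + 1] = np.interp(idx[lo:hi + 1], idx[good], row[good])
    return out


def carpet_area_weights(carpet: SurfaceCarpet, radius_map: np.ndarray | None = None,
                        cos_floor: float = POLE_COS_FLOOR) -> np.ndarray:
    """Compute per-pixel surface-area weights and flag unreliable pole bins.

    The embryo surface is treated as a radius graph ``r = R(theta, z)``
    over the carpet grid, with ``R`` the per-bin outer surface radius
    (gaps interpolated along z, then 3x3-mean smoothed).  The angle
    ``alpha`` between the local outward normal and the radial direction
    satisfies

        cos(alpha) = 1 / sqrt(1 + (dR/dtheta / R)^2 + (dR/dz)^2)

    and the pixel's surface area is ``R * dtheta * dz / cos(alpha)`` — the
    first-fundamental-form area element.  Bins with ``cos(alpha)`` below
    ``cos_floor`` (projection poles, steep furrows) or without a defined
    radius are flagged and excluded from area sums.
    """
    R = (carpet.surface_radius_map if radius_map is None
         else np.asarray(radius_map, float))
    Rs = _nan_mean_3x3(_interp_nan_z(R))
    dth, dz = carpet.dtheta, carpet.dz

    # circular central difference in theta, ordinary gradient in z
    dR_dth = (np.roll(Rs, -1, axis=0) - np.roll(Rs, 1, axis=0)) / (2.0 * dth)
    dR_dz = np.gradient(Rs, dz, axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cos_a = 1.0 / np.sqrt(1.0 + (dR_dth / Rs) ** 2 + dR_dz ** 2)
        weight = Rs * dth * dz / cos_a

    flags = ~np.isfinite(weight) | (cos_a < cos_floor)
    if flags.all():
        raise ValueError("all carpet bins flagged; no reliable surface area")
    weight = np.where(flags, np.nan, weight)
    carpet.area_weight = weight
    carpet.pole_flags = flags
    return weight


def backmap_region(carpet: SurfaceCarpet, region: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`SurfaceCarpet.backmap_region`."""
    return carpet.backmap_region(region)


def carpet_from_band(stack: VolumeStack, mask: EmbryoMask,
                     depth_outer: float = 6.0, n_theta: int = 360,
                     n_z: int = 200, dorsal_ref=(0.0, 1.0, 0.0)
                     ) -> tuple[SurfaceCarpet, np.ndarray]:
    """Convenience pipeline: surface band (0..depth_outer um) to weighted carpet.

    Returns the carpet (with area weights computed) and the recovered AP
    axis.  The radial band of the projection is taken wide open
    (0..infinity) because the band selection already happened in depth space
    when peeling the shell.
    """
    from .segmentation import extract_layer
    shell = extract_layer(mask, 0.0, depth_outer)
    pc = build_point_cloud(stack, shell)
    axis, _ = principal_axis(pc)
    aligned = align_and_rotate(pc, axis, dorsal_ref)
    cyl = to_cylindrical(aligned)
    carpet = project_carpet(cyl, 0.0, float(cyl.r.max()) + 1.0, n_theta, n_z)
    carpet_area_weights(carpet)
    return carpet, axis
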