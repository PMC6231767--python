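"""Synthetic embryo volumes, tissue-spreading series and coupled motion movies.

Every generator returns machine-readable ground truth (solid masks, surface
meshes, per-frame area tables, velocity series) so that each downstream
analysis stage can be scored against known truth without re-derivation.

The embryo is modelled as an ellipsoid whose longest (anterior-posterior)
semi-axis points along a configurable orientation.  A bright shell of
prescribed thickness carries a membrane-like texture: the surface is
partitioned into cells by a nearest-seed (Voronoi-style) rule and voxels
near a boundary between two cells are rendered brighter, mimicking the
appearance of a membrane label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .volume import DEFAULT_SPACING, VolumeStack

# membrane boundary half-width used by the nearest-seed texture, in um
_BOUNDARY_WIDTH_UM = 0.6
# AR(1) lag-1 coefficient of the synthetic velocity processes
_AR1_COEFF = 0.5
# fraction of total surface area left open when cap growth hands over to the
# shrinking elliptical ventral window
_WINDOW_HANDOFF_FRACTION = 0.12


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class EmbryoSpec:
    """Geometry and rendering parameters of one synthetic embryo.

    ``semi_axes`` are the ellipsoid semi-axes in um with the AP semi-axis
    first (and longest); ``orientation`` is the AP axis direction as an
    (x, y, z) unit vector; ``voxel_spacing`` follows array axis order
    (z, y, x).  Intensities are arbitrary units.
    """

    semi_axes: tuple[float, float, float] = (80.0, 18.0, 18.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    shell_thickness: float = 3.0
    membrane_cell_scale: float = 6.0
    interior_intensity: float = 40.0
    shell_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0
    volume_shape: tuple[int, int, int] | None = None
    margin_um: float = 2.0

    def __post_init__(self) -> None:
        ax = np.asarray(self.semi_axes, dtype=float)
        if np.any(ax <= 0):
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if ax[0] < max(ax[1], ax[2]):
            raise ValueError("AP semi-axis (first entry) must be the longest")
        if self.shell_thickness >= ax.min():
            raise ValueError("shell_thickness must be smaller than the smallest semi-axis")
        if self.shell_thickness <= 0:
            raise ValueError("shell_thickness must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        _unit(self.orientation)

    def axis_frame(self) -> np.ndarray:
        """Orthonormal frame (3x3, rows) with row 0 = AP axis, in (x, y, z)."""
        u1 = _unit(self.orientation)
        helper = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(helper, u1)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        u2 = _unit(helper - np.dot(helper, u1) * u1)
        u3 = np.cross(u1, u2)
        return np.vstack([u1, u2, u3])

    def surface_area_analytic(self) -> float:
        """Thomsen's approximation of the ellipsoid surface area in um^2."""
        a, b, c = self.semi_axes
        p = 1.6075
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 4.0 * math.pi * s ** (1.0 / p)


@dataclass(frozen=True)
class SpreadingSpec:
    """Piecewise-linear tissue-spreading schedule with a pause and closure.

    Area grows at ``area_rate_phase1`` um^2/min until ``pause_start``, stays
    constant during the pause, then grows at ``area_rate_phase2`` until the
    ventral window closes; the window's AP extent ("height") and transverse
    extent ("width") shrink linearly at the closure rates.
    """

    area_rate_phase1: float = 500.0
    area_rate_phase2: float = 800.0
    pause_start: float = 70.0
    pause_end: float = 120.0
    closure_height_rate: float = 11.0
    closure_width_rate: float = 3.0
    frame_interval: float = 5.0
    n_frames: int = 40
    initial_area_um2: float | None = None

    def __post_init__(self) -> None:
        if not self.pause_start < self.pause_end:
            raise ValueError("pause_start must precede pause_end")
        for name in ("area_rate_phase1", "area_rate_phase2",
                     "closure_height_rate", "closure_width_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("frame_interval must be > 0 and n_frames >= 1")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval)

    def scheduled_area(self, t: np.ndarray, initial_area: float) -> np.ndarray:
        """Scheduled region area at time(s) ``t`` minutes."""
        t = np.asarray(t, dtype=float)
        growth1 = self.area_rate_phase1 * np.minimum(t, self.pause_start)
        growth2 = self.area_rate_phase2 * np.clip(t - self.pause_end, 0.0, None)
        return initial_area + growth1 + growth2


@dataclass(frozen=True)
class CoupledMotionSpec:
    """Two-channel motion movie with a controllable velocity correlation.

    The substrate channel advects with an AR(1) velocity series; the cell
    channel's velocity is ``coupling_rho`` times the substrate velocity plus
    an independent AR(1) term scaled to keep the marginal variance, plus
    white measurement noise.  Frames are sampled every ``frame_interval``
    seconds (20 s by default, ten samples per 200-s analysis window).
    """

    coupling_rho: float = 0.9
    base_velocity_sd: float = 0.24
    noise_sd: float = 0.05
    frame_interval: float = 20.0
    n_frames: int = 31
    image_size: int = 128
    texture_scale: float = 8.0
    pixel_size_um: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.coupling_rho) > 1:
            raise ValueError("|coupling_rho| must be <= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.texture_scale < 2:
            raise ValueError("texture_scale must be >= 2 px; finer texture makes "
                             "optical flow unrecoverable")
        if self.n_frames < 2 or self.image_size < 16:
            raise ValueError("need n_frames >= 2 and image_size >= 16")


# ---------------------------------------------------------------------------
# embryo volume
# ---------------------------------------------------------------------------

def _ellipsoid_field(spec: EmbryoSpec, shape: tuple[int, int, int],
                     semi_axes: np.ndarray) -> np.ndarray:
    """Implicit ellipsoid function sampled at voxel centers (<=1 inside)."""
    sz, sy, sx = spec.voxel_spacing
    nz, ny, nx = shape
    center = 0.5 * np.array([nx * sx, ny * sy, nz * sz])  # (x, y, z)
    x = (np.arange(nx) + 0.5) * sx - center[0]
    y = (np.arange(ny) + 0.5) * sy - center[1]
    z = (np.arange(nz) + 0.5) * sz - center[2]
    frame = spec.axis_frame()
    f = np.zeros(shape, dtype=np.float32)
    for row, a in zip(frame, semi_axes):
        # q = (p - c) . u  for each voxel, built by broadcasting
        q = (x[None, None, :] * row[0]
             + y[None, :, None] * row[1]
             + z[:, None, None] * row[2]).astype(np.float32)
        f += (q / np.float32(a)) ** 2
    return f


def _auto_shape(spec: EmbryoSpec) -> tuple[int, int, int]:
    frame = spec.axis_frame()
    ax = np.asarray(spec.semi_axes)
    # support of the ellipsoid along each world axis
    support = np.sqrt(((frame * ax[:, None]) ** 2).sum(axis=0))  # (x, y, z)
    sz, sy, sx = spec.voxel_spacing
    ext = 2.0 * (support + spec.margin_um)
    return (int(np.ceil(ext[2] / sz)), int(np.ceil(ext[1] / sy)),
            int(np.ceil(ext[0] / sx)))


def _check_fits(spec: EmbryoSpec, shape: tuple[int, int, int]) -> None:
    frame = spec.axis_frame()
    ax = np.asarray(spec.semi_axes)
    support = np.sqrt(((frame * ax[:, None]) ** 2).sum(axis=0))  # (x, y, z)
    sz, sy, sx = spec.voxel_spacing
    extents = np.array([shape[2] * sx, shape[1] * sy, shape[0] * sz])
    for name, sup, ext in zip("xyz", support, extents):
        if 2 * sup > ext:
            raise ValueError(
                f"ellipsoid does not fit inside the volume along the {name} axis: "
                f"needs {2 * sup:.1f} um, volume extent is {ext:.1f} um")


@dataclass
class SyntheticEmbryo:
    """Rendered synthetic embryo with exact ground truth."""

    stack: VolumeStack
    mask: np.ndarray            # exact solid binary mask
    shell_mask: np.ndarray      # bright-shell voxels only
    mesh: trimesh.Trimesh       # triangulated outer surface, vertices in (x, y, z) um
    spec: EmbryoSpec
    seeds_xyz: np.ndarray = field(default=None)  # texture seed points


def surface_seed_points(spec: EmbryoSpec, n: int | None = None) -> np.ndarray:
    """Quasi-uniform seed points on the ellipsoid surface, (n, 3) xyz um.

    A Fibonacci lattice on the unit sphere is scaled to the ellipsoid; the
    count defaults to one seed per hexagonal cell of side membrane_cell_scale.
    """
    if n is None:
        area = spec.surface_area_analytic()
        n = max(8, int(round(area / (0.866 * spec.membrane_cell_scale ** 2))))
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    golden = math.pi * (1 + 5 ** 0.5)
    theta = golden * k
    dirs = np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])
    frame = spec.axis_frame()
    ax = np.asarray(spec.semi_axes)
    # body-frame point on the ellipsoid, then rotate into world frame
    body = dirs * ax
    return body @ frame


def make_embryo_volume(spec: EmbryoSpec) -> SyntheticEmbryo:
    """Render one membrane-textured ellipsoidal embryo volume.

    Returns the intensity stack together with the exact solid mask, the
    bright-shell mask and a marching-cubes surface mesh for use as oracles.
    """
    shape = spec.volume_shape or _auto_shape(spec)
    _check_fits(spec, shape)
    ax = np.asarray(spec.semi_axes, dtype=float)

    f_outer = _ellipsoid_field(spec, shape, ax)
    f_inner = _ellipsoid_field(spec, shape, ax - spec.shell_thickness)
    solid = f_outer <= 1.0
    interior = f_inner <= 1.0
    shell = solid & ~interior

    data = np.full(shape, spec.background_intensity, dtype=np.float32)
    data[interior] = spec.interior_intensity
    data[shell] = spec.shell_intensity

    # nearest-seed membrane texture on the shell
    seeds = surface_seed_points(spec)
    sz, sy, sx = spec.voxel_spacing
    center = 0.5 * np.array([shape[2] * sx, shape[1] * sy, shape[0] * sz])
    zi, yi, xi = np.nonzero(shell)
    pts = np.column_stack([(xi + 0.5) * sx, (yi + 0.5) * sy, (zi + 0.5) * sz]) - center
    if len(pts):
        d, _ = cKDTree(seeds).query(pts, k=2, workers=-1)
        boundary = (d[:, 1] - d[:, 0]) < _BOUNDARY_WIDTH_UM
        vals = np.full(len(pts), spec.shell_intensity, dtype=np.float32)
        vals[boundary] = 1.5 * spec.shell_intensity
        data[zi, yi, xi] = vals

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    verts, faces, _, _ = marching_cubes(f_outer, level=1.0,
                                        spacing=spec.voxel_spacing)
    # marching_cubes vertices are (z, y, x) physical; convert to (x, y, z)
    # relative to the embryo center but shifted by half a voxel so that they
    # live in the same frame as voxel centers
    verts_xyz = verts[:, ::-1] + 0.5 * np.array([sx, sy, sz]) - center
    mesh = trimesh.Trimesh(vertices=verts_xyz, faces=faces, process=False)

    stack = VolumeStack(data=data, spacing=spec.voxel_spacing)
    return SyntheticEmbryo(stack=stack, mask=solid, shell_mask=shell,
                           mesh=mesh, spec=spec, seeds_xyz=seeds)


# ---------------------------------------------------------------------------
# spreading series
# ---------------------------------------------------------------------------

@dataclass
class SpreadingSeries:
    """Ground truth for one synthetic spreading experiment.

    ``area_table`` has one row per frame with the scheduled and realized
    region areas; ``face_region`` marks mesh faces inside the spreading
    region; ``region_masks`` labels the shell voxels of the region;
    ``window_masks`` holds ventral-view 2D binary masks of the open window
    for frames in the closure regime (``None`` before that), with axis 0
    along AP.
    """

    embryo: SyntheticEmbryo
    area_table: pd.DataFrame
    face_region: list[np.ndarray]
    region_masks: list[np.ndarray]
    window_masks: list[np.ndarray | None]
    window_pixel_um: float
    volumes: list[VolumeStack] | None = None


def _mesh_geodesic_from_point(mesh: trimesh.Trimesh, source_vertex: int) -> np.ndarray:
    """Single-source geodesic distance along mesh edges (edge-graph Dijkstra)."""
    edges = mesh.edges_unique
    lengths = mesh.edges_unique_length
    n = len(mesh.vertices)
    graph = coo_matrix((np.concatenate([lengths, lengths]),
                        (np.concatenate([edges[:, 0], edges[:, 1]]),
                         np.concatenate([edges[:, 1], edges[:, 0]]))),
                       shape=(n, n)).tocsr()
    return dijkstra(graph, directed=False, indices=source_vertex)


def make_spreading_series(embryo_spec: EmbryoSpec, spread: SpreadingSpec,
                          dorsal_direction=(0.0, 1.0, 0.0),
                          window_pixel_um: float = 0.5,
                          render_volumes: bool = False) -> SpreadingSeries:
    """Generate a spreading-tissue series with exact per-frame area truth.

    A surface cap centred on the dorsal pole grows so that its realized mesh
    area follows the piecewise-linear schedule (solved per frame by bisection
    on the geodesic radius).  Once the uncovered complement shrinks below a
    hand-off fraction of the total surface, the open region is re-expressed
    as a ventral elliptical window whose AP extent and transverse extent
    decrease linearly at the prescribed closure rates until both reach zero.
    """
    embryo = make_embryo_volume(embryo_spec)
    mesh = embryo.mesh
    total_area = float(mesh.area)

    t = spread.times()
    initial = spread.initial_area_um2
    if initial is None:
        initial = 0.02 * total_area
    scheduled = spread.scheduled_area(t, initial)

    dorsal = _unit(dorsal_direction)
    ap = _unit(embryo_spec.orientation)
    if abs(np.dot(dorsal, ap)) > 0.99:
        raise ValueError("dorsal_direction must not be parallel to the AP axis")

    verts = np.asarray(mesh.vertices)
    dorsal_pole = int(np.argmax(verts @ dorsal))
    geo = _mesh_geodesic_from_point(mesh, dorsal_pole)
    face_geo = geo[mesh.faces].mean(axis=1)
    face_area = mesh.area_faces

    # precompute window coordinates: AP position and transverse arc offset
    # from the ventral meridian, for faces and for shell voxels
    face_centers = verts[mesh.faces].mean(axis=1)
    lateral = np.cross(ap, dorsal)
    lateral = _unit(lateral - np.dot(lateral, ap) * ap)
    dperp = _unit(np.cross(lateral, ap))  # dorsal direction orthogonalized

    def window_coords(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zc = xyz @ ap
        yv = xyz @ dperp
        xv = xyz @ lateral
        r = np.hypot(yv, xv)
        # angle from the ventral meridian (-dperp), arc length across
        ang = np.arctan2(xv, -yv)
        return zc, np.abs(ang) * r

    f_zc, f_arc = window_coords(face_centers)
    # window is centred on the ventral meridian at the AP centre of the egg
    ventral_z = 0.0

    zi, yi, xi = np.nonzero(embryo.shell_mask)
    sz, sy, sx = embryo_spec.voxel_spacing
    shp = embryo.mask.shape
    center = 0.5 * np.array([shp[2] * sx, shp[1] * sy, shp[0] * sz])
    vox_xyz = np.column_stack([(xi + 0.5) * sx, (yi + 0.5) * sy,
                               (zi + 0.5) * sz]) - center
    v_zc, v_arc = window_coords(vox_xyz)
    vox_tree = cKDTree(verts)
    _, vox_vertex = vox_tree.query(vox_xyz, workers=-1)
    vox_geo = geo[vox_vertex]

    def cap_area(radius: float) -> float:
        return float(face_area[face_geo <= radius].sum())

    r_hi = float(np.nanmax(geo[np.isfinite(geo)]))
    handoff_area = _WINDOW_HANDOFF_FRACTION * total_area
    h_rate = spread.closure_height_rate
    w_rate = spread.closure_width_rate

    face_region, region_masks, window_masks = [], [], []
    realized, regime = [], []
    closure_active = False
    h0 = w0 = t_switch = None
    for k, tk in enumerate(t):
        open_area = total_area - scheduled[k]
        if not closure_active and open_area < 0:
            raise ValueError(
                f"area schedule exceeds the total embryo surface area "
                f"({total_area:.0f} um^2) at t={tk:.0f} min")
        if (not closure_active and open_area <= handoff_area
                and h_rate > 0 and w_rate > 0):
            closure_active = True
            t_switch = tk
            # extents chosen to match the open area at hand-off and to reach
            # zero simultaneously at the prescribed linear rates
            tau0 = math.sqrt(4.0 * open_area / (math.pi * h_rate * w_rate))
            h0, w0 = h_rate * tau0, w_rate * tau0
        if closure_active:
            h = max(0.0, h0 - h_rate * (tk - t_switch))
            w = max(0.0, w0 - w_rate * (tk - t_switch))
            if h > 0 and w > 0:
                in_win_f = (((f_zc - ventral_z) / (h / 2)) ** 2
                            + (f_arc / (w / 2)) ** 2) <= 1.0
                in_win_v = (((v_zc - ventral_z) / (h / 2)) ** 2
                            + (v_arc / (w / 2)) ** 2) <= 1.0
            else:
                in_win_f = np.zeros(len(f_zc), dtype=bool)
                in_win_v = np.zeros(len(v_zc), dtype=bool)
            fmask = ~in_win_f
            vmask = ~in_win_v
            window_masks.append(_raster_window(h, w, h0, w0, window_pixel_um))
            regime.append("closure")
        else:
            # bisection on the geodesic radius against the schedule
            lo, hi = 0.0, r_hi
            for _ in range(48):
                mid = 0.5 * (lo + hi)
                if cap_area(mid) < scheduled[k]:
                    lo = mid
                else:
                    hi = mid
            fmask = face_geo <= hi
            vmask = vox_geo <= hi
            window_masks.append(None)
            regime.append("growth")
        face_region.append(fmask)
        label = np.zeros(shp, dtype=bool)
        label[zi[vmask], yi[vmask], xi[vmask]] = True
        region_masks.append(label)
        realized.append(float(face_area[fmask].sum()))

    table = pd.DataFrame({
        "time_min": t,
        "scheduled_area_um2": scheduled,
        "realized_area_um2": realized,
        "regime": regime,
    })

    volumes = None
    if render_volumes:
        volumes = []
        for k, tk in enumerate(t):
            data = embryo.stack.data.copy()
            data[region_masks[k]] *= 1.2  # mark the spreading tissue brighter
            volumes.append(VolumeStack(data=data, spacing=embryo_spec.voxel_spacing,
                                       timestamp=float(tk)))

    return SpreadingSeries(embryo=embryo, area_table=table,
                           face_region=face_region, region_masks=region_masks,
                           window_masks=window_masks,
                           window_pixel_um=window_pixel_um, volumes=volumes)


def _raster_window(h: float, w: float, h0: float, w0: float,
                   pixel_um: float) -> np.ndarray:
    """Rasterize the elliptical ventral window; axis 0 = AP (height)."""
    nh = max(4, int(math.ceil(h0 / pixel_um)) + 4)
    nw = max(4, int(math.ceil(w0 / pixel_um)) + 4)
    za = (np.arange(nh) + 0.5) * pixel_um - nh * pixel_um / 2
    xa = (np.arange(nw) + 0.5) * pixel_um - nw * pixel_um / 2
    if h <= 0 or w <= 0:
        return np.zeros((nh, nw), dtype=bool)
    return ((za[:, None] / (h / 2)) ** 2 + (xa[None, :] / (w / 2)) ** 2) <= 1.0


# ---------------------------------------------------------------------------
# coupled motion series
# ---------------------------------------------------------------------------

@dataclass
class CoupledMotion:
    """Two-channel movie with ground-truth velocity series.

    Velocities are signed AP (image x) components in um per frame; entry
    ``t`` moves the texture between frames ``t`` and ``t+1``, so the series
    have length ``n_frames - 1``.
    """

    frames_cell: np.ndarray       # (T, H, W)
    frames_substrate: np.ndarray  # (T, H, W)
    v_cell: np.ndarray            # (T-1,) um/frame, signed
    v_substrate: np.ndarray       # (T-1,) um/frame, signed
    cell_outline: np.ndarray      # ring ROI mask (H, W)
    cell_area: np.ndarray         # filled ROI mask (H, W)
    spec: CoupledMotionSpec

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.v_cell)) * self.spec.frame_interval


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = _AR1_COEFF) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - phi ** 2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


def _smooth_texture(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Band-limited random texture with feature size ~``scale`` px, periodic."""
    from scipy.ndimage import fourier_gaussian
    white = rng.standard_normal((size, size))
    tex = np.fft.ifft2(fourier_gaussian(np.fft.fft2(white), sigma=scale / 2.0)).real
    tex = (tex - tex.mean()) / tex.std()
    return (2.0 + tex).astype(np.float64)


def _render_drift(texture: np.ndarray, shifts_px: np.ndarray) -> np.ndarray:
    """Render frames of a periodic texture at subpixel x-shifts (Fourier)."""
    size = texture.shape[1]
    f = np.fft.fft2(texture)
    freq = np.fft.fftfreq(size)
    frames = np.empty((len(shifts_px),) + texture.shape, dtype=np.float32)
    for t, s in enumerate(shifts_px):
        phase = np.exp(-2j * np.pi * freq * s)[None, :]
        frames[t] = np.fft.ifft2(f * phase).real
    return frames


def make_coupled_motion_series(spec: CoupledMotionSpec) -> CoupledMotion:
    """Render paired cell/substrate movies with a prescribed velocity coupling."""
    rng = np.random.default_rng(spec.seed)
    n_v = spec.n_frames - 1
    v_s = _ar1(rng, n_v, spec.base_velocity_sd)
    v_i = _ar1(rng, n_v, spec.base_velocity_sd)
    rho = spec.coupling_rho
    v_c = rho * v_s + math.sqrt(max(0.0, 1.0 - rho ** 2)) * v_i
    if spec.noise_sd > 0:
        v_c = v_c + rng.normal(0.0, spec.noise_sd, size=n_v)

    px = spec.pixel_size_um
    disp_s = np.concatenate([[0.0], np.cumsum(v_s)]) / px
    disp_c = np.concatenate([[0.0], np.cumsum(v_c)]) / px

    tex_c = _smooth_texture(rng, spec.image_size, spec.texture_scale)
    tex_s = _smooth_texture(rng, spec.image_size, spec.texture_scale)
    frames_c = _render_drift(tex_c, disp_c)
    frames_s = _render_drift(tex_s, disp_s)

    yy, xx = np.mgrid[: spec.image_size, : spec.image_size]
    cy = cx = spec.image_size / 2.0
    r = np.hypot(yy - cy + 0.5, xx - cx + 0.5)
    radius = spec.image_size / 5.0
    cell_area = r <= radius
    cell_outline = (r <= radius + 1.5) & (r >= radius - 1.5)

    return CoupledMotion(frames_cell=frames_c, frames_substrate=frames_s,
                         v_cell=v_c, v_substrate=v_s,
                         cell_outline=cell_outline, cell_area=cell_area,
                         spec=spec)
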