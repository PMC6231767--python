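"""Embryo segmentation and concentric layer peeling.

Intensity volumes are thresholded into exactly two solid components (embryo
and background) with a time-adaptive threshold, then the solid mask is
peeled into concentric sub-surface shells by depth-resolved erosion.

Depths are physical (um).  Erosion by depth ``r`` keeps the voxels whose
Euclidean distance to the background (computed with the anisotropic voxel
spacing) exceeds ``r``, which is exactly morphological erosion by the ball
of radius ``r`` um — an ellipsoidal structuring element in voxel units.
Shells are the half-open distance bands ``inner < d <= outer``, so any
depth grid partitions the mask exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import VolumeStack

logger = logging.getLogger(__name__)

#: weight of the current frame's Otsu threshold in the exponential smoothing
THRESHOLD_SMOOTHING = 0.3

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EmbryoMask:
    """Solid binary embryo mask: one connected component, no cavities."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    timestamp: float = 0.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def check_invariants(self) -> None:
        """Assert the solid-mask contract (single component, no cavities)."""
        if self.voxel_count == 0:
            return
        _, n = ndimage.label(self.mask, structure=_STRUCT_26)
        if n != 1:
            raise AssertionError(f"mask has {n} connected components, expected 1")
        filled = ndimage.binary_fill_holes(self.mask, structure=_STRUCT_26)
        if filled.sum() != self.voxel_count:
            raise AssertionError("mask has interior cavities; filling is not idempotent")


@dataclass
class LayerShell:
    """Concentric sub-surface band of an :class:`EmbryoMask`.

    ``depth_inner``/``depth_outer`` are distances from the embryo surface in
    um; the shell holds the voxels with surface distance in
    ``(depth_inner, depth_outer]``.
    """

    mask: np.ndarray
    depth_inner: float
    depth_outer: float
    spacing: tuple[float, float, float]
    parent: EmbryoMask | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.depth_outer <= self.depth_inner or self.depth_inner < 0:
            raise ValueError("need 0 <= depth_inner < depth_outer")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _surface_depth(mask: np.ndarray, spacing) -> np.ndarray:
    """Distance (um) of every voxel to the nearest background voxel."""
    return ndimage.distance_transform_edt(mask, sampling=spacing)


def segment_embryo(stack: VolumeStack, history: float | list[float] | None = None,
                   smoothing: float = THRESHOLD_SMOOTHING) -> EmbryoMask:
    """Segment one volume into a solid embryo mask by adaptive thresholding.

    The per-frame Otsu threshold is exponentially smoothed against the
    threshold history (weight ``smoothing`` on the new frame) to damp
    frame-to-frame flicker in time-lapse series.  All but the largest
    connected component are discarded and interior holes (dim yolk) filled.
    """
    data = np.asarray(stack.data)
    otsu = float(threshold_otsu(data))
    prev = None
    if history is not None:
        hist = np.atleast_1d(np.asarray(history, dtype=float))
        if len(hist):
            prev = float(hist[-1])
    thr = otsu if prev is None else smoothing * otsu + (1.0 - smoothing) * prev

    fg = data > thr
    if not fg.any():
        raise ValueError(f"empty foreground after thresholding at {thr:.3g}")

    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == np.argmax(counts)

    border = np.zeros_like(fg)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    border_total = int(border.sum())
    if border_total and int((fg & border).sum()) > 0.5 * border_total:
        warnings.warn("foreground touches more than half of the volume border; "
                      "the threshold likely failed", stacklevel=2)

    # 26-connected background complement prevents diagonal leaks out of cavities
    fg = ndimage.binary_fill_holes(fg, structure=_STRUCT_26)
    out = EmbryoMask(mask=fg, spacing=stack.spacing, timestamp=stack.timestamp,
                     threshold=thr)
    out.check_invariants()
    logger.debug("segmented frame t=%.1f min: threshold %.4g, %d voxels",
                 stack.timestamp, thr, out.voxel_count)
    return out


def segment_series(stacks: list[VolumeStack],
                   smoothing: float = THRESHOLD_SMOOTHING) -> list[EmbryoMask]:
    """Segment a time series, carrying the smoothed threshold across frames."""
    masks: list[EmbryoMask] = []
    thresholds: list[float] = []
    for stack in stacks:
        m = segment_embryo(stack, history=thresholds or None, smoothing=smoothing)
        thresholds.append(m.threshold)
        masks.append(m)
    return masks


def erode_surface(mask: EmbryoMask, depth: float) -> EmbryoMask:
    """Peel ``depth`` um off the mask surface (anisotropy-aware erosion)."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return EmbryoMask(mask=mask.mask.copy(), spacing=mask.spacing,
                          timestamp=mask.timestamp, threshold=mask.threshold)
    eroded = _surface_depth(mask.mask, mask.spacing) > depth
    if not eroded.any():
        warnings.warn(f"erosion depth {depth} um removed the entire mask",
                      stacklevel=2)
    return EmbryoMask(mask=eroded, spacing=mask.spacing,
                      timestamp=mask.timestamp, threshold=mask.threshold)


def extract_layer(mask: EmbryoMask, depth_inner: float,
                  depth_outer: float) -> LayerShell:
    """Extract the concentric shell between two surface depths (um).

    Equivalent to eroding at both depths and subtracting, computed from a
    single distance transform so that shells over any depth grid partition
    the mask exactly.
    """
    if depth_inner < 0 or depth_outer <= depth_inner:
        raise ValueError(
            f"need 0 <= depth_inner < depth_outer, got ({depth_inner}, {depth_outer})")
    d = _surface_depth(mask.mask, mask.spacing)
    shell = (d > depth_inner) & ~(d > depth_outer) & mask.mask
    return LayerShell(mask=shell, depth_inner=depth_inner,
                      depth_outer=depth_outer, spacing=mask.spacing, parent=mask)


def smooth_mask(mask: EmbryoMask, mode: str, radius: float) -> EmbryoMask:
    """Smooth the mask surface by morphological opening or closing.

    Opening removes protrusions smaller than ``radius`` um; closing fills
    indentations smaller than ``radius`` um.  Both use the physical ball
    structuring element and are idempotent.
    """
    if mode not in ("open", "close"):
        raise ValueError(f"mode must be 'open' or 'close', got {mode!r}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return EmbryoMask(mask=mask.mask.copy(), spacing=mask.spacing,
                          timestamp=mask.timestamp, threshold=mask.threshold)

    spacing = np.asarray(mask.spacing)
    pad = tuple(int(np.ceil(radius / s)) + 1 for s in spacing)
    m = np.pad(mask.mask, [(p, p) for p in pad], mode="constant")

    def erode(a):
        return ndimage.distance_transform_edt(a, sampling=spacing) > radius

    def dilate(a):
        return ~erode(~a)

    if mode == "open":
        out = dilate(erode(m))
    else:
        out = erode(dilate(m))
    sl = tuple(slice(p, -p) for p in pad)
    return EmbryoMask(mask=out[sl], spacing=mask.spacing,
                      timestamp=mask.timestamp, threshold=mask.threshold)
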