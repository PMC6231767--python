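"""Tissue-level kinematics: region areas, spreading phases, ventral closure,
angular cell positions and germband extension.

Times are minutes relative to the onset of germband extension; positions
along the egg are given in percent egg length (%EL) with 0% at the
posterior pole; angular positions along the dorso-ventral circumference are
folded across the midline into [0, 180] degrees (0 = dorsal, 180 = ventral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import SurfaceCarpet

#: a pause exists only if the 3-segment fit improves the residual by >= 10%
PAUSE_RESIDUAL_IMPROVEMENT = 0.10
#: and its slope magnitude stays below min(phase slopes) / 5
PAUSE_SLOPE_RATIO = 5.0


# ---------------------------------------------------------------------------
# region areas on carpets
# ---------------------------------------------------------------------------

def _pole_cap_estimates(carpet: SurfaceCarpet, region: np.ndarray) -> float:
    """Estimated surface area (um^2) of flagged pole caps adjoining ``region``.

    For each z end of the carpet whose outermost usable ring is covered by
    the region, the flagged cap beyond it is approximated as a spherical cap
    ``pi * (a^2 + h^2)`` with base radius ``a`` (mean ring radius) and
    height ``h`` (axial distance from the ring to the data extreme).
    """
    flags = carpet.pole_flags
    n_theta, n_z = carpet.shape
    good_ring = (~flags).sum(axis=0) >= max(1, n_theta // 2)
    if not good_ring.any():
        return 0.0
    z_centers = 0.5 * (carpet.z_edges[:-1] + carpet.z_edges[1:])
    total = 0.0
    for end, extreme in ((int(np.argmax(good_ring)), carpet.z_data_min),
                        (n_z - 1 - int(np.argmax(good_ring[::-1])), carpet.z_data_max)):
        ring_cover = region[:, end].sum()
        if ring_cover < n_theta // 2:
            continue
        a = np.nanmean(carpet.radius_map[:, end])
        h = abs(z_centers[end] - extreme)
        if np.isfinite(a):
            total += np.pi * (a ** 2 + h ** 2)
    return total


def region_area(carpet: SurfaceCarpet, region: np.ndarray,
                include_pole_caps: bool = False) -> float:
    """Corrected surface area (um^2) of a region marked on the carpet.

    Sums the per-pixel area weights over the region.  Regions touching
    flagged pole/furrow pixels raise unless ``include_pole_caps`` is set, in
    which case flagged pixels are excluded from the sum and caps at the
    carpet's z ends covered by the region are added as spherical-cap
    estimates.
    """
    if carpet.area_weight is None or carpet.pole_flags is None:
        raise ValueError("carpet has no area weights; run carpet_area_weights first")
    region = np.asarray(region, dtype=bool)
    if region.shape != carpet.shape:
        raise ValueError("region shape does not match the carpet")
    overlap = int((region & carpet.pole_flags).sum())
    if overlap and not include_pole_caps:
        raise ValueError(
            f"region overlaps {overlap} flagged pole/furrow pixels; pass "
            "include_pole_caps=True to exclude them and estimate the caps")
    usable = region & ~carpet.pole_flags
    if include_pole_caps:
        # columns beyond the outermost usable rings belong to the cap
        # estimate; drop their stray unflagged pixels to avoid double counting
        n_theta, n_z = carpet.shape
        good_ring = (~carpet.pole_flags).sum(axis=0) >= max(1, n_theta // 2)
        if good_ring.any():
            lo = int(np.argmax(good_ring))
            hi = n_z - 1 - int(np.argmax(good_ring[::-1]))
            usable[:, :lo] = False
            usable[:, hi + 1:] = False
    area = float(np.nansum(np.where(usable, carpet.area_weight, 0.0)))
    if include_pole_caps:
        area += _pole_cap_estimates(carpet, region)
    return area


# ---------------------------------------------------------------------------
# spreading phases
# ---------------------------------------------------------------------------

@dataclass
class PhaseSegmentation:
    """Two-breakpoint piecewise-linear fit of an area time series."""

    has_pause: bool
    pause_start: float | None
    pause_end: float | None
    slopes: tuple[float, float, float]  # phase1, pause, phase2 (um^2/min)
    residual: float                     # RSS of the selected model
    residual_single: float              # RSS of the single-line fit

    @property
    def breakpoints(self) -> tuple[float, float] | None:
        if not self.has_pause:
            return None
        return (self.pause_start, self.pause_end)


def _pwl_design(t: np.ndarray, b1: float, b2: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t,
                            np.clip(t - b1, 0.0, None),
                            np.clip(t - b2, 0.0, None)])


def detect_phases(time_min: np.ndarray, area_um2: np.ndarray,
                  min_segment: int = 3) -> PhaseSegmentation:
    """Detect the biphasic spreading pattern with an intervening pause.

    Fits a continuous piecewise-linear model with two breakpoints by
    exhaustive least squares over all breakpoint pairs on the sample grid
    (each segment at least ``min_segment`` samples).  A pause is reported
    only if the 3-segment fit improves the residual by at least 10% over a
    single line and the middle slope magnitude is below a fifth of the
    smaller phase slope.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(area_um2, dtype=float)
    if len(t) < 12:
        raise ValueError("need at least 12 samples to detect phases")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    # single-line fit
    A1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    rss1 = float(((y - A1 @ coef1) ** 2).sum())

    scale = max(abs(y).max(), 1.0)
    if np.ptp(y) <= 1e-12 * scale:
        # exactly constant series: the whole series is a pause
        return PhaseSegmentation(has_pause=True, pause_start=float(t[0]),
                                 pause_end=float(t[-1]),
                                 slopes=(0.0, 0.0, 0.0),
                                 residual=0.0, residual_single=rss1)

    best = None
    n = len(t)
    for i in range(min_segment, n - 2 * min_segment + 1):
        for j in range(i + min_segment, n - min_segment + 1):
            b1, b2 = t[i - 1], t[j - 1]
            A = _pwl_design(t, b1, b2)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((y - A @ coef) ** 2).sum())
            if best is None or rss < best[0]:
                best = (rss, b1, b2, coef)
    rss3, b1, b2, coef = best
    s1 = float(coef[1])
    s2 = float(coef[1] + coef[2])
    s3 = float(coef[1] + coef[2] + coef[3])

    improves = rss3 <= (1.0 - PAUSE_RESIDUAL_IMPROVEMENT) * rss1
    flat_middle = abs(s2) < min(abs(s1), abs(s3)) / PAUSE_SLOPE_RATIO
    if improves and flat_middle:
        return PhaseSegmentation(True, float(b1), float(b2), (s1, s2, s3),
                                 rss3, rss1)
    return PhaseSegmentation(False, None, None,
                             (float(coef1[1]),) * 3, rss1, rss1)


# ---------------------------------------------------------------------------
# ventral closure
# ---------------------------------------------------------------------------

@dataclass
class ClosureSeries:
    """Per-frame serosal-window extents and fitted linear closure rates.

    ``height`` is the AP extent of the open window on the ventral view,
    ``width`` the transverse extent; the rates are positive when the window
    shrinks (um/min).  ``closure_time`` is the first frame time with an
    empty window, or None if the window never closes within the series.
    """

    table: pd.DataFrame
    height_rate: float
    width_rate: float
    closure_time: float | None


def closure_metrics(window_masks: list[np.ndarray], pixel_um: float | tuple,
                    times_min: np.ndarray) -> ClosureSeries:
    """Measure window extents per frame and fit linear closure rates.

    ``window_masks`` are ventral-view binary masks of the open window with
    axis 0 along AP.  Rates come from ordinary least squares on the frames
    with a nonempty window.
    """
    if np.isscalar(pixel_um):
        pix = (float(pixel_um), float(pixel_um))
    else:
        pix = tuple(float(p) for p in pixel_um)
    times = np.asarray(times_min, dtype=float)
    if len(window_masks) != len(times):
        raise ValueError("one mask per time point required")

    heights, widths = [], []
    for m in window_masks:
        m = np.asarray(m, dtype=bool)
        if m.any():
            rows = np.nonzero(m.any(axis=1))[0]
            cols = np.nonzero(m.any(axis=0))[0]
            heights.append((rows[-1] - rows[0] + 1) * pix[0])
            widths.append((cols[-1] - cols[0] + 1) * pix[1])
        else:
            heights.append(0.0)
            widths.append(0.0)
    heights = np.asarray(heights)
    widths = np.asarray(widths)
    open_frames = heights > 0
    if open_frames.sum() < 3:
        raise ValueError("need at least 3 frames with a nonempty window")

    def ols_rate(vals):
        slope = np.polyfit(times[open_frames], vals[open_frames], 1)[0]
        return float(-slope)

    closed = np.nonzero(~open_frames)[0]
    closure_time = float(times[closed[0]]) if len(closed) else None
    table = pd.DataFrame({"time_min": times, "window_height_um": heights,
                          "window_width_um": widths})
    return ClosureSeries(table=table, height_rate=ols_rate(heights),
                         width_rate=ols_rate(widths), closure_time=closure_time)


# ---------------------------------------------------------------------------
# angular positions and germband extension
# ---------------------------------------------------------------------------

def angular_position(theta_bin: int | np.ndarray, carpet: SurfaceCarpet) -> np.ndarray:
    """Fold a carpet theta bin to degrees in [0, 180] across the midline.

    0 deg is the dorsal midline, 180 deg the ventral midline; left and
    right sides fold onto each other.
    """
    centers = 0.5 * (carpet.theta_edges[:-1] + carpet.theta_edges[1:])
    theta_deg = np.degrees(centers[np.asarray(theta_bin)])
    return np.minimum(theta_deg, 360.0 - theta_deg)


def fold_angle_deg(theta_rad: np.ndarray) -> np.ndarray:
    """Fold an angle in radians to [0, 180] degrees across the dorsal midline."""
    deg = np.degrees(np.mod(theta_rad, 2.0 * np.pi))
    return np.minimum(deg, 360.0 - deg)


def germband_extension(landmark_ap_um: np.ndarray, posterior_pole_um: float,
                       anterior_pole_um: float) -> np.ndarray:
    """Germband front position as percent egg length (0% = posterior pole).

    ``landmark_ap_um`` is the AP coordinate of the most anterior point of
    the dorsally extending germband in each frame, in the same axis as the
    two pole coordinates.
    """
    landmark = np.atleast_1d(np.asarray(landmark_ap_um, dtype=float))
    length = anterior_pole_um - posterior_pole_um
    if length == 0:
        raise ValueError("egg length is zero")
    frac = (landmark - posterior_pole_um) / length
    if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
        raise ValueError("landmark lies outside the egg AP extent")
    return 100.0 * np.clip(frac, 0.0, 1.0)


def track_angles(tracks: pd.DataFrame, carpet: SurfaceCarpet) -> pd.DataFrame:
    """Annotate a track table (cell_id, frame/time, theta_bin, z_bin) with the
    folded angular position in degrees."""
    out = tracks.copy()
    out["angle_deg"] = angular_position(out["theta_bin"].to_numpy(), carpet)
    return out
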