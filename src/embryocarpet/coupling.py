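"""Mechanical coupling between a cell layer and its substrate.

Lucas-Kanade optical flow is computed on each channel's 2D time-lapse; the
AP component of the flow is rectified (magnitudes) and averaged per frame
over a region of interest — a band around the cell outline for the
membrane-reporter channel, the filled cell area for the substrate channel.
The two per-frame velocity series are then compared by normalized
cross-correlation evaluated in every sliding 200-s window (per-window mean
removal), the correlation functions averaged across windows, and the
zero-lag value of the average reported as the coupling coefficient.
Randomized (derangement) cell-substrate pairings provide the negative
control, and groups of per-cell coefficients are compared with a two-sided
unpaired t-test plus Hampel outlier flagging and a chi-square normality
check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

#: default Lucas-Kanade integration window (pixels, odd)
LK_WINDOW_PX = 15
#: structure-tensor eigenvalue threshold, as a fraction of max(intensity)^2
LK_EIGEN_FRACTION = 1e-4
#: cross-correlation analysis window in seconds
CROSSCORR_WINDOW_S = 200.0
#: default width of the cell-outline ROI band in pixels
OUTLINE_BAND_PX = 3


@dataclass
class FlowField:
    """Dense displacement field between two frames.

    ``u``/``v`` are the x/y displacement components in um per frame;
    ``valid`` marks pixels with enough local texture for a reliable
    estimate (smaller structure-tensor eigenvalue above threshold).
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    pixel_size_um: float = 1.0
    frame_pair: tuple[int, int] | None = None


def lucas_kanade_flow(frame_a: np.ndarray, frame_b: np.ndarray,
                      window_px: int = LK_WINDOW_PX,
                      pixel_size_um: float = 1.0,
                      eigen_fraction: float = LK_EIGEN_FRACTION,
                      n_iter: int = 3) -> FlowField:
    """Dense Lucas-Kanade optical flow from ``frame_a`` to ``frame_b``.

    Solves the windowed least-squares normal equations per pixel and
    refines by warping ``frame_a`` with the current estimate (coarse
    displacements converge in a few iterations).  Pixels whose structure
    tensor's smaller eigenvalue falls below ``eigen_fraction * max(I)^2``
    are marked invalid.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2D")
    if window_px < 5 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 5")

    yy, xx = np.mgrid[: a.shape[0], : a.shape[1]].astype(float)
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    win = window_px
    eig_thresh = eigen_fraction * max(a.max(), b.max(), 1e-30) ** 2
    lam_min_first = None

    for _ in range(max(1, n_iter)):
        warped = ndimage.map_coordinates(a, [yy - v, xx - u], order=1,
                                         mode="nearest")
        # averaging both frames' gradients symmetrizes the estimator
        avg = 0.5 * (warped + b)
        ix = ndimage.sobel(avg, axis=1) / 8.0
        iy = ndimage.sobel(avg, axis=0) / 8.0
        it = b - warped

        sxx = ndimage.uniform_filter(ix * ix, win)
        syy = ndimage.uniform_filter(iy * iy, win)
        sxy = ndimage.uniform_filter(ix * iy, win)
        sxt = ndimage.uniform_filter(ix * it, win)
        syt = ndimage.uniform_filter(iy * it, win)

        trace = sxx + syy
        diff = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy ** 2)
        lam_min = 0.5 * (trace - diff)
        if lam_min_first is None:
            lam_min_first = lam_min
        det = sxx * syy - sxy ** 2
        ok = (np.abs(det) > 1e-30) & (lam_min > 0)
        # G d = -[sxt, syt]
        du = np.where(ok, -(syy * sxt - sxy * syt) / np.where(ok, det, 1.0), 0.0)
        dv = np.where(ok, -(sxx * syt - sxy * sxt) / np.where(ok, det, 1.0), 0.0)
        u = u + du
        v = v + dv

    valid = lam_min_first > eig_thresh
    return FlowField(u=u * pixel_size_um, v=v * pixel_size_um, valid=valid,
                     pixel_size_um=pixel_size_um)


def flow_series(frames: np.ndarray, **kwargs) -> list[FlowField]:
    """Lucas-Kanade flow for every consecutive frame pair of a movie."""
    frames = np.asarray(frames)
    fields = []
    for t in range(len(frames) - 1):
        f = lucas_kanade_flow(frames[t], frames[t + 1], **kwargs)
        f.frame_pair = (t, t + 1)
        fields.append(f)
    return fields


@dataclass
class VelocitySeries:
    """Per-frame mean AP-velocity magnitudes (um/frame) in a ROI."""

    time_s: np.ndarray
    value: np.ndarray
    roi_kind: str = "cell_area"
    channel: str = ""


def outline_band(outline_or_area: np.ndarray, band_px: int = OUTLINE_BAND_PX
                 ) -> np.ndarray:
    """Band of ``band_px`` total width around a region's outline."""
    m = np.asarray(outline_or_area, dtype=bool)
    r = band_px / 2.0
    d_in = ndimage.distance_transform_edt(m)
    d_out = ndimage.distance_transform_edt(~m)
    return (d_in <= r) & m | (d_out <= r) & ~m


def roi_velocity_series(flows: list[FlowField], roi: np.ndarray, ap_direction,
                        frame_interval_s: float = 20.0,
                        roi_kind: str = "cell_area",
                        channel: str = "") -> VelocitySeries:
    """Mean magnitude of the AP flow component over a ROI, per frame pair.

    Only pixels valid in the flow field contribute; an empty ROI or a ROI
    with no valid pixels in some frame is an error.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    ap = np.asarray(ap_direction, dtype=float)
    ap = ap / np.linalg.norm(ap)
    values = []
    for f in flows:
        if roi.shape != f.u.shape:
            raise ValueError("ROI shape does not match the flow field")
        sel = roi & f.valid
        if not sel.any():
            raise ValueError("ROI contains no valid flow pixels")
        comp = f.u[sel] * ap[0] + f.v[sel] * ap[1]
        values.append(float(np.abs(comp).mean()))
    return VelocitySeries(time_s=np.arange(len(values)) * frame_interval_s,
                          value=np.asarray(values), roi_kind=roi_kind,
                          channel=channel)


@dataclass
class CouplingResult:
    """Window-averaged normalized cross-correlation of two velocity series."""

    lags: np.ndarray          # lag in frames, symmetric around 0
    function: np.ndarray      # averaged correlation function over lags
    coefficient: float        # summary scalar (zero-lag by default)
    window_spans: list[tuple[float, float]]
    n_windows: int
    cell_id: str | int | None = None


def _series_values(s) -> np.ndarray:
    return np.asarray(s.value if isinstance(s, VelocitySeries) else s, dtype=float)


def windowed_crosscorr(cell, substrate, window_s: float = CROSSCORR_WINDOW_S,
                       frame_interval_s: float = 20.0,
                       reduction: str = "zero_lag",
                       cell_id=None) -> CouplingResult:
    """Normalized cross-correlation averaged over all sliding windows.

    Every full ``window_s`` window (stride one frame) is mean-removed and
    its normalized cross-correlation function computed over all lags; the
    functions are averaged across windows.  ``reduction`` picks the summary
    coefficient: the zero-lag value (default) or the lag with maximal
    absolute correlation (``"peak"``).
    """
    a = _series_values(cell)
    b = _series_values(substrate)
    if len(a) != len(b):
        raise ValueError("series lengths differ")
    L = int(round(window_s / frame_interval_s))
    if len(a) < L:
        raise ValueError(f"series shorter than one {window_s:.0f}-s window "
                         f"({L} samples)")
    lags = np.arange(-(L - 1), L)
    funcs = []
    spans = []
    for start in range(0, len(a) - L + 1):
        wa = a[start: start + L] - a[start: start + L].mean()
        wb = b[start: start + L] - b[start: start + L].mean()
        denom = np.sqrt((wa ** 2).sum() * (wb ** 2).sum())
        if denom == 0:
            warnings.warn(f"zero-variance window at sample {start}; skipped",
                          stacklevel=2)
            continue
        # c(k) = sum_t wa(t) * wb(t + k) / denom
        cc = np.correlate(wb, wa, mode="full") / denom
        funcs.append(cc)
        spans.append((start * frame_interval_s, (start + L - 1) * frame_interval_s))
    if not funcs:
        raise ValueError("all windows had zero variance")
    func = np.mean(funcs, axis=0)
    if reduction == "zero_lag":
        coeff = float(func[L - 1])
    elif reduction == "peak":
        coeff = float(func[np.argmax(np.abs(func))])
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return CouplingResult(lags=lags, function=func, coefficient=coeff,
                          window_spans=spans, n_windows=len(funcs),
                          cell_id=cell_id)


def randomized_control(cells: list, substrates: list, seed: int,
                       **kwargs) -> list[CouplingResult]:
    """Coupling coefficients under a derangement cell-substrate pairing.

    Every cell is paired with a substrate that is not its own (negative
    control); the derangement is drawn reproducibly from ``seed``.
    """
    if len(cells) != len(substrates):
        raise ValueError("need one substrate per cell")
    n = len(cells)
    if n < 2:
        raise ValueError("no derangement exists for fewer than 2 cells")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    return [windowed_crosscorr(cells[i], substrates[perm[i]],
                               cell_id=f"{i}x{perm[i]}", **kwargs)
            for i in range(n)]


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def hampel_outliers(values: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Flag values deviating from the median by more than ``n_mad`` scaled MADs."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > n_mad * mad


def chi2_normality(values: np.ndarray, n_bins: int | None = None
                   ) -> tuple[float, float]:
    """Pearson chi-square goodness-of-fit of a fitted normal distribution.

    Observations are binned into equiprobable bins of the fitted normal
    (df = bins - 3, parameters estimated from the data).  Returns
    ``(statistic, p_value)``; with too few observations for any df the
    p-value is NaN.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n_bins is None:
        n_bins = max(4, min(8, n // 3))
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return float("inf"), 0.0
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 3
    p = float(stats.chi2.sf(statistic, df)) if df >= 1 else float("nan")
    return statistic, p


@dataclass
class GroupComparison:
    """Two-sided unpaired t comparison of two coefficient groups."""

    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    outliers_a: np.ndarray
    outliers_b: np.ndarray
    normality_p_a: float
    normality_p_b: float


def compare_groups(coeffs_a, coeffs_b) -> GroupComparison:
    """Compare two groups of coupling coefficients.

    Reports Hampel outlier flags (not removed), a chi-square normality
    check per group, and the two-sided unpaired Student's t-test.
    """
    a = np.asarray([c.coefficient if isinstance(c, CouplingResult) else c
                    for c in coeffs_a], dtype=float)
    b = np.asarray([c.coefficient if isinstance(c, CouplingResult) else c
                    for c in coeffs_b], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    _, pna = chi2_normality(a)
    _, pnb = chi2_normality(b)
    return GroupComparison(
        t_statistic=float(t_stat), p_value=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
        outliers_a=hampel_outliers(a), outliers_b=hampel_outliers(b),
        normality_p_a=pna, normality_p_b=pnb,
    )
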