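"""Single-cell time-lapse analysis: ROI detection, phase coherence, CoM waves.

Operates on bioluminescence image stacks (frames x height x width) acquired
at 1-2 frames per hour.  Cells are segmented from the temporal variability
of the signal, per-cell traces feed the :mod:`rhythmkit.rhythm` estimators
unchanged, phase synchrony across cells is summarised by the Rayleigh vector
length, and the circuit-level spatiotemporal wave is described by the
intensity-weighted centre of mass (CoM) and its mean cycle path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .rhythm import Trace

__all__ = [
    "ROI", "ImagingSession", "RayleighResult", "CoMPath",
    "detect_rois", "extract_traces", "rayleigh", "com_series",
    "com_path_metrics", "roi_phases",
]


@dataclass
class ROI:
    id: int
    mask: np.ndarray            # boolean (height, width)
    centroid_px: tuple[float, float]   # (x, y)


@dataclass
class ImagingSession:
    """An image stack with whatever derived objects have been computed."""

    stack: np.ndarray           # (frames, height, width)
    frame_interval_h: float
    rois: list[ROI] | None = None
    traces: list[Trace] | None = None
    com: np.ndarray | None = None      # (frames, 2) as (x, y)

    def __post_init__(self) -> None:
        if self.stack.ndim != 3:
            raise ValueError("stack must be (frames, height, width)")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")


@dataclass
class RayleighResult:
    """Circular summary of per-cell phases.

    ``R`` is the mean resultant length of the unit phase vectors: 1 for
    perfect synchrony, near 0 for dispersed phases.  The p-value is the
    Rayleigh uniformity test (series approximation); it is flagged
    approximate for n < 50.
    """

    mean_phase_rad: float
    R: float
    n: int
    p_value: float
    approximate: bool = False


@dataclass
class CoMPath:
    positions: np.ndarray       # (frames, 2)
    mean_cycle_path: np.ndarray  # (n_bins, 2)
    perimeter_px: float
    direction_deg: float


# ---------------------------------------------------------------------------
# segmentation and traces


def _despeckle(stack: np.ndarray) -> np.ndarray:
    """Per-frame 3x3 median filter."""
    return ndimage.median_filter(stack.astype(float), size=(1, 3, 3))


def detect_rois(
    stack: np.ndarray,
    frame_interval_h: float = 1.0,
    k_sd: float = 1.5,
    min_px: int = 4,
    max_px: int = 400,
) -> list[ROI]:
    """Segment oscillating cells from a time-lapse stack.

    Pipeline: per-frame 3x3 median despeckle, temporal-minimum background
    subtraction, then thresholding of the temporal standard-deviation
    projection at ``mean + k_sd * SD`` of that projection.  Connected
    components with areas in ``[min_px, max_px]`` become ROIs — the area
    ceiling removes large static bright regions that are not single cells.
    """
    if stack.shape[0] * frame_interval_h < 24:
        raise ValueError("need at least 24 h of frames to segment oscillators")
    clean = _despeckle(stack)
    clean = clean - clean.min(axis=0, keepdims=True)
    sd = clean.std(axis=0)
    thr = sd.mean() + k_sd * sd.std()
    binary = sd > thr
    labels = measure.label(binary, connectivity=2)
    rois: list[ROI] = []
    for region in measure.regionprops(labels):
        if not (min_px <= region.area <= max_px):
            continue
        mask = labels == region.label
        cy, cx = region.centroid
        rois.append(ROI(id=len(rois), mask=mask, centroid_px=(float(cx), float(cy))))
    if not rois:
        warnings.warn("no ROIs detected", stacklevel=2)
    return rois


def extract_traces(
    stack: np.ndarray, rois: list[ROI], frame_interval_h: float = 1.0,
    treatment_time_h: float | None = None,
) -> list[Trace]:
    """Mean intensity over each ROI mask per frame, as rhythm-ready traces."""
    t = np.arange(stack.shape[0]) * frame_interval_h
    out = []
    for roi in rois:
        y = stack[:, roi.mask].mean(axis=1)
        out.append(Trace(t, y.astype(float), frame_interval_h,
                         treatment_time_h, label=f"roi{roi.id}"))
    return out


def roi_phases(
    traces: list[Trace],
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-ROI phase (h) and period (h) from damped-cosine fits.

    The phase statistic is the time of the first fitted peak inside the
    analysis window, modulo the fitted period.  Arrhythmic ROIs are dropped;
    the returned index list maps rows back to the input traces.
    """
    from .rhythm import fit_fftnlls

    phases, periods, kept = [], [], []
    for i, tr in enumerate(traces):
        fit = fit_fftnlls(tr, window)
        if fit.arrhythmic:
            continue
        phases.append(fit.phase_peak_h % fit.period_h)
        periods.append(fit.period_h)
        kept.append(i)
    return np.asarray(phases), np.asarray(periods), kept


# ---------------------------------------------------------------------------
# circular statistics


def rayleigh(phases_h: np.ndarray, period_h: float) -> RayleighResult:
    """Rayleigh vector of phases expressed in hours of a cycle.

    Phases are mapped to angles ``2 pi phase / period``; R is the length of
    the mean unit vector and the p-value follows the standard series
    approximation of the Rayleigh uniformity test.
    """
    phases_h = np.asarray(phases_h, dtype=float)
    n = len(phases_h)
    if n < 2:
        raise ValueError("need at least two phases")
    theta = 2 * np.pi * phases_h / period_h
    C, S = np.cos(theta).sum(), np.sin(theta).sum()
    R = float(np.hypot(C, S) / n)
    z = n * R ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4)
                      / (288 * n ** 2))
    return RayleighResult(mean_phase_rad=float(np.arctan2(S, C)),
                          R=R, n=n, p_value=float(np.clip(p, 0.0, 1.0)),
                          approximate=n < 50)


# ---------------------------------------------------------------------------
# centre of mass


def com_series(
    stack: np.ndarray,
    threshold_percentile: float = 20.0,
    min_total_fraction: float = 0.05,
) -> np.ndarray:
    """Per-frame intensity-weighted centre of mass of supra-threshold pixels.

    Frames are despeckled (3x3 median), background subtracted (temporal
    minimum projection) and normalised to their own maximum; the threshold
    is the given percentile of each frame's nonzero pixels.  Returns an
    (n_frames, 2) array of (x, y) positions.  Frames with no supra-threshold
    signal, or whose total intensity is below ``min_total_fraction`` of the
    brightest frame's total (circadian troughs, where a centre of mass would
    only track noise), yield NaN.

    Background here is the per-frame spatial minimum (a flat dark-current
    offset), not the temporal minimum used for segmentation: the centre of
    mass must still see static structures.
    """
    clean = _despeckle(stack)
    clean = clean - clean.min(axis=(1, 2), keepdims=True)
    n_frames, h, w = clean.shape
    yy, xx = np.mgrid[0:h, 0:w]
    totals = clean.sum(axis=(1, 2))
    floor = min_total_fraction * totals.max()
    out = np.full((n_frames, 2), np.nan)
    for i in range(n_frames):
        frame = clean[i]
        fmax = frame.max()
        if fmax <= 0 or totals[i] < floor:
            continue
        frame = frame / fmax
        nz = frame[frame > 0]
        thr = np.percentile(nz, threshold_percentile)
        sel = frame >= thr
        weights = frame[sel]
        total = weights.sum()
        if total <= 0:
            continue
        out[i, 0] = (weights * xx[sel]).sum() / total
        out[i, 1] = (weights * yy[sel]).sum() / total
    return out


def com_path_metrics(
    positions: np.ndarray,
    period_h: float,
    frame_interval_h: float = 1.0,
    n_days: int = 5,
    n_bins: int = 24,
    start_h: float = 0.0,
) -> CoMPath:
    """Mean cycle path of the CoM and its perimeter/direction.

    Frames within ``n_days`` circadian cycles from ``start_h`` are folded by
    circadian phase into ``n_bins`` bins; bin-mean positions ordered by phase
    form the mean cycle path.  The perimeter closes the loop; the direction
    is the orientation of the first principal axis of the mean path.
    """
    positions = np.asarray(positions, dtype=float)
    t = np.arange(len(positions)) * frame_interval_h
    sel = (t >= start_h) & (t < start_h + n_days * period_h)
    t, pos = t[sel], positions[sel]
    ok = ~np.isnan(pos).any(axis=1)
    t, pos = t[ok], pos[ok]
    if len(pos) < n_bins:
        n_bins = max(2, len(pos))
    phase_bin = ((t % period_h) / period_h * n_bins).astype(int) % n_bins
    mean_path = np.full((n_bins, 2), np.nan)
    for b in range(n_bins):
        if (phase_bin == b).any():
            mean_path[b] = pos[phase_bin == b].mean(axis=0)
    mean_path = mean_path[~np.isnan(mean_path).any(axis=1)]
    if len(mean_path) < 2:
        return CoMPath(positions, mean_path, 0.0, np.nan)
    closed = np.vstack([mean_path, mean_path[:1]])
    perimeter = float(np.sqrt(np.sum(np.diff(closed, axis=0) ** 2, axis=1)).sum())
    centered = mean_path - mean_path.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = float(np.rad2deg(np.arctan2(vt[0, 1], vt[0, 0])) % 180.0)
    return CoMPath(positions=positions, mean_cycle_path=mean_path,
                   perimeter_px=perimeter, direction_deg=direction)
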