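"""Wheel-running actogram analysis.

Works on activity counts in short (default 6-min) bins with a lighting
schedule annotation: Sokolove-Bushell chi-squared periodogram, per-day
activity onsets/offsets, phase angle of entrainment, activity duration
(alpha), sigmoidal 50%-phase-shift (PS50) fits for jet-lag re-entrainment,
and Aschoff Type II light-pulse phase shifts by onset-regression
extrapolation.

Onset/offset thresholds mimic common actogram-software defaults and are all
configurable.  Days are calendar days; free-running drift across days is
handled by unwrapping onset times rather than by re-slicing into circadian
days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .rhythm import EstimationError

__all__ = [
    "ActivityRecord", "LightSegment", "PeriodogramResult", "PS50Fit",
    "chi_sq_periodogram", "detect_onsets_offsets", "phase_angle", "alpha",
    "ps50", "light_pulse_shift", "unwrap_onsets",
]


@dataclass
class LightSegment:
    mode: str                  # "LD", "DD" or "light_pulse"
    start_day: int
    end_day: int               # exclusive
    lights_on_h: Optional[float] = None
    lights_off_h: Optional[float] = None


@dataclass
class ActivityRecord:
    """Binned activity counts plus the lighting schedule."""

    counts: np.ndarray
    bin_min: int = 6
    schedule: list[LightSegment] | None = None
    start_time_h: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        if (24 * 60) % self.bin_min != 0:
            raise ValueError("bin_min must divide 24 h evenly")

    @property
    def bin_h(self) -> float:
        return self.bin_min / 60.0

    @property
    def bins_per_day(self) -> int:
        return int(round(24 / self.bin_h))

    @property
    def n_days(self) -> int:
        return len(self.counts) // self.bins_per_day


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    significance_line: np.ndarray
    best_period_h: float | None    # None when nothing clears the line


@dataclass
class PS50Fit:
    asymptotes: tuple[float, float]
    midpoint_day: float
    slope: float
    rss: float


# ---------------------------------------------------------------------------
# periodogram


def chi_sq_periodogram(
    record: ActivityRecord,
    band: tuple[float, float] = (20.0, 28.0),
    step_h: float = 0.1,
    alpha_level: float = 0.001,
) -> PeriodogramResult:
    """Sokolove-Bushell chi-squared periodogram.

    For each trial period of K bins the statistic is the between-column
    variance of the folded data scaled so that, under the null of no
    periodicity, Qp ~ chi-square with K - 1 degrees of freedom:

        Qp = (N / K) * sum_h (M_h - M)^2 / (sum_i (x_i - M)^2 / N)

    where M_h are the K column means of the data folded modulo K and M is
    the grand mean.  The significance line is the chi-square 1 - alpha
    quantile at K - 1 df; the best period is the Qp argmax above the line.
    """
    x = record.counts
    N = len(x)
    bin_h = record.bin_h
    if N * bin_h < 2 * band[1]:
        raise ValueError("record must span at least twice the longest trial period")
    M = x.mean()
    denom = np.sum((x - M) ** 2) / N
    if denom == 0:
        raise ValueError("constant record has no periodicity to test")

    ks = np.unique(np.round(np.arange(band[0], band[1] + 1e-9, step_h) / bin_h
                            ).astype(int))
    ks = ks[ks >= 2]
    periods = ks * bin_h
    qp = np.empty(len(ks))
    sig = np.empty(len(ks))
    idx = np.arange(N)
    for j, K in enumerate(ks):
        cols = idx % K
        sums = np.bincount(cols, weights=x, minlength=K)
        cnts = np.bincount(cols, minlength=K)
        Mh = sums / cnts
        qp[j] = (N / K) * np.sum((Mh - M) ** 2) / denom
        sig[j] = stats.chi2.ppf(1 - alpha_level, K - 1)
    above = qp > sig
    best = float(periods[np.argmax(qp - sig)]) if above.any() else None
    if best is not None and not above[np.argmax(qp - sig)]:  # pragma: no cover
        best = None
    return PeriodogramResult(periods_h=periods, qp=qp,
                             significance_line=sig, best_period_h=best)


# ---------------------------------------------------------------------------
# onsets / offsets


def detect_onsets_offsets(
    record: ActivityRecord,
    onset_threshold: float = 0.2,
    confirm_h: float = 3.0,
    confirm_fraction: float = 0.5,
    quiet_h: float = 4.0,
    quiet_fraction: float = 0.2,
    smooth_h: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day activity onset and offset, as clock hours; NaN when missing.

    An onset is the first active bin of the day (count above
    ``onset_threshold`` of that day's ``smooth_h``-smoothed peak) that is
    preceded by a quiet interval (at most ``quiet_fraction`` of the previous
    ``quiet_h`` hours active, looking across the day boundary) and confirmed
    by at least ``confirm_fraction`` of the following ``confirm_h`` hours
    being active.  The offset is the symmetric criterion running backwards.
    Days with no supra-threshold activity are flagged missing, not
    interpolated.
    """
    bpd = record.bins_per_day
    bin_h = record.bin_h
    w = max(1, int(round(smooth_h / bin_h)))
    cw = max(1, int(round(confirm_h / bin_h)))
    qw = max(1, int(round(quiet_h / bin_h)))
    x = record.counts
    n = len(x)
    kernel = np.ones(w) / w
    smoothed = np.convolve(x, kernel, mode="same")

    # per-day activity threshold, applied to the continuous record
    active = np.zeros(n, dtype=bool)
    day_thr = np.full(record.n_days, np.nan)
    for d in range(record.n_days):
        sl = slice(d * bpd, (d + 1) * bpd)
        peak = smoothed[sl].max()
        if peak > 0:
            day_thr[d] = onset_threshold * peak
            active[sl] = x[sl] > day_thr[d]

    onsets = np.full(record.n_days, np.nan)
    offsets = np.full(record.n_days, np.nan)
    for d in range(record.n_days):
        if np.isnan(day_thr[d]):
            continue
        lo, hi = d * bpd, (d + 1) * bpd
        # the quiet interval must be at least half observable, so bouts
        # truncated by the record edges are not misread as onsets/offsets
        for g in np.flatnonzero(active[lo:hi]) + lo:
            confirm = active[g:min(n, g + cw)]
            quiet = active[max(0, g - qw):g]
            if (confirm.size and confirm.mean() >= confirm_fraction
                    and quiet.size >= qw // 2
                    and quiet.mean() <= quiet_fraction):
                onsets[d] = (g - lo) * bin_h
                break
        for g in (np.flatnonzero(active[lo:hi]) + lo)[::-1]:
            confirm = active[max(0, g - cw + 1):g + 1]
            quiet = active[g + 1:min(n, g + 1 + qw)]
            if (confirm.size and confirm.mean() >= confirm_fraction
                    and quiet.size >= qw // 2
                    and quiet.mean() <= quiet_fraction):
                offsets[d] = (g + 1 - lo) * bin_h
                break
    return onsets, offsets


def unwrap_onsets(onsets: np.ndarray) -> np.ndarray:
    """Remove 24 h jumps from a per-day clock-hour marker series.

    Free-running markers that drift across midnight wrap by +-24 h; this
    restores continuity by shifting each day's value by the multiple of 24
    closest to its predecessor.
    """
    out = np.asarray(onsets, dtype=float).copy()
    last = np.nan
    for i, v in enumerate(out):
        if np.isnan(v):
            continue
        if not np.isnan(last):
            out[i] = v - 24.0 * np.round((v - last) / 24.0)
        last = out[i]
    return out


def phase_angle(
    record: ActivityRecord,
    onsets: np.ndarray,
    days: np.ndarray | None = None,
) -> float:
    """Mean phase angle of entrainment in minutes.

    Defined as lights-off minus activity onset over entrained (LD) days;
    positive when onset precedes lights-off, negative when activity starts
    after lights-off.
    """
    if record.schedule is None:
        raise EstimationError("record has no lighting schedule")
    angles = []
    for seg in record.schedule:
        if seg.mode != "LD" or seg.lights_off_h is None:
            continue
        for d in range(seg.start_day, min(seg.end_day, len(onsets))):
            if days is not None and d not in days:
                continue
            o = onsets[d]
            if np.isnan(o):
                continue
            diff = seg.lights_off_h - o
            diff -= 24.0 * np.round(diff / 24.0)
            angles.append(diff * 60.0)
    if not angles:
        raise EstimationError("no entrained days with detected onsets")
    return float(np.mean(angles))


def alpha(onsets: np.ndarray, offsets: np.ndarray) -> float:
    """Mean daily activity duration (onset to offset) in hours, modulo 24."""
    onsets = np.asarray(onsets, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    ok = ~np.isnan(onsets) & ~np.isnan(offsets)
    if not ok.any():
        raise EstimationError("no days with both onset and offset")
    dur = (offsets[ok] - onsets[ok]) % 24.0
    return float(np.mean(dur))


# ---------------------------------------------------------------------------
# re-entrainment


def ps50(
    marker_h: np.ndarray,
    days: np.ndarray | None = None,
) -> PS50Fit:
    """Four-parameter logistic fit of re-entrainment markers vs day.

    ``marker_h`` are per-day onset (phase advance) or offset (phase delay)
    clock hours, unwrapped; ``days`` default to 1..n.  The PS50 is the day
    at which the curve crosses midway between its asymptotes, which is the
    fitted midpoint.
    """
    y = np.asarray(marker_h, dtype=float)
    if days is None:
        days = np.arange(1, len(y) + 1, dtype=float)
    days = np.asarray(days, dtype=float)
    ok = ~np.isnan(y)
    days, y = days[ok], y[ok]
    if len(y) < 5:
        raise EstimationError("need at least 5 marker days for a sigmoid fit")

    def model(d, lower, upper, mid, slope):
        return lower + (upper - lower) / (1.0 + np.exp(-slope * (d - mid)))

    lo0 = float(np.median(y[: max(2, len(y) // 4)]))
    hi0 = float(np.median(y[-max(2, len(y) // 4):]))
    p0 = [lo0, hi0, float(np.median(days)), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            model, days, y, p0=p0,
            bounds=([-np.inf, -np.inf, days.min() - 1, 0.05],
                    [np.inf, np.inf, days.max() + 1, 50.0]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise EstimationError(f"sigmoid fit did not converge: {exc}") from exc
    resid = y - model(days, *popt)
    return PS50Fit(asymptotes=(float(popt[0]), float(popt[1])),
                   midpoint_day=float(popt[2]), slope=float(popt[3]),
                   rss=float(np.sum(resid ** 2)))


def light_pulse_shift(
    record: ActivityRecord,
    pulse_day: int,
    onsets: np.ndarray | None = None,
    n_fit: int = 5,
    transient_days: int = 2,
) -> float:
    """Aschoff Type II phase shift from a single light pulse, in hours.

    Regression lines are fitted to at least ``n_fit`` onsets before the
    pulse and to stable onsets after it (excluding ``transient_days``
    transient cycles); the shift is the difference of the two extrapolations
    at the pulse day, with delays negative.  Because both sides are
    regressions, free-running drift (tau != 24) cancels out of the estimate.
    """
    if onsets is None:
        onsets, _ = detect_onsets_offsets(record)
    onsets = unwrap_onsets(onsets)
    days = np.arange(len(onsets), dtype=float)
    pre = ~np.isnan(onsets) & (days < pulse_day)
    post = ~np.isnan(onsets) & (days >= pulse_day + 1 + transient_days)
    if pre.sum() < n_fit:
        raise EstimationError(f"need >= {n_fit} pre-pulse onsets, found {int(pre.sum())}")
    if post.sum() < n_fit:
        raise EstimationError(f"need >= {n_fit} post-pulse onsets, found {int(post.sum())}")
    pre_fit = stats.linregress(days[pre], onsets[pre])
    post_fit = stats.linregress(days[post], onsets[post])
    at = float(pulse_day)
    pre_ext = pre_fit.intercept + pre_fit.slope * at
    post_ext = post_fit.intercept + post_fit.slope * at
    return float(pre_ext - post_ext)
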