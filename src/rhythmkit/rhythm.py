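"""Ensemble bioluminescence rhythm metrics.

Quantifies circadian properties of photomultiplier-tube recordings from
organotypic SCN slices expressing luciferase clock reporters (PER2::LUC and
similar): damped-cosine (FFT-initialised nonlinear least squares) fits for
period / amplitude / relative amplitude error, peak-extrapolation phase
shifts, growth-extrapolated acute fold induction, and RMS-based amplitude
analogues for arrhythmic (e.g. Cry-null) tissue.

Sign conventions
----------------
Phase delays are negative, advances positive.  A "delay" means observed
post-treatment peaks occur *later* than the peaks predicted by extrapolating
the pre-treatment rhythm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "Trace",
    "RhythmFit",
    "TreatmentResponse",
    "EstimationError",
    "detrend_rolling",
    "fit_fftnlls",
    "detect_peaks",
    "phase_shift",
    "fold_induction",
    "acute_induction_arrhythmic",
    "rms_change",
    "amplitude_change",
    "period_change",
    "correlate_responses",
    "analyze_treatment",
]

#: circadian search band for spectral initialisation, hours
CIRCADIAN_BAND = (16.0, 32.0)


class EstimationError(RuntimeError):
    """An estimator's preconditions were not met (e.g. too few peaks)."""


@dataclass
class Trace:
    """A uniformly sampled luminescence (or calcium) time series.

    Parameters
    ----------
    t : array of sample times in hours, strictly increasing, uniform grid.
    y : signal in counts per second (cps) or equivalent.
    treatment_time_h : time of bath treatment, if any.
    """

    t: np.ndarray
    y: np.ndarray
    dt_h: float | None = None
    treatment_time_h: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError("t must be strictly increasing")
        if np.ptp(steps) > 1e-6:
            raise ValueError("t must be uniformly spaced (within 1e-6 h)")
        if self.dt_h is None:
            self.dt_h = float(steps[0])
        elif abs(self.dt_h - steps[0]) > 1e-6:
            raise ValueError("dt_h inconsistent with t grid")

    @property
    def duration_h(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, start_h: float, end_h: float) -> "Trace":
        """Sub-trace on [start_h, end_h)."""
        mask = (self.t >= start_h) & (self.t < end_h)
        if mask.sum() < 2:
            raise ValueError(f"window [{start_h}, {end_h}) contains <2 samples")
        return Trace(self.t[mask], self.y[mask], self.dt_h,
                     self.treatment_time_h, self.label)

    def replace(self, **kw) -> "Trace":
        return dataclasses.replace(self, **kw)


@dataclass
class RhythmFit:
    """Damped-cosine fit of one trace window.

    ``amplitude`` is the envelope value at the window start; use
    :meth:`amplitude_at` to reference it to another time.  ``rae`` is the
    relative amplitude error: half-width of the 95% amplitude confidence
    interval divided by the amplitude, clipped to [0, 1] (0 = perfectly
    determined rhythm, 1 = arrhythmic).
    """

    period_h: float
    amplitude: float
    phase_peak_h: float
    damping_rate: float
    rae: float
    window: tuple[float, float]
    residual_sd: float
    arrhythmic: bool = False

    def amplitude_at(self, time_h: float) -> float:
        """Envelope amplitude extrapolated to ``time_h`` via the fitted damping."""
        return float(self.amplitude * np.exp(-self.damping_rate * (time_h - self.window[0])))

    def peak_times(self, until_h: float) -> np.ndarray:
        """Fitted peak times from the window start up to ``until_h``."""
        first = self.phase_peak_h
        n = max(0, int(np.floor((until_h - first) / self.period_h)) + 1)
        return first + self.period_h * np.arange(n)


@dataclass
class TreatmentResponse:
    """Per-slice response summary to a single bath treatment."""

    phase_shift_h: float | None
    fold_induction: float | None
    d_period_h: float | None
    amplitude_change_pct: float | None
    rms_change_pct: float | None
    pre_fit: RhythmFit | None = None
    post_fit: RhythmFit | None = None

    def to_dict(self) -> dict:
        d = {
            "phase_shift_h": self.phase_shift_h,
            "fold_induction": self.fold_induction,
            "d_period_h": self.d_period_h,
            "amplitude_change_pct": self.amplitude_change_pct,
            "rms_change_pct": self.rms_change_pct,
        }
        for name, fit in (("pre_fit", self.pre_fit), ("post_fit", self.post_fit)):
            if fit is not None:
                d[name] = {
                    "period_h": fit.period_h, "amplitude": fit.amplitude,
                    "phase_peak_h": fit.phase_peak_h, "damping_rate": fit.damping_rate,
                    "rae": fit.rae, "window": list(fit.window),
                    "residual_sd": fit.residual_sd, "arrhythmic": fit.arrhythmic,
                }
        return d


# ---------------------------------------------------------------------------
# detrending and peak detection


def detrend_rolling(trace: Trace, window_h: float = 24.0) -> Trace:
    """Subtract a centred moving-average baseline of width ``window_h``.

    Edges use the mean of the available partial window, so the output has the
    same length as the input.
    """
    nbins = int(round(window_h / trace.dt_h))
    if nbins < 1 or nbins > len(trace.t):
        raise ValueError(
            f"baseline window {window_h} h does not fit trace of "
            f"{trace.duration_h:.1f} h at dt={trace.dt_h} h")
    baseline = (pd.Series(trace.y)
                .rolling(nbins, center=True, min_periods=1)
                .mean().to_numpy())
    return trace.replace(y=trace.y - baseline)


def _smooth(y: np.ndarray, nbins: int) -> np.ndarray:
    if nbins <= 1:
        return y
    return (pd.Series(y).rolling(nbins, center=True, min_periods=1)
            .mean().to_numpy())


def detect_peaks(
    trace: Trace,
    min_separation_h: float = 16.0,
    smooth_h: float = 2.0,
    detrend_window_h: float = 24.0,
    prominence_frac: float = 0.02,
    refine_h: float = 4.0,
    value_refine_h: float = 1.5,
) -> list[tuple[float, float]]:
    """Circadian peaks of a trace as ``(peak_time_h, raw_peak_value)`` pairs.

    Candidate peaks are local maxima of the detrended, lightly smoothed
    signal separated by at least ``min_separation_h``.  Each peak time is
    then refined by a least-squares parabola over ``+-refine_h`` of the
    detrended signal around the candidate (quadratic interpolation of the
    three surrounding bins when the parabola degenerates).  The peak value
    is read from the raw trace via a narrower local parabola
    (``+-value_refine_h``), which suppresses single-bin noise without
    flattening sharp peaks.
    """
    det = detrend_rolling(trace, detrend_window_h)
    ys = _smooth(det.y, int(round(smooth_h / trace.dt_h)))
    span = float(np.ptp(ys))
    if span == 0.0:
        return []
    idx, _ = signal.find_peaks(
        ys,
        distance=max(1, int(round(min_separation_h / trace.dt_h))),
        prominence=prominence_frac * span,
        height=prominence_frac * span,  # a real peak rises above the baseline
    )
    nref = max(2, int(round(refine_h / trace.dt_h)))
    out: list[tuple[float, float]] = []
    for i in idx:
        tp = trace.t[i]
        lo, hi = max(0, i - nref), min(len(ys), i + nref + 1)
        tau = trace.t[lo:hi] - trace.t[i]
        coef = np.polyfit(tau, det.y[lo:hi], 2)
        if coef[0] < 0:
            delta = float(np.clip(-coef[1] / (2 * coef[0]), -refine_h, refine_h))
        else:
            denom = ys[i - 1] - 2 * ys[i] + ys[i + 1] if 0 < i < len(ys) - 1 else 0.0
            delta = (float(np.clip(0.5 * (ys[i - 1] - ys[i + 1]) / denom, -1, 1))
                     * trace.dt_h) if denom < 0 else 0.0
        tp = trace.t[i] + delta
        j = int(round(tp / trace.dt_h - trace.t[0] / trace.dt_h))
        j = min(max(j, 0), len(ys) - 1)
        nval = max(2, int(round(value_refine_h / trace.dt_h)))
        vlo, vhi = max(0, j - nval), min(len(ys), j + nval + 1)
        vtau = trace.t[vlo:vhi] - tp
        raw_coef = np.polyfit(vtau, trace.y[vlo:vhi], 2)
        out.append((float(tp), float(np.polyval(raw_coef, 0.0))))
    return out


# ---------------------------------------------------------------------------
# FFT-initialised damped-cosine fitting


def _damped_cos(t, c0, c1, A, lam, T, phi, t0):
    return c0 + c1 * (t - t0) + A * np.exp(-lam * (t - t0)) * np.cos(
        2 * np.pi * (t - phi) / T)


def fit_fftnlls(
    trace: Trace,
    window: tuple[float, float] | None = None,
    period_band: tuple[float, float] = CIRCADIAN_BAND,
) -> RhythmFit:
    """Damped-cosine fit with FFT initialisation.

    The dominant discrete Fourier component of the linearly detrended window
    inside ``period_band`` seeds a nonlinear least-squares fit of

        y(t) = c0 + c1 t + A exp(-lam (t - t0)) cos(2 pi (t - phi) / T).

    Returns an ``arrhythmic`` result (rae = 1) rather than failing silently
    when no spectral component lies in the band or the fit cannot be
    determined.
    """
    sub = trace if window is None else trace.window(*window)
    t, y = sub.t, sub.y
    t0 = float(t[0])
    win = (t0, float(t[-1]))
    if (win[1] - win[0]) < 2 * period_band[0]:
        raise ValueError("window must span at least two putative cycles")

    def _arrhythmic() -> RhythmFit:
        return RhythmFit(period_h=np.nan, amplitude=0.0, phase_peak_h=np.nan,
                         damping_rate=0.0, rae=1.0, window=win,
                         residual_sd=float(np.std(y)), arrhythmic=True)

    # spectral initialisation on the linearly detrended window
    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    n = len(t)
    freqs = np.fft.rfftfreq(n, d=sub.dt_h)
    spec = np.fft.rfft(resid)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    band = (periods >= period_band[0]) & (periods <= period_band[1])
    if not band.any() or not np.any(np.abs(spec[band]) > 0):
        return _arrhythmic()
    k = np.flatnonzero(band)[np.argmax(np.abs(spec[band]))]
    T_init = float(np.clip(periods[k], *period_band))
    A_init = 2 * np.abs(spec[k]) / n
    # spec[k] ~ (A n / 2) exp(i theta) for resid = A cos(2 pi f (t-t0) + theta)
    theta = float(np.angle(spec[k]))
    phi_init = t0 + (-theta / (2 * np.pi)) * T_init

    p0 = [coef[1] * t0 + coef[0], coef[1], A_init, 0.0, T_init, phi_init]
    # damping bounded to physiologically plausible rates so that noise-only
    # windows cannot be absorbed by an exploding or collapsing envelope
    lo = [-np.inf, -np.inf, 0.0, -0.05, period_band[0], phi_init - T_init]
    hi = [np.inf, np.inf, np.inf, 0.1, period_band[1], phi_init + T_init]
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, c0, c1, A, lam, T, phi: _damped_cos(tt, c0, c1, A, lam, T, phi, t0),
            t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return _arrhythmic()

    c0, c1, A, lam, T, phi = popt
    residual = y - _damped_cos(t, *popt, t0)
    rss = float(np.sqrt(np.mean(residual ** 2)))
    var_A = pcov[2, 2]
    if not np.isfinite(var_A) or A <= 0:
        rae = 1.0
    else:
        rae = float(np.clip(1.96 * np.sqrt(var_A) / A, 0.0, 1.0))
    # first fitted peak at or after the window start
    phase_peak = phi + np.ceil((t0 - phi) / T - 1e-9) * T
    return RhythmFit(
        period_h=float(T), amplitude=float(A), phase_peak_h=float(phase_peak),
        damping_rate=float(lam), rae=rae, window=win, residual_sd=rss,
        arrhythmic=bool(rae >= 0.9),
    )


# ---------------------------------------------------------------------------
# treatment-response estimators


def _require_treatment(trace: Trace) -> float:
    if trace.treatment_time_h is None:
        raise EstimationError("trace has no treatment_time_h set")
    return float(trace.treatment_time_h)


def phase_shift(
    trace: Trace,
    pre_window_h: float = 96.0,
    post_window_h: float = 96.0,
    skip_h: float = 36.0,
    pre_period_h: float | None = None,
    n_post_peaks: int = 4,
) -> float:
    """Phase shift (hours) of the rhythm after treatment; delays negative.

    Peaks predicted by extrapolating multiples of the pre-treatment period
    from the last pre-treatment peak are compared with observed peaks in the
    post-treatment analysis window (the first ``skip_h`` hours after
    treatment are excluded).  Each observed peak is paired with the nearest
    predicted peak, differences capped at half a period to avoid
    cycle-skipping, and the shift is ``predicted - observed`` averaged over
    at most ``n_post_peaks`` peaks, so that a later-than-predicted (delayed)
    rhythm yields a negative value.
    """
    t0 = _require_treatment(trace)
    peaks = detect_peaks(trace)
    # peaks within half a baseline window of the trace edges carry
    # detrending edge bias and are not used
    edge_h = 12.0
    peaks = [(pt, pv) for pt, pv in peaks
             if trace.t[0] + edge_h <= pt <= trace.t[-1] - edge_h]
    pre = [(pt, pv) for pt, pv in peaks if pt < t0 and pt >= t0 - pre_window_h - 12]
    post = [(pt, pv) for pt, pv in peaks
            if t0 + skip_h <= pt <= t0 + skip_h + post_window_h]
    if len(pre) < 3:
        raise EstimationError(f"need >=3 pre-treatment peaks, found {len(pre)}")
    if len(post) < 2:
        raise EstimationError(f"need >=2 post-treatment peaks, found {len(post)}")
    post = post[:n_post_peaks]

    if pre_period_h is None:
        fit = fit_fftnlls(trace, (max(trace.t[0], t0 - pre_window_h), t0))
        if fit.arrhythmic:
            raise EstimationError("pre-treatment window is arrhythmic; cannot predict peaks")
        pre_period_h = fit.period_h

    last_pre = pre[-1][0]
    diffs = []
    for pt, _ in post:
        k = max(1, round((pt - last_pre) / pre_period_h))
        predicted = last_pre + k * pre_period_h
        d = pt - predicted
        d -= pre_period_h * np.round(d / pre_period_h)  # wrap to +-T/2
        diffs.append(d)
    return float(-np.mean(diffs))


def fold_induction(trace: Trace, n_pre: int = 3) -> float:
    """Acute induction as observed/extrapolated next-peak ratio.

    An exponential ("growth") regression of log peak value on peak index over
    the last ``n_pre`` pre-treatment peaks predicts the next peak value; the
    ratio of the first observed post-treatment peak to that prediction is the
    fold induction.
    """
    t0 = _require_treatment(trace)
    peaks = detect_peaks(trace)
    pre = [(pt, pv) for pt, pv in peaks if pt < t0]
    post = [(pt, pv) for pt, pv in peaks if pt >= t0]
    if len(pre) < n_pre:
        raise EstimationError(f"need >={n_pre} pre-treatment peaks, found {len(pre)}")
    if not post:
        raise EstimationError("need >=1 post-treatment peak, found 0")
    values = np.array([pv for _, pv in pre[-n_pre:]])
    if np.any(values <= 0):
        raise EstimationError("nonpositive peak value; cannot fit exponential growth")
    idx = np.arange(1, n_pre + 1, dtype=float)
    slope, intercept = np.polyfit(idx, np.log(values), 1)
    predicted = float(np.exp(intercept + slope * (n_pre + 1)))
    observed = post[0][1]
    if observed <= 0:
        raise EstimationError("nonpositive observed peak value")
    return float(observed / predicted)


def acute_induction_arrhythmic(trace: Trace, window_h: float = 6.0) -> float:
    """Acute induction for arrhythmic (e.g. Cry-null) recordings.

    The trace is normalised to its own maximum; the statistic is the highest
    normalised value within ``window_h`` hours after treatment minus the
    normalised value immediately before treatment.
    """
    t0 = _require_treatment(trace)
    if trace.t[-1] < t0 + window_h:
        raise EstimationError(f"need >= {window_h} h of post-treatment data")
    ymax = np.max(trace.y)
    if ymax <= 0:
        raise EstimationError("trace maximum must be positive for normalisation")
    y = trace.y / ymax
    pre_idx = np.flatnonzero(trace.t < t0)
    if not pre_idx.size:
        raise EstimationError("no samples before treatment")
    before = y[pre_idx[-1]]
    mask = (trace.t > t0) & (trace.t <= t0 + window_h)
    return float(np.max(y[mask]) - before)


def rms_change(
    trace: Trace,
    pre_window_h: float = 48.0,
    post_gap_h: float = 24.0,
    post_window_h: float = 48.0,
    baseline_window_h: float = 24.0,
) -> float:
    """Percent change in detrended RMS after treatment.

    The trace is normalised to its maximum and a rolling baseline of
    ``baseline_window_h`` is subtracted; RMS is computed over the
    ``pre_window_h`` hours before treatment and over a ``post_window_h``
    window starting ``post_gap_h`` after treatment.  Used as an amplitude
    analogue where no reliable oscillation exists.
    """
    t0 = _require_treatment(trace)
    if trace.t[0] > t0 - pre_window_h:
        raise EstimationError(f"need >= {pre_window_h} h of pre-treatment data")
    if trace.t[-1] < t0 + post_gap_h + post_window_h:
        raise EstimationError(
            f"need >= {post_gap_h + post_window_h} h of post-treatment data")
    ymax = np.max(trace.y)
    if ymax <= 0:
        raise EstimationError("trace maximum must be positive for normalisation")
    norm = trace.replace(y=trace.y / ymax)
    det = detrend_rolling(norm, baseline_window_h)

    def _rms(a: float, b: float) -> float:
        mask = (det.t >= a) & (det.t < b)
        return float(np.sqrt(np.mean(det.y[mask] ** 2)))

    pre = _rms(t0 - pre_window_h, t0)
    post = _rms(t0 + post_gap_h, t0 + post_gap_h + post_window_h)
    if pre == 0:
        raise EstimationError("pre-treatment RMS is zero")
    return float(100.0 * (post - pre) / pre)


def amplitude_change(
    pre_fit: RhythmFit, post_fit: RhythmFit, at_time_h: float | None = None,
) -> float:
    """Percent amplitude change between two fits.

    Both fitted envelopes are extrapolated to a common reference time
    (default: the end of the pre-treatment window, i.e. the treatment time)
    so that ongoing damping does not masquerade as a treatment effect.
    """
    if at_time_h is None:
        at_time_h = pre_fit.window[1]
    a_pre = pre_fit.amplitude_at(at_time_h)
    a_post = post_fit.amplitude_at(at_time_h)
    if a_pre <= 0:
        raise EstimationError("pre-treatment amplitude must be positive")
    return float(100.0 * (a_post - a_pre) / a_pre)


def period_change(pre_fit: RhythmFit, post_fit: RhythmFit) -> float:
    """Period change in hours (post minus pre)."""
    return float(post_fit.period_h - pre_fit.period_h)


class CorrelationResult(NamedTuple):
    pearson_r: float
    p_value: float
    slope: float
    intercept: float


def correlate_responses(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided t test plus an OLS line.

    Used e.g. to relate phase shift to acute fold induction across slices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.linregress(x, y)
    return CorrelationResult(float(res.rvalue), float(res.pvalue),
                             float(res.slope), float(res.intercept))


def analyze_treatment(
    trace: Trace,
    pre_window_h: float = 96.0,
    post_window_h: float = 96.0,
    skip_h: float = 36.0,
    with_rms: bool = False,
) -> TreatmentResponse:
    """Full per-slice treatment response.

    Fits the four days before treatment and four days after it (excluding
    the first ``skip_h`` hours post-treatment) and derives phase shift, fold
    induction, period and amplitude changes; the RMS change is included on
    request (it targets arrhythmic recordings).
    """
    t0 = _require_treatment(trace)
    pre_start = max(float(trace.t[0]), t0 - pre_window_h)
    post_start = t0 + skip_h
    post_end = min(float(trace.t[-1]) + trace.dt_h, post_start + post_window_h)
    pre_fit = fit_fftnlls(trace, (pre_start, t0))
    post_fit = fit_fftnlls(trace, (post_start, post_end))

    def _try(fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except EstimationError:
            return None

    shift = _try(phase_shift, trace, pre_window_h, post_window_h, skip_h)
    fold = _try(fold_induction, trace)
    d_per = amp = None
    if not pre_fit.arrhythmic and not post_fit.arrhythmic:
        d_per = period_change(pre_fit, post_fit)
        amp = _try(amplitude_change, pre_fit, post_fit, t0)
    rms = _try(rms_change, trace) if with_rms else None
    return TreatmentResponse(
        phase_shift_h=shift, fold_induction=fold, d_period_h=d_per,
        amplitude_change_pct=amp, rms_change_pct=rms,
        pre_fit=pre_fit, post_fit=post_fit)
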