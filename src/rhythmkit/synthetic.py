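"""Synthetic data generators with known ground truth.

Each generator emulates one class of input the analysis modules consume —
ensemble bioluminescence traces, single-cell time-lapse image stacks,
wheel-running actograms, and expression matrices — and returns the planted
parameters alongside the data so every downstream estimator can be validated
by parameter recovery.

Generation is phenomenological: a damped cosine with treatment-induced phase
delay / period lengthening / amplitude loss / acute induction stands in for
the TTFL reporter signal; no biophysical ODE model is attempted.

Phase convention: phase is the clock time of a peak.  CT12 is defined as the
reporter peak, so generators also report the circadian time of treatment as
``12 + (treatment time - nearest prior peak time) mod period``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .rhythm import Trace
from .imaging import ROI, ImagingSession
from .behaviour import ActivityRecord, LightSegment
from .expression import ExpressionMatrix

__all__ = [
    "EnsembleSpec", "EnsembleTruth", "SyntheticTrace", "gen_ensemble_trace",
    "WaveFieldSpec", "WaveFieldTruth", "SyntheticStack", "gen_image_stack",
    "ActogramSpec", "ScheduleSegment", "ActogramTruth", "SyntheticActogram",
    "gen_actogram",
    "ExpressionSpec", "GroupSpec", "ExpressionTruth", "SyntheticExpression",
    "gen_expression",
]


# ---------------------------------------------------------------------------
# ensemble traces


class EnsembleSpec(BaseModel):
    """Parameters of one synthetic ensemble bioluminescence recording.

    Times are hours, signal units counts per second (cps).  ``phase_h`` is
    the clock time of the first oscillation peak.  Damping is exponential on
    the oscillatory term only, leaving the baseline stable.  Treatment
    effects (all optional) switch on at ``treatment_time_h``: the oscillation
    continues with period ``period_h + d_period_h``, peaks shifted by
    ``d_phase_h`` (negative = delay, i.e. later peaks), amplitude scaled by
    ``amp_scale``, plus an additive induction transient that rises
    instantaneously at treatment to ``(induction_fold - 1)`` times the
    extrapolated next untreated peak value and decays with time constant
    ``induction_decay_h``.
    """

    duration_h: float = 240.0
    dt_h: float = Field(default=0.1, gt=0)
    period_h: float = Field(default=24.0, gt=0)
    phase_h: float = 12.0
    amplitude: float = Field(default=100.0, ge=0)
    damping_rate: float = 0.005
    baseline: float = 200.0
    baseline_drift: float = 0.0
    noise_sd: float = Field(default=10.0, ge=0)
    treatment_time_h: Optional[float] = None
    d_phase_h: float = 0.0
    d_period_h: float = 0.0
    amp_scale: float = Field(default=1.0, ge=0.0, le=1.0)
    induction_fold: float = Field(default=1.0, ge=0.0)
    induction_decay_h: float = Field(default=12.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EnsembleSpec":
        if self.duration_h < 3 * self.period_h:
            raise ValueError("duration_h must be at least 3 periods")
        if self.treatment_time_h is not None and not (
                0 < self.treatment_time_h < self.duration_h):
            raise ValueError("treatment_time_h must lie inside the recording")
        return self


@dataclass
class EnsembleTruth:
    """Ground truth of a generated ensemble trace."""

    peak_times_h: np.ndarray        # peaks of the noiseless signal
    peak_values: np.ndarray
    predicted_next_peak_value: float | None  # untreated extrapolation
    realized_fold_induction: float | None    # first post-peak / prediction
    treatment_ct: float | None               # circadian time of treatment
    spec: EnsembleSpec | None = None


@dataclass
class SyntheticTrace:
    trace: Trace
    truth: EnsembleTruth


def _ensemble_model(spec: EnsembleSpec):
    """Noiseless signal model; returns (f(t), anchors dict)."""
    T, phi, A = spec.period_h, spec.phase_h, spec.amplitude
    lam, b0, b1 = spec.damping_rate, spec.baseline, spec.baseline_drift
    t0 = spec.treatment_time_h
    anchors: dict = {}
    if t0 is not None:
        # last untreated cosine peak before treatment and the next predicted one
        k_last = int(np.floor((t0 - phi) / T))
        p_last = phi + k_last * T
        t_pred = p_last + T
        v_pred = b0 + b1 * t_pred + A * np.exp(-lam * t_pred)
        T_post = T + spec.d_period_h
        # delays are negative, so the first post peak is predicted - d_phase
        t_ref = t_pred - spec.d_phase_h
        anchors.update(p_last=p_last, t_pred=t_pred, v_pred=v_pred,
                       t_ref=t_ref, T_post=T_post)

    def f(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        base = b0 + b1 * t
        osc_pre = A * np.exp(-lam * t) * np.cos(2 * np.pi * (t - phi) / T)
        if t0 is None:
            return base + osc_pre
        osc_post = (A * spec.amp_scale * np.exp(-lam * t)
                    * np.cos(2 * np.pi * (t - anchors["t_ref"]) / anchors["T_post"]))
        transient = ((spec.induction_fold - 1.0) * anchors["v_pred"]
                     * np.exp(-(t - t0) / spec.induction_decay_h))
        post = base + osc_post + np.where(t >= t0, transient, 0.0)
        return np.where(t < t0, base + osc_pre, post)

    return f, anchors


def _model_peaks(f, duration_h: float, dt_fine: float,
                 min_separation_h: float) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of a noiseless model on a fine grid, quadratically refined."""
    from scipy.signal import find_peaks

    t = np.arange(0.0, duration_h, dt_fine)
    y = f(t)
    span = np.ptp(y)
    if span == 0:
        return np.array([]), np.array([])
    idx, _ = find_peaks(y, distance=max(1, int(min_separation_h / dt_fine)),
                        prominence=1e-6 * span)
    times = []
    for i in idx:
        tp = t[i]
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                tp += np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -1, 1) * dt_fine
        times.append(tp)
    times = np.asarray(times)
    return times, f(times)


def gen_ensemble_trace(spec: EnsembleSpec) -> SyntheticTrace:
    """Generate one ensemble trace plus its ground truth.

    Deterministic for a given spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_h, spec.dt_h)
    f, anchors = _ensemble_model(spec)
    y = f(t)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
    trace = Trace(t, y, spec.dt_h, spec.treatment_time_h, label="synthetic")

    peak_t, peak_v = _model_peaks(f, spec.duration_h, spec.dt_h / 10.0,
                                  min_separation_h=0.5 * spec.period_h)
    t0 = spec.treatment_time_h
    v_pred = fold = ct = None
    if t0 is not None:
        v_pred = float(anchors["v_pred"])
        post = peak_t > t0
        if post.any() and v_pred > 0:
            fold = float(peak_v[post][0] / v_pred)
        prior = peak_t[peak_t <= t0]
        if prior.size:
            ct = float((12.0 + (t0 - prior[-1]) % spec.period_h) % 24.0)
    truth = EnsembleTruth(peak_times_h=peak_t, peak_values=peak_v,
                          predicted_next_peak_value=v_pred,
                          realized_fold_induction=fold,
                          treatment_ct=ct, spec=spec)
    return SyntheticTrace(trace=trace, truth=truth)


# ---------------------------------------------------------------------------
# wave-field image stacks


class WaveFieldSpec(BaseModel):
    """A grid of oscillating cells with a spatial phase gradient.

    Cells are rendered as discs in a 16-bit stack; each cell's luminescence
    follows its own damped-cosine trace whose phase is offset by the
    projection of the cell position onto the gradient direction, scaled so
    the offset spans ``phase_gradient_span_h`` across the field, plus
    Gaussian scatter.  If the per-cell spec carries a treatment, the
    post-treatment gradient direction/span may differ — emulating a
    treatment that re-directs and compresses the spatiotemporal wave.
    """

    grid_nx: int = Field(default=5, ge=2)
    grid_ny: int = Field(default=5, ge=2)
    cell_radius_px: int = Field(default=3, ge=1)
    cell_spacing_px: Optional[int] = None   # default 4 * radius
    margin_px: int = 6
    frame_interval_h: float = Field(default=1.0, gt=0)
    phase_gradient_direction_deg: float = 45.0
    phase_gradient_span_h: float = Field(default=3.0, ge=0)
    post_treatment_gradient_direction_deg: Optional[float] = None
    post_treatment_gradient_span_h: Optional[float] = None
    phase_scatter_sd_h: float = Field(default=0.25, ge=0)
    post_treatment_scatter_sd_h: Optional[float] = None  # phase "tumbling"
    cell: EnsembleSpec = Field(
        default_factory=lambda: EnsembleSpec(noise_sd=0.0, baseline=20.0))
    intensity_per_cps: float = 50.0
    seed: int = 0


@dataclass
class WaveFieldTruth:
    centers_px: np.ndarray          # (n_cells, 2) x, y
    pre_phase_offsets_h: np.ndarray
    post_phase_offsets_h: np.ndarray
    cell_period_pre_h: float
    cell_period_post_h: float
    com_noiseless: np.ndarray       # (frames, 2) intensity-weighted CoM
    spec: WaveFieldSpec | None = None


@dataclass
class SyntheticStack:
    session: ImagingSession
    truth: WaveFieldTruth


def _gradient_offsets(centers: np.ndarray, direction_deg: float,
                      span_h: float) -> np.ndarray:
    u = np.array([np.cos(np.deg2rad(direction_deg)),
                  np.sin(np.deg2rad(direction_deg))])
    proj = centers @ u
    if np.ptp(proj) == 0 or span_h == 0:
        return np.zeros(len(centers))
    frac = (proj - proj.min()) / np.ptp(proj)
    return (frac - 0.5) * span_h


def gen_image_stack(spec: WaveFieldSpec) -> SyntheticStack:
    """Render a synthetic time-lapse stack of oscillating cell discs."""
    rng = np.random.default_rng(spec.seed)
    r = spec.cell_radius_px
    spacing = spec.cell_spacing_px or 4 * r
    nx, ny = spec.grid_nx, spec.grid_ny
    width = 2 * spec.margin_px + (nx - 1) * spacing + 2 * r + 1
    height = 2 * spec.margin_px + (ny - 1) * spacing + 2 * r + 1
    xs = spec.margin_px + r + spacing * np.arange(nx)
    ys = spec.margin_px + r + spacing * np.arange(ny)
    centers = np.array([(x, y) for y in ys for x in xs], dtype=float)

    pre_off = _gradient_offsets(centers, spec.phase_gradient_direction_deg,
                                spec.phase_gradient_span_h)
    post_dir = (spec.post_treatment_gradient_direction_deg
                if spec.post_treatment_gradient_direction_deg is not None
                else spec.phase_gradient_direction_deg)
    post_span = (spec.post_treatment_gradient_span_h
                 if spec.post_treatment_gradient_span_h is not None
                 else spec.phase_gradient_span_h)
    post_off = _gradient_offsets(centers, post_dir, post_span)
    scatter = rng.normal(0.0, 1.0, size=len(centers))
    post_scatter = rng.normal(0.0, 1.0, size=len(centers))
    pre_off = pre_off + spec.phase_scatter_sd_h * scatter
    post_sd = (spec.post_treatment_scatter_sd_h
               if spec.post_treatment_scatter_sd_h is not None
               else spec.phase_scatter_sd_h)
    if spec.post_treatment_scatter_sd_h is None:
        # same draw: an untreated field keeps its cellular phase identity
        post_off = post_off + post_sd * scatter
    else:
        post_off = post_off + post_sd * post_scatter

    n_frames = int(np.floor(spec.cell.duration_h / spec.frame_interval_h))
    frame_t = np.arange(n_frames) * spec.frame_interval_h

    yy, xx = np.mgrid[0:height, 0:width]
    stack_f = np.zeros((n_frames, height, width), dtype=float)
    rois: list[ROI] = []
    traces: list[Trace] = []
    for i, (cx, cy) in enumerate(centers):
        cell_spec = spec.cell.model_copy(update={
            "phase_h": spec.cell.phase_h + pre_off[i],
            "d_phase_h": spec.cell.d_phase_h + (pre_off[i] - post_off[i]),
            "dt_h": spec.frame_interval_h,
            "seed": int(rng.integers(0, 2 ** 31 - 1)),
        })
        f, _ = _ensemble_model(cell_spec)
        values = f(frame_t)
        if cell_spec.noise_sd > 0:
            cell_rng = np.random.default_rng(cell_spec.seed)
            values = values + cell_rng.normal(0, cell_spec.noise_sd, n_frames)
        values = np.clip(values, 0.0, None)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        stack_f[:, mask] += values[:, None]
        rois.append(ROI(id=i, mask=mask, centroid_px=(float(cx), float(cy))))
        traces.append(Trace(frame_t, values, spec.frame_interval_h,
                            spec.cell.treatment_time_h, label=f"cell{i}"))

    # CoM of the noiseless field (re-render without per-cell noise)
    noiseless = np.zeros_like(stack_f)
    for i, (cx, cy) in enumerate(centers):
        cell_spec = spec.cell.model_copy(update={
            "phase_h": spec.cell.phase_h + pre_off[i],
            "d_phase_h": spec.cell.d_phase_h + (pre_off[i] - post_off[i]),
            "dt_h": spec.frame_interval_h,
            "noise_sd": 0.0,
        })
        f, _ = _ensemble_model(cell_spec)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        noiseless[:, mask] += np.clip(f(frame_t), 0.0, None)[:, None]
    total = noiseless.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        com_x = (noiseless * xx).sum(axis=(1, 2)) / total
        com_y = (noiseless * yy).sum(axis=(1, 2)) / total
    com = np.column_stack([com_x, com_y])

    scale = spec.intensity_per_cps
    stack16 = np.clip(stack_f * scale, 0, 65535).astype(np.uint16)
    session = ImagingSession(stack=stack16,
                             frame_interval_h=spec.frame_interval_h,
                             rois=rois, traces=traces, com=None)
    truth = WaveFieldTruth(
        centers_px=centers, pre_phase_offsets_h=pre_off,
        post_phase_offsets_h=post_off,
        cell_period_pre_h=spec.cell.period_h,
        cell_period_post_h=spec.cell.period_h + spec.cell.d_period_h,
        com_noiseless=com, spec=spec)
    return SyntheticStack(session=session, truth=truth)


# ---------------------------------------------------------------------------
# actograms


class ScheduleSegment(BaseModel):
    """One block of the lighting schedule.

    ``LD`` segments entrain activity onset to ``lights_off_h`` minus the
    phase angle; successive LD segments with different lights implement
    jet-lag shifts, to which onsets re-entrain along a logistic.  ``DD``
    segments free-run at ``tau_dd_h``.  A ``light_pulse`` segment is DD with
    a single pulse at ``pulse_zt_h`` (ZT of the preceding LD cycle) on its
    first day, shifting subsequent onsets by the spec's ``pulse_shift_h``.
    """

    mode: Literal["LD", "DD", "light_pulse"]
    days: int = Field(ge=1)
    lights_on_h: float = 6.0
    lights_off_h: float = 18.0
    shift_h: float = 0.0
    pulse_zt_h: float = 14.0


class ActogramSpec(BaseModel):
    """Parameters of a synthetic wheel-running record (6-min bins)."""

    bin_min: int = Field(default=6, gt=0)
    schedule: list[ScheduleSegment] = Field(
        default_factory=lambda: [ScheduleSegment(mode="LD", days=10)])
    tau_dd_h: float = Field(default=23.7, gt=0)
    phase_angle_min: float = 6.0    # onset this many minutes before lights-off
    alpha_h: float = Field(default=10.0, lt=24.0, gt=0)
    bout_rate: float = Field(default=40.0, gt=0)  # counts per bin when active
    background_fraction: float = 0.02
    reentrain_ps50_day: float = 4.0
    reentrain_slope: float = 1.5    # per day
    pulse_shift_h: float = 0.0
    pulse_transient_days: int = 2
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ActogramSpec":
        if (24 * 60) % self.bin_min != 0:
            raise ValueError("bin_min must divide 24 h evenly")
        return self

    @property
    def n_days(self) -> int:
        return sum(s.days for s in self.schedule)


@dataclass
class ActogramTruth:
    onsets_h: np.ndarray    # absolute hours since record start, per day
    offsets_h: np.ndarray
    spec: ActogramSpec | None = None


@dataclass
class SyntheticActogram:
    record: ActivityRecord
    truth: ActogramTruth


def _logistic(x: np.ndarray | float, mid: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(x, dtype=float) - mid)))


def gen_actogram(spec: ActogramSpec) -> SyntheticActogram:
    """Generate Poisson wheel-running counts with planted onsets.

    Counts are Poisson at ``bout_rate`` per bin inside the daily activity
    window and at ``background_fraction * bout_rate`` outside it, so onset
    detectors are exercised against a nonzero background.
    """
    rng = np.random.default_rng(spec.seed)
    bin_h = spec.bin_min / 60.0
    n_days = spec.n_days
    n_bins = int(round(n_days * 24 / bin_h))

    onsets: list[float] = []   # clock-hour of onset per day, unwrapped
    segments: list[LightSegment] = []
    day0 = 0
    prev_onset: float | None = None
    drift = spec.tau_dd_h - 24.0
    for seg in spec.schedule:
        seg_days = np.arange(seg.days)
        if seg.mode == "LD":
            target = seg.lights_off_h - spec.phase_angle_min / 60.0
            if prev_onset is None or abs(target - prev_onset) < 0.25:
                day_onsets = np.full(seg.days, target)
            else:
                delta = target - prev_onset
                delta -= 24.0 * np.round(delta / 24.0)  # re-entrain the short way
                frac = _logistic(seg_days + 1, spec.reentrain_ps50_day,
                                 spec.reentrain_slope)
                day_onsets = prev_onset + delta * frac
            segments.append(LightSegment("LD", day0, day0 + seg.days,
                                         seg.lights_on_h, seg.lights_off_h))
        else:  # DD or light_pulse
            start = prev_onset if prev_onset is not None else 18.0
            day_onsets = start + drift * (seg_days + 1)
            if seg.mode == "light_pulse" and spec.pulse_shift_h != 0.0:
                # delays negative: shift onsets later by -pulse_shift_h,
                # approached linearly over the transient days
                full = -spec.pulse_shift_h
                ramp = np.clip((seg_days + 1) / max(1, spec.pulse_transient_days + 1),
                               0.0, 1.0)
                day_onsets = day_onsets + full * ramp
            segments.append(LightSegment(seg.mode, day0, day0 + seg.days,
                                         None, None))
        onsets.extend(day_onsets.tolist())
        prev_onset = float(day_onsets[-1])
        day0 += seg.days

    # onset clock hours are continuous (un-wrapped) across days, so the
    # absolute times stay monotone even when an onset drifts past midnight
    onsets_abs = np.array([24.0 * d + h for d, h in enumerate(onsets)])
    offsets_abs = onsets_abs + spec.alpha_h

    rate = np.full(n_bins, spec.background_fraction * spec.bout_rate)
    centers = (np.arange(n_bins) + 0.5) * bin_h
    for a, b in zip(onsets_abs, offsets_abs):
        rate[(centers >= a) & (centers < b)] = spec.bout_rate
    counts = rng.poisson(rate)

    record = ActivityRecord(counts=counts, bin_min=spec.bin_min,
                            schedule=segments)
    truth = ActogramTruth(onsets_h=onsets_abs, offsets_h=offsets_abs, spec=spec)
    return SyntheticActogram(record=record, truth=truth)


# ---------------------------------------------------------------------------
# expression matrices


class GroupSpec(BaseModel):
    name: str
    n_samples: int = Field(ge=2)


_CATEGORIES = ("CRE-TATA", "CRE-NoTATA", "Others")


class ExpressionSpec(BaseModel):
    """Parameters of a synthetic gene x sample intensity matrix.

    Emulates a four-group treated/vehicle array design: log-normal
    intensities, a planted fraction of differentially expressed genes in
    ``de_group`` (vs all other groups), per-probe detection p-values with a
    fraction of never-detected probes, and promoter-category labels drawn
    from separate ratios for null and DE genes so category enrichment is
    plantable.
    """

    n_genes: int = Field(default=5000, ge=10)
    groups: list[GroupSpec] = Field(default_factory=lambda: [
        GroupSpec(name="CT10", n_samples=4),
        GroupSpec(name="CT12_Veh", n_samples=4),
        GroupSpec(name="CT12_VIP", n_samples=4),
        GroupSpec(name="CT16_VIP", n_samples=4),
    ])
    de_group: str = "CT12_VIP"
    de_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    de_up_fraction: float = Field(default=0.65, ge=0.0, le=1.0)
    effect_size_log2: float = 1.0
    dispersion: float = Field(default=0.25, ge=0.0)
    detection_fail_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    cre_background_ratios: tuple[float, float, float] = (0.10, 0.25, 0.65)
    cre_de_ratios: tuple[float, float, float] = (0.25, 0.30, 0.45)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ExpressionSpec":
        for name in ("cre_background_ratios", "cre_de_ratios"):
            v = getattr(self, name)
            if abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.de_group not in {g.name for g in self.groups}:
            raise ValueError("de_group must be one of the group names")
        return self


@dataclass
class ExpressionTruth:
    de_genes: list[str]
    de_log2fc: dict[str, float]
    undetected_genes: list[str]
    spec: ExpressionSpec | None = None


@dataclass
class SyntheticExpression:
    matrix: ExpressionMatrix
    truth: ExpressionTruth


def gen_expression(spec: ExpressionSpec) -> SyntheticExpression:
    """Generate a log-normal intensity matrix with planted DE and enrichment."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples, group_of = [], {}
    for g in spec.groups:
        for j in range(g.n_samples):
            name = f"{g.name}_s{j}"
            samples.append(name)
            group_of[name] = g.name

    n, m = spec.n_genes, len(samples)
    mu = rng.normal(7.0, 1.5, size=n)
    log2 = mu[:, None] + rng.normal(0.0, spec.dispersion, size=(n, m))

    undetected = rng.random(n) < spec.detection_fail_fraction
    detected_idx = np.flatnonzero(~undetected)
    n_de = int(round(spec.de_fraction * len(detected_idx)))
    de_idx = rng.choice(detected_idx, size=n_de, replace=False) if n_de else \
        np.array([], dtype=int)
    sign = np.where(rng.random(n_de) < spec.de_up_fraction, 1.0, -1.0)
    de_cols = [i for i, s in enumerate(samples)
               if group_of[s] == spec.de_group]
    lfc = sign * spec.effect_size_log2
    for gi, eff in zip(de_idx, lfc):
        log2[gi, de_cols] += eff

    values = np.power(2.0, log2)
    detection = np.where(undetected[:, None],
                         rng.uniform(0.02, 1.0, size=(n, m)),
                         rng.uniform(0.0, 0.009, size=(n, m)))

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    cats = np.empty(n, dtype=object)
    bg = np.array(spec.cre_background_ratios)
    de_r = np.array(spec.cre_de_ratios)
    null_mask = ~is_de
    cats[null_mask] = rng.choice(_CATEGORIES, size=null_mask.sum(), p=bg)
    if is_de.any():
        cats[is_de] = rng.choice(_CATEGORIES, size=is_de.sum(), p=de_r)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        detection_p=pd.DataFrame(detection, index=genes, columns=samples),
        groups=pd.Series(group_of, name="group"),
        gene_annotation=pd.Series(cats, index=genes, name="cre_category"),
    )
    truth = ExpressionTruth(
        de_genes=[genes[i] for i in de_idx],
        de_log2fc={genes[i]: float(e) for i, e in zip(de_idx, lfc)},
        undetected_genes=[genes[i] for i in np.flatnonzero(undetected)],
        spec=spec)
    return SyntheticExpression(matrix=matrix, truth=truth)
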