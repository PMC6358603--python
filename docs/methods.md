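# Methods

This note documents the models, estimator conventions, defaults and
limitations behind rhythmkit.  All times are hours, signals counts per
second (cps), activity counts per bin.

## Synthetic data model

Generation is phenomenological: the goal is data on which every estimator
can be validated by parameter recovery, not a biophysical model of the
transcriptional–translational feedback loop.

### Ensemble traces (`EnsembleSpec`, `gen_ensemble_trace`)

The noiseless signal is

    y(t) = b0 + b1 t + A e^(−λt) cos(2π(t−φ)/T)          (before treatment)

with damping applied to the oscillatory term only — decaying peak
envelopes over stable troughs, as seen in slice recordings.  From the
treatment time t0 the oscillation continues with period T + ΔT, amplitude
A·amp_scale, and peak times displaced by −d_phase_h (delays are negative
throughout the package), anchored so the first post-treatment peak sits at
the next extrapolated pre-treatment peak minus d_phase_h.  An additive
induction transient rises instantaneously at t0 to
(induction_fold − 1) × (extrapolated next untreated raw peak value) and
decays exponentially with time constant induction_decay_h (default 12 h —
induced reporter bioluminescence visibly persists into the next cycle; the
rise kinetics are not modelled).  Gaussian iid noise is added last.

Consequence worth knowing: the *realized* fold induction at the first
post-treatment peak is slightly below the planted value (≈1.48 for a
planted 1.5 with treatment 2 h before the peak), because the transient
decays between treatment and the peak.  The generator reports the realized
value in its ground truth alongside the planted parameter.

Defaults emulate a typical organotypic recording: 10 days at 6-min bins,
T = 24 h, first peak at hour 12, A = 100, baseline 200, λ = 0.005/h, noise
10 (10% of amplitude).  Treatment at hour 106 is 2 h before the peak, i.e.
circadian time 10 under the convention CT12 = reporter peak; the generator
reports the treatment CT as 12 + (t0 − preceding peak) mod T.

Ground-truth peak times/values are computed numerically from the noiseless
model on a 10× finer grid with parabolic refinement, so they include the
small peak displacements produced by damping, drift and the transient.

### Wave fields (`WaveFieldSpec`, `gen_image_stack`)

Cells are discs (default radius 3 px, 5×5 grid, spacing 4 radii) whose
intensities follow per-cell ensemble traces.  A cell's phase offset is the
projection of its position onto the gradient direction, scaled so offsets
span `phase_gradient_span_h` (default 3 h) across the field, plus Gaussian
scatter (default 0.25 h).  After treatment the gradient direction, span and
scatter may change (`post_treatment_*`): re-directing the wave, collapsing
it, or dispersing cellular phases ("phase tumbling").  When no
post-treatment scatter is given, the pre-treatment draw is reused so an
untreated field keeps its cellular phase identity.  The stack is rendered
16-bit; the ground truth includes per-cell phase offsets, ROI masks, true
traces and the intensity-weighted CoM of the noiseless field.

### Actograms (`ActogramSpec`, `gen_actogram`)

Counts are Poisson: bout_rate (default 40/bin) inside the daily activity
window (onset to onset + alpha_h, default 10 h), 2% of bout_rate outside —
onset detectors must cope with a nonzero floor.  Onsets follow the
schedule: in LD, lights-off minus the phase angle (default +6 min, onset
before lights-off); after an LD→LD shift they approach the new steady
state along a logistic with midpoint `reentrain_ps50_day` and slope
`reentrain_slope`/day, taking the short way around the clock; in DD they
drift by (tau_dd_h − 24) per day; a light-pulse segment is DD with all
subsequent onsets displaced by −pulse_shift_h, reached linearly over
`pulse_transient_days` (default 2) transient cycles.  Onset clock hours are
kept continuous (un-wrapped) across days so activity windows stay disjoint
when an onset drifts past midnight.

### Expression matrices (`ExpressionSpec`, `gen_expression`)

log2 intensities are N(μ_g, dispersion²) around gene means μ_g ~ N(7, 1.5²)
and exponentiated to a log-normal raw scale.  The default design has four
groups of four samples (untreated baseline, vehicle, and two
treatment/harvest-time groups) matching a treated-slice array experiment.
A fraction (default 5%) of detected genes is shifted by ±effect_size_log2
in the designated group, 65% of them upward.  A fraction (default 20%) of
genes receives detection p-values above 0.01 in every sample (never
detected); the rest are below 0.01 everywhere.  Promoter categories are
sampled from `cre_background_ratios` for null genes and `cre_de_ratios`
for the planted ones, so category enrichment has a controllable truth.

## Estimator conventions

### Peak detection

Candidates are local maxima of the 24 h rolling-detrended, 2 h smoothed
trace, ≥16 h apart, with height and prominence above 2% of the signal
span.  Peak times are refined by a least-squares parabola over ±4 h of the
detrended signal (the cosine is near-quadratic over a sixth of a cycle, so
the vertex is unbiased while noise is averaged); peak values are read from
the raw trace via a narrower ±1.5 h parabola, which suppresses single-bin
noise without flattening sharp induction peaks.  Three-point quadratic
interpolation is the fallback when the parabola degenerates.

### Damped-cosine fit and RAE

Nonlinear least squares of c0 + c1 t + A e^(−λ(t−t0)) cos(2π(t−φ)/T),
seeded by the dominant rFFT component in the 16–32 h band after linear
detrending.  T is bounded to the band; λ to [−0.05, 0.1]/h (physiological
damping; wider bounds let noise-only windows be absorbed by exploding
envelopes).  One oscillatory component only — SCN ensemble traces are
single-component circadian.  RAE = 1.96·SE(A)/A from the fit covariance,
clipped to [0, 1]; a window is labelled arrhythmic when RAE ≥ 0.9, when no
spectral component exists in the band, or when the fit fails.  Amplitudes
are referenced to the window start; comparisons across windows extrapolate
both envelopes to a common time (the treatment time) so ongoing damping is
not misread as a treatment effect.

### Treatment response windows

Defaults follow the 4-days-before / 4-days-after convention, excluding the
first 36 h after treatment from phase and fit windows (the acute transient
is not steady-state rhythm).  Phase shift: predicted peak k = last
pre-treatment peak + k·T_pre (T_pre from the pre-window fit); each observed
post-window peak pairs with the nearest prediction, differences capped at
T/2 to avoid cycle-skipping; shift = mean(predicted − observed) over at
most 4 peaks, so delays are negative.  Peaks within 12 h of the trace edges
are excluded (detrending edge bias).  Because observed−predicted is
wrapped at half a period, shifts beyond ±T/2 alias; the planted effects
studied here are well inside that range.  Fold induction uses a log-linear
("growth") regression over exactly the last three pre-treatment peak
values.  The RMS amplitude analogue normalises the trace to its maximum,
subtracts a 24 h rolling baseline, and compares RMS over [t0−48, t0) with
[t0+24, t0+72).

### Imaging

ROI segmentation thresholds the temporal-SD projection at mean + 1.5·SD
after per-frame 3×3 median despeckling and temporal-minimum background
subtraction; components outside 4–400 px are rejected.  The per-ROI phase
entering Rayleigh statistics is the first fitted peak time in the analysis
window modulo the fitted period.  The Rayleigh p-value uses the standard
series approximation of the uniformity test and is flagged approximate for
n < 50.  `com_series` subtracts the per-frame *spatial* minimum instead of
the temporal minimum — the CoM must still see static structures — applies
the 20th-percentile threshold over nonzero pixels (CCD thresholds in real
pipelines are operator-chosen; this is configurable), weights by intensity,
and returns NaN for frames whose total intensity is under 5% of the
brightest frame (circadian troughs, where a CoM would only track noise).
The mean cycle path folds positions by circadian phase into 24 bins/cycle
(hourly frames) over 5 cycles by default; the perimeter closes the loop,
and the direction is the first principal axis of the binned path.

### Behaviour

The periodogram uses the Sokolove–Bushell statistic in the form
Qp = (N/K)·Σ_h(M_h − M)² / (Σ_i(x_i − M)²/N) for a trial period of K bins,
which is χ²(K−1) under the null (verified by simulation); the significance
line is the 1−0.001 quantile; the best period is the largest excursion
above the line, or absent.  Onsets: first bin above 20% of the day's
smoothed peak, preceded by a ≥4 h quiet interval (≤20% active, looking
across the day boundary) and confirmed by ≥50% activity over the following
3 h; offsets are the mirror criterion.  Bouts truncated by the record edges
are not scored.  These thresholds mimic common actogram-software defaults
and are all arguments.  Days are calendar days; free-running drift is
handled by un-wrapping marker times across days rather than re-slicing into
circadian days — the downstream regression/logistic estimators are
invariant to that choice and unwrapping is robust to missed days.  PS50 is
the fitted midpoint of a 4-parameter logistic of marker time vs day;
including a few pre-shift days anchors the lower asymptote and is the
recommended usage.  Light-pulse shifts fit regression lines to ≥5 onsets
per side, excluding 2 transient cycles after the pulse, and difference the
extrapolations at the pulse day; drift from tau ≠ 24 cancels between the
two lines.

### Expression

The variance-stabilising transform is log2(x + c) with c = 1 by default;
bead-level variance modelling is deliberately out of scope, and the
transform is switchable at the `normalize` call.  Quantile normalisation
replaces each column's order statistics with the mean order statistic and
is exactly idempotent.  The moderated t shrinks gene variances toward a
prior fitted by the method of moments on log sample variances: with
residual df d, log s² has variance trigamma(d/2) + trigamma(d0/2) around
log s0² after digamma bias correction; the excess over trigamma(d/2) is
inverted (Newton on the trigamma) for the prior df d0, and the posterior
variance (d0 s0² + d s²)/(d0 + d) enters a t statistic with d0 + d degrees
of freedom.  Zero or negative excess yields d0 = ∞ (fully pooled variance,
normal reference).  With moderation off the statistic reduces exactly to
the pooled-variance two-sample t.  FDR is Benjamini–Hochberg.  Enrichment
is a plain goodness-of-fit chi-square of the regulated set's category
counts against background-ratio expectations (df = categories − 1), with a
reliability flag when any expected count is below 5; up- and down-regulated
sets can be tested pooled or separately by passing the corresponding gene
sets.

## What the synthetic tests do and do not show

The generators reproduce the *structure* of the real inputs — damped
single-component rhythms, disc-shaped cells on a dark field, Poisson
activity with crisp onsets, log-normal intensities with planted effects —
and the validation shows the estimators recover planted parameters under
those conditions (phase-shift MAE < 0.3 h at 10% noise; period to 0.1 h;
PS50 to 0.25 day; calibrated type-I rates).  They do not emulate slice
explant drift and medium-change artefacts, cell movement or division,
mouse-to-mouse behavioural idiosyncrasies (nest-building days, split
activity), bead-array spatial artefacts, or probe cross-hybridisation.
Passing tests therefore demonstrate correctness of the computations and
robustness to the modelled noise, not immunity to every artefact of real
recordings.

## Problem sizes and numerics

Validation runs use 10-day ensemble recordings (2400 samples), 25-cell
fields of 240 hourly frames, 17–23-day actograms at 6-min bins, and
3000–5000-gene matrices, with 20–100 Monte-Carlo seeds per claim and up to
1000 for rejection-rate calibrations — enough for the quoted tolerances
while keeping the full suite and the acceptance script fast on one CPU.
Tie-breaks and degenerate inputs: constant traces yield empty peak lists
and are rejected by the periodogram; uniform stacks yield zero ROIs with a
warning; days without supra-threshold activity are reported missing, never
interpolated; correlation is refused for constant input; enrichment is
refused for categories absent from the background.

## Known limitations

- Phase shifts alias beyond half a period; the peak-pairing cap at T/2 is
  a convention, not a detection of cycle slips.
- The phase-shift estimate conflates a sustained period change with the
  acute shift when both are planted (as does any peak-extrapolation
  method); parameter-recovery claims use one effect at a time.
- RAE uses the asymptotic fit covariance, not a bootstrap; near-arrhythmic
  windows are summarised only by the arrhythmic flag.
- No image registration or ROI tracking: drifting or dividing cells are
  outside scope.
- The periodogram grid is limited to integer multiples of the bin width
  (0.1 h at 6-min bins), bounding period resolution accordingly.
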