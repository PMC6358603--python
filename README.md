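# rhythmkit

Quantification toolkit for circadian experiments on the suprachiasmatic
nucleus (SCN) and similar systems: ensemble bioluminescence recordings from
organotypic slices carrying luciferase clock reporters (e.g. PER2::LUC),
single-cell bioluminescence time-lapse imaging, wheel-running behaviour, and
microarray-style expression matrices.

It is written for chronobiologists who need the standard quantities of the
field — period, amplitude, relative amplitude error (RAE), phase shifts,
acute induction, circuit-level phase coherence and spatiotemporal waves,
behavioural re-entrainment kinetics, and transcript-set enrichment — as a
tested, scriptable pipeline rather than a chain of spreadsheet and GUI
steps.  A synthetic-data module generates every input class with known
ground truth, so each estimator is validated by parameter recovery.

## What it computes

**Ensemble traces** (`rhythmkit.rhythm`).  Damped-cosine fits initialised
from the dominant Fourier component in the 16–32 h band,

    y(t) = c0 + c1 t + A e^(−λ(t−t0)) cos(2π(t−φ)/T),

give period T, amplitude A, damping λ and RAE (half-width of the 95%
amplitude CI over A, clipped to [0, 1]).  Phase shifts compare observed
post-treatment peaks with peaks predicted by extrapolating the
pre-treatment period from the last pre-treatment peak (delays negative);
acute induction is the first observed post-treatment peak over the value
extrapolated from an exponential ("growth") regression of the three
preceding peaks; arrhythmic (e.g. Cry1⁻/⁻Cry2⁻/⁻) recordings are handled
with a 6-h induction window and a detrended-RMS amplitude analogue.

**Imaging** (`rhythmkit.imaging`).  ROI segmentation from the temporal-SD
projection of a despeckled, background-subtracted stack; per-cell traces
feed the same rhythm estimators; phase coherence is the Rayleigh mean
resultant length R with the standard uniformity test; the spatiotemporal
wave is summarised by the intensity-weighted centre of mass (CoM), its
phase-folded mean cycle path, the path perimeter and principal direction.

**Behaviour** (`rhythmkit.behaviour`).  Sokolove–Bushell chi-squared
periodogram with the χ²(K−1) significance line; threshold-based activity
onset/offset detection; phase angle of entrainment (lights-off minus onset,
positive when activity starts early); activity duration (alpha); 50%
phase-shift day (PS50) from a four-parameter logistic fit of re-entrainment
markers; Aschoff Type II light-pulse shifts by onset-regression
extrapolation.

**Expression** (`rhythmkit.expression`).  Detection-p filtering (a probe is
dropped only when undetected in every sample of the comparison), log2 +
quantile normalisation, a moderated t statistic with method-of-moments
variance shrinkage and Benjamini–Hochberg FDR, and promoter-category
(CRE-TATA / CRE-NoTATA / Others) chi-square enrichment against background
ratios, reported as observed/expected per category.

## Worked example

```python
import rhythmkit.rhythm as rhythm
import rhythmkit.synthetic as synthetic

# a 10-day PER2::LUC-like recording, treated at hour 106 (circadian time 10)
# with a planted 4 h phase delay, 1.5-fold induction and amplitude halving
spec = synthetic.EnsembleSpec(
    treatment_time_h=106.0, d_phase_h=-4.0, induction_fold=1.5,
    amp_scale=0.5, noise_sd=5.0, duration_h=240.0, seed=11)
trace = synthetic.gen_ensemble_trace(spec).trace
resp = rhythm.analyze_treatment(trace)
print(f"phase shift   {resp.phase_shift_h:+.2f} h")
print(f"fold induction {resp.fold_induction:.2f}")
print(f"period change {resp.d_period_h:+.2f} h")
print(f"amplitude     {resp.amplitude_change_pct:+.1f} %")
```

prints

```
phase shift   -4.26 h
fold induction 1.23
period change -0.10 h
amplitude     -54.7 %
```

i.e. the planted delay is recovered within ~0.3 h, the induction reads 1.23
for this seed (the transient decays between treatment and the next peak,
and the halved oscillation lowers the observed peak), the period is
essentially unchanged and the amplitude loss is recovered within a few
percentage points.  The same estimators are exposed on files through the CLI:

```sh
rhythmkit simulate ensemble --config cfg.json --seed 1 --out sim/
rhythmkit analyze sim/trace.csv --treatment-time 106 --out response.json
rhythmkit image stack.tif --frame-interval 1 --out imaging/
rhythmkit behaviour actogram.csv --schedule sched.json --out behaviour/
rhythmkit expr matrix.tsv --annot annotation.tsv \
    --compare CT12_VIP,CT12_Veh --out expr/
```

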