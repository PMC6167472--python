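# Methods

This note records the scientific and numerical choices behind `tbivitals`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Signals and conventions

Waveforms are uniformly sampled single-channel ECG or PPG at 240 Hz (any
fs ≥ 100 Hz is accepted), in arbitrary amplitude units. Time is seconds
from arrival in the trauma resuscitation unit (TRU); sample indices are
0-based; inter-beat intervals are milliseconds. The analysis windows are
the first 15 and 60 minutes from arrival (900 s / 3600 s); a window with
fewer than 30 good beats (`AnalysisWindow.min_good_beats`) is rejected
rather than imputed.

## Beat detection and delineation

The R-peak detector is a Pan–Tompkins-style energy detector: 5–25 Hz
band-pass (2nd-order Butterworth, zero-phase), squared derivative, 150 ms
moving-window integration, threshold at 15% of the 99th energy percentile,
250 ms refractory period, and refinement of each detection to the raw
signal maximum within ±60 ms. The threshold is relative, so the detector is
amplitude-scale free; a flat record yields no detections. Beats whose
delineation windows cross the record edge are dropped.

Delineation searches fixed windows around R: Q is the signal minimum in the
80 ms before R, S the minimum in the 100 ms after, P the maximum in
[R−250 ms, R−80 ms), T the maximum in (R+100 ms, R+400 ms]. These windows
cover the normal adult QRS at 240 Hz and guarantee the fiducial ordering
P < Q < R < S < T by construction. A beat whose Q or S lands exactly on its
window boundary has no real deflection (e.g. a monophasic complex) and is
kept but flagged low-confidence.

PPG systolic peaks are found by prominence (40% of the robust signal
range), which prevents secondary dicrotic waves from being counted as
pulses; the pulse foot is the minimum between consecutive peaks.

## Beat-quality masking (the interval Z-test)

Good-quality signal is assumed to yield approximately normal inter-beat
intervals locally, so an interval whose |z| exceeds 3.0 within its segment
marks a low-quality beat, and both beats bounding a flagged interval are
masked. Two deliberate choices:

* **Robust scaling by default.** The plain mean/SD Z-test is corrupted by
  the very outliers it hunts (a single 2000 ms dropout interval inflates
  the SD enough to hide itself). The default uses median and 1.4826×MAD;
  the textbook mean/SD mode is available via `robust=False`.
* **Segments are 300 consecutive intervals**, not a fixed time span. Two
  reasons: the mask must be invariant under affine rescaling of the
  interval series (time-based boundaries depend on the values themselves),
  and the MAD scale estimate needs a few hundred samples before the 3-sigma
  tail test is calibrated — with ~75-interval segments the realized
  false-flag rate on clean data runs well above the nominal
  2Φ(−3) ≈ 0.27%, with 300 it sits at 0.2–0.4%. Artifacts of interest
  (dropouts, motion bursts) are far shorter than a segment and remain
  conspicuous.

Fewer than 10 intervals are indeterminate: everything is flagged bad, with
a warning, rather than guessed at.

## HRV / PPGV and morphology features

Time-domain metrics follow the standard definitions: SDNN and RMSSD on NN
(or PPG peak-to-peak) intervals, pNN50 as a percentage, CV = SDNN/mean.
SDNN uses the sample (n−1) standard deviation. The nonlinear set is fixed
to Poincaré SD1/SD2 and sample entropy (m = 2, r = 0.2·SD) — the canonical
choices where a specific nonlinear battery is not dictated; frequency-domain
HRV is deliberately out of scope. SD1/SD2 use the population variance so
that SD1 is *exactly* the spread of the Poincaré cloud normal to the line
of identity (an identity the tests verify to 1e-9). Metrics whose
preconditions fail (too few intervals, zero tolerance on a constant series)
are omitted with a warning, never NaN-filled.

Each per-beat series (NN interval, Q→R rise time/amplitude, R→S fall
time/amplitude, PPG rise/fall geometry, notch deceleration/acceleration) is
summarized over the window by Q1/median/Q3 (linear interpolation between
order statistics, the type-7 convention), min, max, and Shannon entropy in
bits over 16 equal-width bins between the series min and max. The entropy
is bounded by log₂16 = 4 bits and reaches the bound only for uniform bin
occupancy; a (near-)constant series — range below 1e-9 relative, i.e.
float-noise level — has entropy 0.

## Dicrotic-notch detection

First and second derivatives are three-point central differences
(one-sided at the endpoints; exact for quadratics). Within each pulse the
notch search region is the diastolic downslope between the systolic peak
and the next foot, with a 30 ms margin at both ends; the second derivative
is lightly smoothed (15 ms uniform window, symmetric, so the curvature
maximum does not shift). The notch is the largest interior local maximum of
the smoothed second derivative whose prominence exceeds 5% of the
within-pulse second-derivative range — on a smooth notchless decay the
second derivative is monotone through diastole, so no candidate exists and
absence is reported as a value, not an error. Deceleration/acceleration are
the extrema of the (unsmoothed) second derivative within ±50 ms of the
notch, a neighborhood that covers the notch complex at resting heart
rates. Pulses lacking a notch contribute no values to notch summaries; a
notch-presence fraction is emitted alongside.

## Cohort rules and the ND composite

Inclusion: prehospital shock index ≥ 0.62 (inclusive) or a priority-1/
unstable designation; head AIS > 1 (strict); abdominal and thoracic AIS
≤ 1; survival ≥ 15 min from admission; waveforms available. Every rejection
is attributed to all rules it fails; missing values reject with an explicit
`missing:<rule>` reason; the filter is row-order independent.

ND within 48 h fires on any of: (i) GCS decline ≥ 2 points relative to the
best prior score, suppressed when the decline falls within (0, 2 h] of an
analgo-sedation administration; (ii) new pupillary asymmetry > 2 mm, where
"new" means absent at the first recorded assessment; (iii) a later Marshall
score strictly exceeding an earlier one (radiographic ND); (iv) any
cerebral-edema intervention (ICP monitor, EVD, osmotherapy,
hyperventilation, craniotomy, decompressive craniectomy). A patient meeting
both clinical and radiographic criteria counts once (`nd_type="both"`).
Where the comparison baseline for the GCS rule was open — admission score
or best prior score — the running-best convention is the default and the
admission baseline is selectable (`gcs_baseline="admission"`); running-best
is the more sensitive reading and is monotone (adding a qualifying event
can never un-fire ND).

## Modeling

Logistic models are fitted by maximum likelihood (statsmodels Logit,
|Δloglik| < 1e-8 or 100 iterations). Perfect or quasi-complete separation
is detected (fit failure, |log-odds| > 15, or non-finite standard errors),
flagged on the result, and stabilized with a tiny ridge so a usable —
clearly marked — result is still returned. Stepwise selection forward-adds
the candidate with the smallest Wald chi-square p-value below
p_enter = 0.05 (ties: smaller p, then column order), then backward-drops
any included variable with p above p_remove = 0.10, until neither move
applies; 50 iterations without stabilizing aborts with a diagnostic. The
conventional 0.05/0.10 pair is a choice, not a transcription. Features are
z-scored on the training data before selection so Wald statistics are
comparable across heterogeneous units. The forward/backward scans use an
internal Newton/IRLS solver with the same convergence criterion (a test
pins its Wald p-values to statsmodels at 1e-12); final and reported fits go
through statsmodels.

Cross-validation is 10-fold, repeated 10 times, stratified on the outcome;
a repeat whose folds end up single-class is re-drawn with a perturbed seed
and logged. The *entire* procedure — standardization and stepwise
selection included — is re-run inside every training fold, so out-of-fold
probabilities never touch held-out rows; a fidelity mode that selects once
on all rows (`leak_free=False`) exists and is labeled optimistic. The AUROC
point estimate is the mean over repeats of the pooled out-of-fold AUROC.
The 95% CI is the 2.5/97.5 percentile of the 100 fold-level AUROCs — with
the CI method genuinely open, the percentile distribution was chosen
because it reflects fold-to-fold variability at small n without normality
assumptions; it is wide at desk scale, and that width is honest.
Sensitivity, specificity, PPV and NPV are reported at the Youden-index
optimum (J = sens + spec − 1, maximized over observed cut-points, ties to
the lowest threshold, predictive values at sample prevalence). AUROC uses
the tie-aware Mann–Whitney convention (ties count one half); the
"non-overlapping 95% CIs ⇒ significant" comparison rule is reproduced in
the report layout with the caveat that it is conservative.

**PPG15** — the per-subject out-of-fold ND probability from the PPG
15-minute model — enters the mortality model as a covariate alongside age,
Marshall score, and penetrating mechanism, adjusted for sex, MAP, heart
rate, respiratory rate, and GCS; odds ratios are exp(coef) with
exp(coef ± 1.96·se) CIs. Using out-of-fold rather than refit probabilities
keeps the mortality covariate leak-free too.

## Synthetic data: what it emulates, and what it does not

The simulators are controllable stand-ins with analytic ground truth, not
physiological models.

* **Inter-beat process**: respiratory (0.25 Hz) and slow (0.1 Hz)
  sinusoidal modulation plus white noise. Variance is allocated across the
  three components from their successive-difference gains
  (g = 4sin²(πfΔt) for a sinusoid, 2 for white noise) so RMSSD
  approximates its target, then the deviation series is rescaled so SDNN
  hits its target exactly. Defaults (mean RR 800 ms, SDNN 50 ms, RMSSD
  35 ms) sit in the normal adult range.
* **ECG**: one Gaussian bump per fiducial, placed relative to each R time
  (P at −160 ms, Q/S at ±0.375·QRS-width, T at +250 ms). Bump widths are
  chosen so cross-talk between neighbouring bumps stays ~1%, keeping the
  template amplitudes measurable to within 5%.
* **PPG**: a sin² upstroke to the systolic peak at `ppg_rise_frac` of the
  pulse period, a cos² decay back to baseline, and an explicit Gaussian
  notch dip (width 2.5% of the period) at `notch_delay_frac` with relative
  depth `notch_depth_frac` — so notch position and depth are parameters,
  not emergent properties, and detector error is measurable in samples.
* **Cohorts**: features are i.i.d. standard normal; the ND label is
  Bernoulli(expit(b₀ + Xβ)) with the intercept solved by quadrature so the
  marginal prevalence is exact in expectation, and the analytic AUROC of
  the generating score is computed by numerical integration and stored.
  A separate equal-variance binormal generator gives exact analytic AUROC
  (d′ = √2·Φ⁻¹(AUROC)) for CV-fidelity checks.
* **Waveform-level cohort** (`pipeline.simulate_waveform_cohort`): two
  latent axes — beat-to-beat variability (log-normal SDNN around 45 ms)
  and notch depth — drive both the waveforms and the ND risk (log-odds
  −1.2 and −1.0 per SD; decliners have depressed variability and blunted
  notches, the direction of autonomic impairment). Age, GCS and Marshall
  are weakly tied to the same risk so clinical models carry some, but
  less, signal; mortality is generated from ND status and age.

Not emulated: arrhythmia and ectopy (the quality mask is exercised with
injected artifacts instead), baseline wander and sensor-specific noise
spectra beyond additive white noise and the three artifact types,
multi-lead ECG, SpO₂/respiratory content of the PPG, and any real
correlation structure between clinical covariates. Passing tests therefore
demonstrate correctness of the measurement and modeling chain under known
ground truth — not clinical performance on real recordings.

## Problem sizes and determinism

Default study-scale parameters: 240 Hz, 15-minute windows, 10×10 CV. The
bundled examples and the acceptance script run cohorts of 50–120 patients
with 15-minute (or 5-minute, for single-capability examples) windows —
sizes chosen so a complete run stays desk-scale on one CPU while keeping
≥ 10 events for stratified 10-fold CV. Every stochastic component takes an
explicit seed (numpy `default_rng`); pipelines derive all internal seeds
from one root seed, and repeated runs are bit-for-bit reproducible.

## Known limitations

* The R-peak detector is tuned for resuscitation-grade single-lead ECG at
  240 Hz; it is not an arrhythmia-robust clinical detector.
* Sample entropy is O(n²); fine for 15–60 minute windows (≤ ~5000 beats),
  not for day-long recordings.
* At n ≲ 50 patients the fold-level percentile CI is very wide and the
  mortality model frequently hits separation (flagged, ridge-stabilized);
  conclusions at that scale are illustrative only.
* The waveform-level cohort generator's latent-to-outcome coupling is a
  modeling convenience; extracted-feature AUROCs sit below the latent
  ceiling by construction (measurement noise), and no claim is made that
  they match any particular clinical population.
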