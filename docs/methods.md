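# Methods

This note documents the models, conventions and numerical choices behind
`blinkreflex`, in the spirit of a lab's internal methods appendix.  All
numbers quoted here are either package defaults (stated as such) or values
the test suite and `scripts/acceptance.py` recompute at run time.

## Measurement model

A blink-reflex study records surface EMG from both orbicularis oculi (OOc)
muscles.  Supraorbital-nerve stimulation elicits the trigeminal blink
reflex (TBR): R1 (early, ipsilateral only), R2 (late, ipsilateral) and R2c
(late, contralateral).  Median-nerve stimulation elicits the somatosensory
blink reflex (SBR), recorded ipsilaterally; because it habituates quickly,
only the first trial is measured.  Latency is time from the stimulus
artifact to response onset; R1 size is peak-to-peak amplitude (µV); R2,
R2c and SBR sizes are rectified areas (µV·ms).  Absent responses carry no
latency and an area of 0.  TBR measures are means over 5 trials per
stimulation side; a component is scored present when present in at least
half of its trials (latencies averaged over present trials, areas over all
trials with absent trials contributing 0).

### Onset detection

The acquisition bandwidth (20–2000 Hz) is assumed already applied.  The
detector (a) subtracts the mean of a 20 ms pre-stimulus baseline (1 ms of
stimulus artifact blanked), (b) rectifies and smooths with a 2 ms trailing
moving average, (c) detects a burst where the smoothed signal exceeds
`baseline mean + 4·SD` for at least 3 ms inside the component search
window, and (d) refines the onset by walking back along a 1 ms *centred*
moving average to the last point at baseline level (`+2·SD`), at most 3 ms
and with a half-window compensation so steep onsets are unbiased.  The SD
used for both thresholds is the raw baseline SD scaled analytically for
the smoother (`σ·sqrt(1−2/π)/sqrt(W)`); estimating the SD directly on the
smoothed baseline proved unstable (too few effective samples), which
occasionally collapsed the threshold and produced false onsets.

Default search windows (ms post-stimulus): R1 8–18, R2/R2c 25–87, SBR
35–110.  They bracket the normative latency limits (12.8/38/40/66.7 ms)
with margin for pathological delay.  The area of a detected response is
integrated (trapezoid) from the detected onset to the end of the
component window; an absent response is entered as 0 rather than as a
noise integral.  On synthetic traces the detector recovers 5-trial mean
TBR latencies within ±1 ms and areas within 5%; single-trial SBR onsets
carry a small (<1%) outlier rate when a chance noise plateau fuses with
the burst onset — one reason the clinical protocol averages the TBR over
trials.

## Normative limits

Latency limits are fixed published laboratory values (R1 12.8 ms, R2
38 ms, R2c 40 ms, SBR 66.7 ms; inter-side differences >1.5 ms R1, >5 ms
R2, >8 ms between R2 and R2c of the same stimulus; these are carried
unchanged rather than re-derived, with an opt-in to re-derive).  Size
limits are mean ± 2·SD over a healthy cohort, computed per measure on
(a) the per-subject two-side mean and (b) the per-subject absolute
inter-side difference; sample SD (n−1) is used.  A reference healthy
summary (n = 12) ships with the package; the derived inter-side cut-offs
are 0.384 (R2c/R2 ratio), 1780.2 µV·ms (R2 area), 91.2 µV (R1), 1245.8
µV·ms (SBR), 27.6 (BRER index) and 9.4 (BRIP), with a BRIP lower cut-off
of 84.7%.

## Latency classification (AbLat)

Any absolute or inter-side latency abnormality of the TBR marks a patient
AbLat.  Patterns follow the Aramideh scheme — afferent (R2 and R2c
abnormal to stimulation of one side), efferent (the responses recorded
from one OOc abnormal to stimulation of either side), commissural (R2c
abnormal with all R2 normal), and mixed (combinations, or delay confined
to R1).  Inter-side flags without an absolute delay are attributed to the
relatively later component instance before the pattern rules run.  When
no pure pattern fires, abnormality confined to R2 maps to efferent and to
R2c to commissural; anything else (R1-only or multi-component) maps to
mixed.  The SBR is screened separately (delay beyond 66.7 ms, or
consistent unilateral absence); an SBR-only abnormality marks the patient
AbLat but carries no trigeminal pattern (`pattern="none"`), since the
Aramideh scheme describes the TBR — bilateral SBR absence alone is not
abnormal (it occurs in healthy fast habituators).

## Excitability classification (AbEx)

Two size measures are computed per subject: the R2c/R2 area ratio per
stimulation side (undefined, with a QC note, when the R2 area is 0), and
the side-averaged R2 area per muscle (ipsilateral R2 averaged with the
R2c evoked from the other side).  A muscle is implicated by the ratio
when the ratio to stimulation of the *opposite* side exceeds its
absolute cut-off (the crossed response is recorded contralaterally), or
when the ratio inter-side difference exceeds its cut-off with that
muscle's crossed response relatively larger; and by area via the absolute
or inter-side criterion.  AbEx requires both measures to implicate the
same side.  Supporting evidence flags (R1 amplitude, SBR area, BRER
index, BRIP) are set when their inter-side difference exceeds its
cut-off and the larger value — for BRIP, the *more disinhibited* side —
coincides with the enhanced side.

## BRER and BRIP

BRER: paired supraorbital stimuli at 100–600 ms inter-stimulus intervals;
recovery per interval is the test-R2 area as % of the conditioning-R2
area, computed per pair and averaged over 3 trials (pairs with an absent
conditioning response are excluded with a warning).  The BRER index is
the sum of the six percentages; recovery above 30% at ≤300 ms is the
abnormality criterion.  BRIP: R2 area in prepulse trials as % of the
mean unconditioned R2 area (`pct_of_control`, trial areas averaged before
the percentage, per the "mean control area" definition).  The BRIP value
carried in normative statistics is the percentage *inhibition*,
100 − pct_of_control: healthy prepulse inhibition is strong (≈94%), and
values below the 84.7% lower cut-off indicate reduced inhibition.  This
convention is the only one that makes the reference statistics coherent
(healthy 94.1 ± 4.7 with *lower* values abnormal, and reduced inhibition
in excitability-enhanced patients).

## Diagnostics

The gold standard for conduction-type abnormality is a ponto-medullary
MRI lesion (pons or medulla involved; midbrain alone is negative, since
the trigemino-facial circuit runs ponto-medullary).  Sensitivity and
specificity are TP/(TP+FN) and TN/(TN+FP); the 2×2 association uses the
uncorrected Pearson chi-square (1 df) — Yates' correction is available
but off by default.  A 20-patient reference cohort (lesion-site flags and
latency classification labels) ships as `data/reference_cohort.csv` and
yields sensitivity 70%, specificity 90% and χ² = 7.5 (p ≈ 0.006).

## Synthetic cohort generator

The generator produces measurement tables (and optionally waveform-level
trials) with the statistical structure the analysis assumes.  It is the
package's test bed: passing tests demonstrate that the pipeline recovers
known ground truth under this model, not that the model captures every
feature of clinical EMG (no habituation beyond the first-trial SBR rule,
no artifacts, no non-Gaussian baseline noise, no age structure).

* **Size measures** are lognormal at the subject level (positive,
  right-skewed), moment-matched to the reference means/SDs: R2c/R2 ratio
  0.815 ± 0.093, R2 area 4707.1 ± 2864.3 µV·ms, R1 165.1 ± 79.1 µV, SBR
  1716.0 ± 1061.1 µV·ms, BRIP pct-of-control 5.9 ± 4.7%.  Right/left
  splits are calibrated so the mean |Δ| matches the reference inter-side
  rows (0.170, 546.8, 31.8, 424.8, 3.4); R1/SBR use multiplicative
  splits, BRIP an additive one.  Measured Δs run ≈10% above these latent
  targets because trial-to-trial measurement noise (10% CV, 5-trial
  means) adds variance, as it does in real recordings.
* **The four late-response areas** come from a latent multiplicative
  model `A2(s) = C·u_s·g_s`, `A2c(s) = C·u_s·ρ·g_opp(s)` with per-muscle
  gain g, per-stimulation-side input strength u and crossed attenuation
  ρ; ratio and muscle-area asymmetries therefore co-vary coherently, and
  the per-subject two-side means of ratio and area are pinned exactly to
  the drawn lognormal targets.  An earlier variant that drew ratio and
  area sides independently and solved a linear system needed rejection
  sampling, which biased the ratio mean low; the latent model removes
  that bias by construction.
* **Latencies** are Gaussian: R1 10.5 ± 0.8 ms, R2 33.0 ± 2.0 ms, R2c =
  R2 + (1.0 ± 0.8) ms, SBR 55.6 ± 4.0 ms, with inter-side Δ SDs
  0.4/1.6/–/2.0 ms and trial jitter 0.25/1.0/1.0/1.5 ms.  These sit 2.5–3
  SD below the fixed limits, giving a realistic small healthy
  false-positive rate (≈4% AbLat per subject across the eight rules).
  Trial latencies are clipped to the component search windows.
* **BRER** curves are logistic in log-interval,
  `r(t) = 200·expit((ln t − μ)/0.2621)` with subject shift SD 0.1158 and
  side shift SD 0.0579 on μ = 6.7184, 3 trials of 14% CV noise per
  interval.  The constants were calibrated numerically (root-finding on
  simulated cohorts) so healthy cohorts reproduce recovery ≈4.4% at
  300 ms, ≈48% at 600 ms, and a BRER index of ≈92 ± 34 with inter-side
  Δ ≈ 13.
* **Scenarios.**  A conduction lesion adds a 10 ms delay (or absence) to
  the component instances of a chosen Aramideh pattern.  An excitability
  enhancement multiplies one muscle's R1 amplitude, R2/R2c areas and SBR
  area by a gain (default 2.0), shifts that side's BRER curve left by
  0.405 ln-units (≈ a 1.5× shorter effective interval) and moves BRIP
  25 percentage points toward disinhibition.  The default 20-patient mix
  mirrors the study design: 8 conduction lesions (4 afferent, 1
  efferent, 1 commissural, 2 mixed), 9 enhancements, 2 overlapping, 5
  unaffected.
* **Determinism.**  One spawned RNG substream per subject; healthy draws
  precede scenario transforms so the stream does not depend on the
  scenario, and flipping all scenario sides flips all induced labels.

Parameter recovery: over 100 seeded 20-patient cohorts (1500 scenario
subjects), injected patterns/sides are recovered in ≈92%.  The residual
errors are honest tails of the healthy model: enhancement subjects in the
low-area tail (~8%) fail the area inter-side criterion at gain 2, and a
few percent of lesion subjects acquire extra absolute delays from the
healthy latency tails and escalate to `mixed`.

### Waveform rendering

`render_waveforms` inverts the feature extractor for single-stimulus
trials (TBR, SBR): each present component becomes a Tukey-windowed cosine
burst (1 ms ramps; 250 Hz carrier for R1, 120 Hz otherwise; durations
6/35/35/40 ms) on Gaussian noise (default SD 1.5 µV), scaled exactly to
the target amplitude (R1) or to the target area after subtracting the
expected rectified-noise integral between burst end and window end.
Paired-pulse (BRER) and prepulse (BRIP) conditions are generated at the
measures level only.  Targets whose burst cannot be realised (outside the
window, or area below the noise floor) raise a generation error.

## Known limitations

* Fixed latency limits are not age/sex-stratified and the mean±2SD rule
  assumes approximate normality of the healthy measures.
* A delayed R1 beyond ~15 ms leaves the R1 search window and is measured
  absent at the waveform level (equally abnormal, but "delayed" and
  "absent" are then conflated); measurement-table inputs are unaffected.
* The AbEx logic cannot distinguish unilateral enhancement from
  contralateral suppression; side labels mean "relatively larger".
* The generator's BRIP and BRER models are univariate per side; they do
  not model the common trigemino-facial interneuron pool shared with the
  TBR beyond the enhancement scenario's coherent shifts.
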