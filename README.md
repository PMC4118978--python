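# blinkreflex

Analysis pipeline for blink-reflex excitability studies in clinical
neurophysiology.  From bilateral orbicularis-oculi (OOc) EMG responses it
derives normative cut-offs, classifies each patient as latency-abnormal
(**AbLat**, with an Aramideh pattern: afferent / efferent / commissural /
mixed) and/or excitability-abnormal (**AbEx**, a unilateral enhancement of
response size), computes the paired-pulse excitability recovery curve
(**BRER**) and prepulse inhibition (**BRIP**), and evaluates the
classification against a brainstem-MRI gold standard.  A calibrated
synthetic-cohort generator makes every stage testable without any
recordings.

## The measurements and the model

Supraorbital-nerve stimulation evokes the trigeminal blink reflex: R1
(early, ipsilateral), R2 (late, ipsilateral) and R2c (late, contralateral);
median-nerve stimulation evokes the somatosensory blink reflex (SBR).
Latency is measured from stimulus artifact to onset; R1 size is
peak-to-peak amplitude, late responses are rectified areas (µV·ms); TBR
values are 5-trial means and absent responses are entered with area 0.

The classification rests on two ideas:

* **Latency** against fixed normative limits (R1 12.8 ms, R2 38 ms, R2c
  40 ms, SBR 66.7 ms; inter-side Δ > 1.5 / 5 ms, R2–R2c Δ > 8 ms) marks
  conduction impairment in the ponto-medullary reflex arc (AbLat).
* **Response size** in a healthy subject satisfies R2c/R2 < 1.  The
  R2c/R2 area ratio per stimulation side and the side-averaged R2 area
  per muscle are compared against healthy mean + 2·SD cut-offs (absolute
  and inter-side); when both measures implicate the *same* muscle the
  patient is AbEx on that side — interpreted as abnormal excitability
  from impaired descending control rather than a conduction lesion.
  Asymmetries in R1 amplitude, SBR area, BRER index (the sum of the six
  recovery percentages at 100–600 ms) and BRIP (percentage inhibition of
  the R2 by a weak somatosensory prepulse 100 ms earlier) serve as
  supporting evidence on the same side.

See `docs/methods.md` for the full conventions, generative model and
numerical choices.

## Worked example

```bash
blinkreflex simulate --seed 7 --out demo                 # synthetic cohort
blinkreflex classify --cohort demo --out demo/classification.csv
blinkreflex evaluate --classification demo/classification.csv \
                     --gold demo/gold.csv --out demo/metrics.json
```

The simulated cohort contains 12 healthy controls and 20 patients with
the study-like scenario mix (8 conduction lesions, 9 unilateral
excitability enhancements, 2 overlapping).  The classification table
begins:

```
subject_id  is_ablat     pattern      side  is_abex enhanced_side
     pt001      True    afferent     right    False          none
     pt002      True    afferent      left    False          none
     ...
     pt005      True    efferent      left     True          left
     pt006      True commissural     right    False          none
     pt007      True       mixed bilateral     True         right
     pt009     False        none      none     True          left
```

and `metrics.json` reports the cohort summary and diagnostic metrics of
AbLat against the ponto-medullary lesion flags:

```json
{
  "n_ablat": 8,
  "n_abex": 9,
  "patterns": {"afferent": 4, "mixed": 2, "efferent": 1, "commissural": 1},
  "ablat_vs_pontomedullary": {
    "sensitivity_pct": 100.0,
    "specificity_pct": 100.0,
    "chi_square": {"statistic": 20.0, "p_value": 7.7e-06}
  }
}
```

Every injected scenario was recovered here (sensitivity/specificity 100%
on this seed); on the packaged 20-patient clinical reference cohort
(`blinkreflex.load_reference_cohort()`), where biology is messier, the
same metrics evaluate to sensitivity 70%, specificity 90% and an
uncorrected Pearson χ² of 7.5 (p ≈ 0.006).

The same results are available programmatically:

```python
import blinkreflex as br
from blinkreflex.cohort import GeneratorConfig, generate_cohort

cohort = generate_cohort(GeneratorConfig(seed=7))
limits = br.default_limits()          # packaged normative limits
table = br.classify_cohort(cohort.subjects, limits)
```

`blinkreflex simulate --waveform` additionally renders per-trial EMG
traces (CSV + JSON sidecars) and `blinkreflex extract` measures them back
into the tabular form — the round trip recovers latencies within ±1 ms
and areas within 5%.

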