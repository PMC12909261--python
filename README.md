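# gliotrack

Longitudinal volumetric monitoring for low-grade glioma (LGG): tumor volumes
and Dice agreement from binary segmentation masks, online change-point
detection of growth onsets in dated volume series, and cohort-level lead-time
and error-rate accounting.

Low-grade (WHO grade 2) diffuse gliomas are monitored for years by serial
MRI. Visual comparison of scans is subjective and routinely misses slow
growth; volumetric analysis of the segmented FLAIR lesion, paired with a
statistical change detector, can flag progression much earlier and with a
uniform standard across patients. `gliotrack` implements that analysis as a
library for imaging scientists and neuro-oncology researchers: it consumes
per-patient volume tables (or NIfTI masks from which it computes volumes)
and produces per-patient growth calls, lead times against clinical reference
dates, and cohort summaries. Because clinical imaging of this kind is rarely
shareable, a first-class synthetic-cohort generator reproduces the
structure of such studies so every stage is testable end to end.

## The method

For one patient with dated tumor volumes V_1, …, V_n (mm³):

1. **Post-operative baseline.** The baseline is the first minimum of the
   series after resection — the smallest index *i* with V_i ≤ V_{i+1} —
   excluding earlier scans, whose FLAIR signal reflects resolving surgical
   change rather than tumor. V_b denotes the baseline volume.
2. **Normalization and penalty.** Detection runs on y_t = V_t / V_b with a
   per-patient change-point penalty β = 500 / V_b, i.e. 5% for a 10,000 mm³
   baseline (500 mm³ is 5% of the median baseline volume, so β is
   dimensionless and the pipeline is invariant under a change of volume
   units).
3. **Penalized change-point detection.** The series is partitioned to
   minimize Σ_segments C(seg) + β·(number of change points), where the cost
   of a segment of length L is the root-mean-square-level statistic
   C = L·log(mean(y²)). A change point — the first sample of a new segment —
   is reported only if it *strictly* lowers the penalized objective; the
   initial segment and each segment between change points must contain at
   least 2 samples. The solver is exact (dynamic programming) and is
   verified against an exhaustive enumeration oracle.
4. **Online detection.** To replicate clinical accrual, the detector is
   rerun on each growing prefix y_1..k (k = 4, …, n). The alarm fires at the
   first prefix whose partition contains an *upward* level shift; the first
   such change point is the detected growth onset, mapped back to an actual
   scan date.
5. **Lead time and cohort accounting.** Lead = (clinical reference date −
   onset date) in 30.4375-day months; positive means the detector was
   earlier. Cohorts with progression / clinically-stable / negative-control
   groups and two measurement arms (raw AI vs physician-reviewed volumes)
   are summarized by median and IQR lead per group and arm, with per-patient
   false-positive and false-negative rates.

Mask utilities compute volume = (voxel count) × (voxel volume) and the
Dice–Sørensen overlap D = 2|A∩B| / (|A|+|B|) between segmentations of the
same grid; agreement reports average D over reviewer pairs and express
variability as 1 − mean D.

## Worked example

```python
from datetime import date, timedelta
from gliotrack import Scan, VolumeSeries, lead_months, run_patient

volumes_mm3 = [28_000, 14_500, 10_000, 10_300, 9_900, 10_200,
               12_500, 14_000, 16_500, 19_000]
start = date(2012, 1, 1)
series = VolumeSeries("patient-01", [
    Scan(start + timedelta(days=120 * i), v, "reviewed")
    for i, v in enumerate(volumes_mm3)
])
record = run_patient(series)
print(record.baseline.index, record.onset_date, record.trigger_date)
print(f"{lead_months(record.onset_date, date(2015, 6, 1)):+.1f}")
```

prints

```
3 2013-12-21 2013-12-21
+17.3
```

The post-surgical volume decays to its nadir at scan 3 (10,000 mm³), which
becomes the baseline; the plateau that follows is within noise, and the
climb that begins at scan 7 (12,500 mm³, +25% over baseline) is the first
point at which the penalized detector finds a significant upward shift —
onset and trigger coincide because the alarm fires the moment that scan
arrives. Against a clinical progression date of 2015-06-01, the detector is
17.3 months early. The scripts in `examples/` walk through the other
capabilities (offline vs online detection, full synthetic cohorts, Dice
agreement) and print the numbers they compute.

There is also a thin CLI for running the pipeline from a shell:

```bash
gliotrack simulate --n-progression 34 --n-stable 22 --n-control 7 --seed 1 --out data/
gliotrack summarize --volumes data/volumes.csv --labels data/labels.csv --out results/
```

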