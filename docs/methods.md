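# Methods

## Problem setting

Low-grade gliomas are monitored by serial FLAIR MRI over many years. The
quantity tracked here is the segmented lesion volume V_t (mm³) at each scan
date. The package answers, per patient: *at which scan does the volume
series first show a statistically significant sustained increase?* — and,
per cohort: *how much earlier is that than the clinical reference date, and
at what false-positive / false-negative cost?*

## Change-point model

### Cost and penalty

A partition of the series into contiguous segments is scored as

```
J = Σ_segments C(i..j) + β · (#change points)
```

with two segment statistics:

* `rms` (default): `C = L · log(max(ε, mean(x²)))` for a segment of length
  `L` — the Gaussian log-likelihood cost for a change of scale about zero.
  This is the standard penalized formulation for detecting shifts in the
  root-mean-square level of a signal, the natural statistic for a positive
  quantity (volume) whose meaningful changes are multiplicative.
* `mean`: the sum of squared residuals about the segment mean, for users who
  prefer an additive-shift model.

`ε = 1e−12` guards the logarithm for all-zero segments; volumes are positive
in practice, so the guard is never informative there.

The penalty β is a *minimum improvement*: a change point enters the
partition only if it strictly lowers J. Cost ties are resolved toward fewer
change points, then toward the lexicographically earliest change-point
vector, so results are deterministic. A change point is indexed (1-based) by
the first sample of the new segment.

Under the `rms` cost, multiplying the series by c > 0 shifts every segment
cost by `L·log(c²)` and therefore shifts the cost of *every* partition of an
n-sample series by the same `n·log(c²)`: cost differences, and hence the
optimal partition at fixed β, are scale-free. This is load-bearing for the
unit-invariance of the pipeline (below).

### Minimum spacing

`min_distance` (default 2) is the minimum number of samples in the initial
segment and in any segment between two change points. The final segment is
exempt: in online use it is still accruing samples, and an alarm may
legitimately be raised at the newest scan. (Constraining the final segment
as well would forbid exactly the clinically interesting call — "the scan
that arrived today is the change"; it would also delay every online
detection by one scan.)

### Solver and oracle

Series here have 4–30 points, so the solver is a plain O(n²) dynamic program
over "last closed segment end" states, with no pruning. `oracle_detect`
enumerates every admissible change-point vector (n ≤ 16) and applies the
identical tie-breaking; the test suite and the acceptance script check the
two agree exactly — indices and penalized cost — across statistics,
penalties β ∈ {0.01, 0.1, 1, 10} and spacings 1–3 on hundreds of random
series. Because both routes share only the cost definition, this is a
genuine cross-check of the dynamic program, not of itself.

### Online wrapper

`detect_online` reruns the offline solver on each prefix `x[1..k]`,
k = `start_prefix`, …, n, and fires at the first prefix whose partition
contains a change point. `start_prefix` defaults to 4, matching a
≥ 4-scans-per-patient inclusion rule. Two properties deserve note:

* **No nesting across prefixes.** Offline cleanliness of the full series
  does *not* imply the online detector stays quiet: a transient dip can be a
  large fraction of a short prefix (and get split out) yet be diluted to
  insignificance in the full series. The per-prefix reruns are deliberately
  unadjusted for multiplicity — each prefix is scored as if it were the
  complete record, which is exactly the situation on the date of that scan.
* **Growth direction.** For growth calls the monitoring layer passes
  `require_increase=True`: the alarm fires only on the first change point
  whose new segment has a *higher* RMS level than the segment before it.
  A downward shift is shrinkage (or resolving post-surgical change), not
  progression; without this filter, negative noise excursions at the newest
  scan are the dominant false-alarm mode.

## Per-patient pipeline

1. **Baseline**: smallest i with V_i ≤ V_{i+1} (first local minimum; the
   first scan counts as post-operative). A strictly decreasing series has no
   post-nadir observation: the last scan is taken as baseline and the
   patient ends as "insufficient data" rather than an error.
2. **Threshold**: β = `base_constant` / V_b applied to y_t = V_t / V_b. The
   default constant 500 mm³ is 5% of a 10,000 mm³ median baseline — i.e. the
   constant is itself cohort-derived
   (`threshold_constant_from_cohort(baselines, fraction=0.05)` re-derives it
   for any cohort or unit system). Because the constant carries volume
   units, rescaling all volumes rescales it proportionally, β is unchanged,
   and — via the scale-freeness of the rms cost — every detection is
   invariant under a change of units. A zero baseline volume is a hard
   error (the threshold is undefined).
3. **Detection**: online, on the baseline-truncated normalized series, with
   `min_distance=2`, `start_prefix=4`. Fewer than 4 post-baseline scans →
   undetected with an `insufficient_data` flag. Detected indices map back to
   actual scan dates; nothing is interpolated.
4. **Lead time**: (reference − onset) in days / 30.4375 (mean Gregorian
   month; the conversion must be fixed because reference intervals span
   years). Positive = detector earlier than the clinic.

Cohort accounting follows the study design it emulates: lead medians and
IQRs (linear-interpolation quantiles) per (group, arm) over detected
patients; the false-positive denominator pools negative controls with
stable members of the clinically-stable group; the false-negative
denominator pools the progression group with clinically-stable patients
adjudicated as progressing by the reviewed arm. All counts derive from the
supplied labels and records — nothing is hard-coded.

## Synthetic cohorts

The generator reproduces the *structure* of a longitudinal LGG surveillance
study; all outputs are pure functions of (parameters, seed).

Noiseless trajectory (months t since the first post-operative scan):

```
m(t) = max(v_plateau, v_preop · exp(−decay_rate · t))          before onset
m(t) = max(decay(t), growth(t))                                 after onset
```

with growth either exponential in volume (`v_plateau · 2^((t−onset)/T_d)`,
doubling time T_d = 24 months by default — slow, typical of untreated LGG)
or linear in equivalent-sphere diameter (4 mm/year by default, the classic
LGG growth figure). Observed volumes are m(t) times lognormal mean-1 noise.

Defaults, chosen once as study-like conditions and documented here rather
than tuned:

| parameter | default | rationale |
|---|---|---|
| plateau volume | lognormal, median 10,000 mm³, σ_log 0.5 | consistent with a ~10 mL median baseline and the 1–100 mL range of LGG FLAIR lesions |
| post-op elevation | U(1.5, 3) × plateau | resolving surgical FLAIR change |
| decay rate | U(0.08, 0.2) /month | nadir reached ~2–14 months post-op |
| scans per patient | U{10, …, 16} | ~10 scans/patient in multi-year surveillance |
| scan interval | 4 ± 1 months (uniform jitter) | routine LGG follow-up |
| growth onset | U(12, T−20) months | every progressor has ≥ ~5 post-onset scans; with a 24-month doubling time, less follow-up would make growth undetectable by any method |
| clinical reporting delay | U(12, 30) months after onset, capped at last scan | visual reading lags volumetry by one-to-two years |
| reviewed-arm CV | 6.9% | intra-user segmentation variability |
| raw-AI-arm CV | 12.5% total | inter-user variability; generated as extra contour noise *on top of* the reviewed volumes, keeping the arms correlated |

Negative controls (never resected) have no decay phase. Runs differing only
in noise CV consume identical underlying normal draws, so matched-seed
noise-degradation comparisons are paired.

Mask generation digitizes ellipsoids by the center-inclusion rule on an
odd-extent grid (a voxel center always sits at the ellipsoid center), and
`perturb_mask_to_dice` emulates an independent reviewer by balanced random
boundary flips (adds ≈ removes, volume held within ±10%) until the Dice
score with the original reaches a target — inter-reader disagreement is
boundary uncertainty, not systematic volume bias. Unreachable targets (e.g.
Dice 0.5 from a single-voxel mask under balanced flips) raise with a
diagnostic.

### What the generator does not emulate

Real longitudinal series have correlated measurement errors (same scanner,
same rater), missed visits and variable-length gaps beyond uniform jitter,
pseudo-progression and treatment effects, and segmentation failures that are
not multiplicative noise. Passing recovery tests on this generator therefore
demonstrates the *pipeline logic* — baseline anchoring, thresholding, online
semantics, date mapping, accounting — under controlled conditions, not
clinical performance.

## Known limitations

* **Baseline is an order statistic.** Anchoring at the first post-operative
  minimum preferentially selects negative noise excursions; at measurement
  CVs approaching the inter-user level, a −2σ baseline makes an ordinary
  plateau read as a 15–25% sustained elevation and the per-patient false
  alarm rate grows quickly (the acceptance script reports the measured
  rates). At CVs of a few percent — what careful physician-reviewed volumes
  plausibly achieve, since boundary disagreements largely cancel in volume —
  false alarms essentially vanish. Dice variability is an upper bound on,
  not an estimate of, longitudinal volume CV.
* **Detection delay vs onset localization.** With slow exponential growth
  (≈12% per 4-month interval at a 24-month doubling time) the first
  post-onset scan is inside measurement noise; the alarm fires once growth
  accumulates past the penalty, typically 1.5–2 scan intervals after true
  onset, and the online convention then dates the onset at (or near) the
  newest scan. Detected onsets are therefore systematically late relative to
  the latent onset — a property of the online protocol itself, visible at
  every noise level.
* **No multiplicity control.** Rerunning detection per prefix inflates the
  per-patient alarm probability relative to a single offline pass; this is
  intentional (it mirrors clinical accrual) but should be remembered when
  interpreting per-patient false-positive rates.
* **Grid-identity precondition.** Dice and mask comparisons require
  identical shape and spacing; no registration or resampling is performed,
  because the intended comparisons are between contours drawn on the same
  image grid. Empty-vs-empty Dice is defined as 1 (perfect agreement on an
  empty finding).
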