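"""Per-patient growth monitoring and cohort-level accounting.

The pipeline for one patient:

1. assemble the dated tumor-volume series for one measurement arm
   (``raw_ai`` — unreviewed AI segmentations — or ``reviewed`` —
   physician-approved contours);
2. select the post-operative baseline, the first minimum of the volume
   series after resection, and discard earlier scans (early FLAIR elevation
   reflects resolving surgical change, not tumor);
3. normalize by the baseline volume V_b and run online change-point
   detection with a per-patient penalty of ``500 / V_b`` (i.e. 5% of a
   10,000 mm^3 baseline), minimum segment length 2;
4. map detected indices back to scan dates and, given a clinical reference
   date, compute the signed lead time in months.

Cohort accounting mirrors the study design: patients belong to a
``clinical_progression``, ``clinically_stable`` or ``negative_control``
group.  Lead times are summarized per (group, arm) by median and
interquartile range.  The false-positive denominator pools negative controls
with stable members of the clinically-stable group; the false-negative
denominator pools the clinical-progression group with clinically-stable
patients adjudicated as progressing by the reviewed arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .changepoint import ChangePointConfig, OnlineDetection, detect_online

logger = logging.getLogger(__name__)

__all__ = [
    "DAYS_PER_MONTH",
    "ARMS",
    "GROUPS",
    "Scan",
    "VolumeSeries",
    "BaselineSelection",
    "DetectionRecord",
    "ClinicalLabel",
    "CohortSummary",
    "ZeroBaselineError",
    "select_baseline",
    "patient_threshold",
    "threshold_constant_from_cohort",
    "run_patient",
    "run_cohort",
    "lead_months",
    "summarize_cohort",
    "read_volumes",
    "read_labels",
    "series_from_frame",
    "score_against_truth",
]

#: mean Gregorian month, days
DAYS_PER_MONTH = 30.4375

ARMS = ("raw_ai", "reviewed")
GROUPS = ("clinical_progression", "clinically_stable", "negative_control")

#: per-patient penalty numerator: 5% of the cohort's rounded median baseline
#: volume (10,000 mm^3), applied to the baseline-normalized series
DEFAULT_THRESHOLD_CONSTANT = 500.0

#: online detection starts once this many post-baseline scans are available
DEFAULT_START_PREFIX = 4


class ZeroBaselineError(ValueError):
    """Raised when a patient's baseline volume is zero (threshold undefined)."""


@dataclass(frozen=True)
class Scan:
    date: date
    volume: float
    source: str = "raw_ai"


@dataclass
class VolumeSeries:
    """One patient's dated tumor-volume measurements from a single arm."""

    patient_id: str
    scans: list[Scan]

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError(f"{self.patient_id}: series must contain at least one scan")
        dates = [s.date for s in self.scans]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"{self.patient_id}: scan dates must be strictly increasing")
        if any(s.volume < 0 for s in self.scans):
            raise ValueError(f"{self.patient_id}: volumes must be >= 0")
        sources = {s.source for s in self.scans}
        if len(sources) > 1:
            raise ValueError(
                f"{self.patient_id}: a series mixes sources {sorted(sources)}; analyze arms separately"
            )

    @property
    def source(self) -> str:
        return self.scans[0].source

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.volume for s in self.scans], dtype=float)

    @property
    def dates(self) -> list[date]:
        return [s.date for s in self.scans]


@dataclass
class BaselineSelection:
    """Post-operative baseline: 1-based scan index, its volume V_b, and the
    volume series truncated to start at the baseline scan."""

    index: int
    baseline_volume: float
    truncated_series: np.ndarray
    monotone_decreasing: bool = False


@dataclass
class DetectionRecord:
    """Per-patient growth call for one measurement arm."""

    patient_id: str
    arm: str
    growth_detected: bool
    baseline: BaselineSelection
    trigger_date: date | None = None
    onset_date: date | None = None
    trigger_index: int | None = None  # 1-based index into the full scan list
    onset_index: int | None = None
    insufficient_data: bool = False
    lead_months: float | None = None
    online: OnlineDetection | None = None


@dataclass(frozen=True)
class ClinicalLabel:
    """Group membership and the clinical reference date: the documented
    progression date for progressors, the last-MRI date otherwise."""

    patient_id: str
    group: str
    reference_date: date

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.patient_id}: unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class CohortSummary:
    """Cohort metrics per (group, arm) plus per-arm FP/FN rates.

    ``groups`` rows: group, arm, n, n_detected, median_lead, lower_iqr,
    upper_iqr (lead statistics over detected patients only).
    ``rates`` rows: arm, fp_n, fp_total, fp_rate, fn_n, fn_total, fn_rate
    (fractions in [0, 1]).
    """

    groups: pd.DataFrame
    rates: pd.DataFrame
    leads: dict[tuple[str, str], list[float]] = field(default_factory=dict)


def select_baseline(series: VolumeSeries | Sequence[float] | np.ndarray) -> BaselineSelection:
    """First post-operative minimum of the volume series.

    Returns the smallest index i with ``volume[i] <= volume[i+1]`` (the first
    local minimum, counting the first scan as post-operative).  A strictly
    decreasing series — still-resolving surgical change with no post-nadir
    observation — defaults to the last scan and is flagged.
    """
    v = series.volumes if isinstance(series, VolumeSeries) else np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("series must contain at least one scan")
    for i in range(v.size - 1):
        if v[i] <= v[i + 1]:
            return BaselineSelection(index=i + 1, baseline_volume=float(v[i]), truncated_series=v[i:])
    return BaselineSelection(
        index=v.size,
        baseline_volume=float(v[-1]),
        truncated_series=v[-1:],
        monotone_decreasing=True,
    )


def threshold_constant_from_cohort(
    baseline_volumes: Sequence[float] | np.ndarray,
    fraction: float = 0.05,
    round_to: float | None = None,
) -> float:
    """Penalty numerator derived from a cohort: ``fraction`` of the median
    post-operative baseline volume.

    The default per-patient penalty constant (500) is exactly 5% of a
    10,000 mm^3 median baseline; this helper re-derives the constant for an
    arbitrary cohort (or an arbitrary volume unit — the constant carries the
    same unit as the volumes, which is what makes the whole pipeline
    invariant under a change of units).  ``round_to`` optionally rounds the
    median first (the study rounds its median to the nearest 1,000 mm^3).
    """
    if not 0 < fraction:
        raise ValueError("fraction must be > 0")
    v = np.asarray(baseline_volumes, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("need at least one positive baseline volume")
    med = float(np.median(v))
    if round_to is not None:
        med = round(med / round_to) * round_to
    return fraction * med


def patient_threshold(
    baseline: BaselineSelection | float,
    base_constant: float = DEFAULT_THRESHOLD_CONSTANT,
) -> float:
    """Per-patient change-point penalty ``base_constant / V_b``.

    Applied to the baseline-normalized series ``y_t = V_t / V_b``; with the
    default constant this is 5% for a 10,000 mm^3 baseline.
    """
    if not base_constant > 0:
        raise ValueError("base_constant must be > 0 (nonpositive penalty)")
    v_b = baseline.baseline_volume if isinstance(baseline, BaselineSelection) else float(baseline)
    if v_b <= 0:
        raise ZeroBaselineError(f"baseline volume {v_b} mm^3; threshold undefined")
    return base_constant / v_b


def run_patient(
    series: VolumeSeries,
    *,
    base_constant: float = DEFAULT_THRESHOLD_CONSTANT,
    min_distance: int = 2,
    statistic: str = "rms",
    start_prefix: int = DEFAULT_START_PREFIX,
    epsilon: float = 1e-12,
) -> DetectionRecord:
    """Full single-patient pipeline: baseline, normalization, online detection.

    Detected indices are mapped back from the truncated, normalized series to
    the patient's actual scan dates (detection dates always coincide with
    scans; nothing is interpolated).  Fewer than ``start_prefix`` scans after
    baseline truncation yields an undetected record flagged
    ``insufficient_data`` rather than an error.
    """
    baseline = select_baseline(series)
    record = DetectionRecord(
        patient_id=series.patient_id,
        arm=series.source,
        growth_detected=False,
        baseline=baseline,
    )
    truncated = baseline.truncated_series
    start_prefix = max(start_prefix, 2 * min_distance)
    if truncated.size < start_prefix:
        record.insufficient_data = True
        logger.info(
            "%s/%s: %d scan(s) after baseline truncation (< %d); insufficient data",
            series.patient_id, series.source, truncated.size, start_prefix,
        )
        return record

    beta = patient_threshold(baseline, base_constant)
    y = truncated / baseline.baseline_volume
    config = ChangePointConfig(
        statistic=statistic, min_threshold=beta, min_distance=min_distance, epsilon=epsilon
    )
    # growth call: only an upward level shift counts (a volume decrease is
    # shrinkage, not progression)
    online = detect_online(y, config, start_prefix=start_prefix, require_increase=True)
    record.online = online
    record.insufficient_data = online.insufficient_data
    if online.fired:
        offset = baseline.index - 1  # truncated index 1 is the baseline scan
        record.growth_detected = True
        record.trigger_index = online.trigger_index + offset
        record.onset_index = online.onset_index + offset
        record.trigger_date = series.dates[record.trigger_index - 1]
        record.onset_date = series.dates[record.onset_index - 1]
        logger.info(
            "%s/%s: growth detected — onset %s, triggered at scan %d (%s)",
            series.patient_id, series.source, record.onset_date,
            record.trigger_index, record.trigger_date,
        )
    else:
        logger.info("%s/%s: no growth detected", series.patient_id, series.source)
    return record


def lead_months(detection_date: date, reference_date: date) -> float:
    """Signed lead time in mean-Gregorian months (30.4375 days).

    Positive when the detection precedes the clinical reference date.
    """
    return (reference_date - detection_date).days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# cohort I/O and aggregation
# ---------------------------------------------------------------------------

_VOLUME_COLUMNS = ["patient_id", "scan_date", "volume_mm3", "source"]
_LABEL_COLUMNS = ["patient_id", "group", "reference_date"]


def series_from_frame(volumes: pd.DataFrame) -> dict[tuple[str, str], VolumeSeries]:
    """Split a long-format volume table into per-(patient, arm) series."""
    missing = set(_VOLUME_COLUMNS) - set(volumes.columns)
    if missing:
        raise ValueError(f"volume table missing columns {sorted(missing)}")
    bad = set(volumes["source"]) - set(ARMS)
    if bad:
        raise ValueError(f"unknown source value(s) {sorted(bad)}; expected {ARMS}")
    out: dict[tuple[str, str], VolumeSeries] = {}
    for (pid, src), grp in volumes.groupby(["patient_id", "source"], sort=True):
        grp = grp.sort_values("scan_date")
        dates = pd.to_datetime(grp["scan_date"]).dt.date.tolist()
        if len(set(dates)) != len(dates):
            raise ValueError(f"{pid}/{src}: duplicate scan dates")
        scans = [Scan(d, float(v), str(src)) for d, v in zip(dates, grp["volume_mm3"])]
        out[(str(pid), str(src))] = VolumeSeries(patient_id=str(pid), scans=scans)
    return out


def read_volumes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_VOLUME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_labels(path: str) -> dict[str, ClinicalLabel]:
    df = pd.read_csv(path)
    missing = set(_LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(r.patient_id): ClinicalLabel(
            patient_id=str(r.patient_id),
            group=str(r.group),
            reference_date=pd.Timestamp(r.reference_date).date(),
        )
        for r in df.itertuples()
    }


def run_cohort(
    volumes: pd.DataFrame,
    arm: str | None = None,
    **config,
) -> list[DetectionRecord]:
    """Run the per-patient pipeline over every series in a volume table.

    ``arm`` restricts to one source; by default both arms are analyzed
    independently (series never mix sources).
    """
    if arm is not None and arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    records = []
    for (pid, src), series in series_from_frame(volumes).items():
        if arm is not None and src != arm:
            continue
        records.append(run_patient(series, **config))
    return records


def _quantiles(leads: list[float]) -> tuple[float, float, float]:
    """(median, lower IQR, upper IQR) by linear-interpolation quantiles."""
    q25, q50, q75 = np.percentile(leads, [25.0, 50.0, 75.0])
    return float(q50), float(q25), float(q75)


def summarize_cohort(
    records: Iterable[DetectionRecord],
    labels: Mapping[str, ClinicalLabel] | Iterable[ClinicalLabel],
) -> CohortSummary:
    """Aggregate per-patient growth calls into cohort metrics.

    Lead times (detected patients only, change-point onset date vs the
    group's reference date) are summarized per (group, arm) by median and
    IQR.  Error rates per arm follow the study's per-patient accounting:

    * established progressors = clinical_progression group plus
      clinically-stable patients whose *reviewed*-arm record detected growth;
      FN rate = undetected / total among them;
    * true stables = negative controls plus the remaining clinically-stable
      patients; FP rate = detected / total among them.

    Every record must carry a label; an unlabeled patient is an error.
    Detected records have ``lead_months`` filled in place.
    """
    if not isinstance(labels, Mapping):
        labels = {lab.patient_id: lab for lab in labels}
    records = list(records)
    for rec in records:
        if rec.patient_id not in labels:
            raise ValueError(f"patient {rec.patient_id!r} has a detection record but no clinical label")

    # reviewed-arm adjudication of the clinically-stable group
    reviewed_detected = {
        r.patient_id for r in records if r.arm == "reviewed" and r.growth_detected
    }

    def is_progressor(pid: str) -> bool:
        g = labels[pid].group
        if g == "clinical_progression":
            return True
        if g == "clinically_stable":
            return pid in reviewed_detected
        return False

    group_rows = []
    leads_map: dict[tuple[str, str], list[float]] = {}
    arms_present = sorted({r.arm for r in records})
    for group in GROUPS:
        for arm in arms_present:
            sub = [r for r in records if r.arm == arm and labels[r.patient_id].group == group]
            if not sub:
                continue
            leads = []
            for r in sub:
                if r.growth_detected:
                    r.lead_months = lead_months(r.onset_date, labels[r.patient_id].reference_date)
                    leads.append(r.lead_months)
            med = lo = hi = float("nan")
            if leads:
                med, lo, hi = _quantiles(leads)
            leads_map[(group, arm)] = leads
            group_rows.append(
                dict(group=group, arm=arm, n=len(sub), n_detected=len(leads),
                     median_lead=med, lower_iqr=lo, upper_iqr=hi)
            )

    rate_rows = []
    for arm in arms_present:
        by_pid = {r.patient_id: r for r in records if r.arm == arm}
        prog = [pid for pid in by_pid if is_progressor(pid)]
        stable = [pid for pid in by_pid if not is_progressor(pid)]
        fn_n = sum(1 for pid in prog if not by_pid[pid].growth_detected)
        fp_n = sum(1 for pid in stable if by_pid[pid].growth_detected)
        rate_rows.append(
            dict(
                arm=arm,
                fp_n=fp_n, fp_total=len(stable),
                fp_rate=fp_n / len(stable) if stable else float("nan"),
                fn_n=fn_n, fn_total=len(prog),
                fn_rate=fn_n / len(prog) if prog else float("nan"),
            )
        )

    return CohortSummary(
        groups=pd.DataFrame(group_rows),
        rates=pd.DataFrame(rate_rows),
        leads=leads_map,
    )


def score_against_truth(
    records: Iterable[DetectionRecord],
    truth: pd.DataFrame,
    interval_months: float = 4.0,
) -> dict[str, float]:
    """Score detection records against a simulated ground truth.

    ``truth`` needs columns ``patient_id`` and ``true_onset_date`` (empty for
    patients that never grow).  Returns per-patient sensitivity, FP rate, and
    the fraction of detections whose onset date falls within one scan
    interval of the true onset — the patient's own mean interval when the
    truth table carries a ``scan_interval_months`` column, else
    ``interval_months`` (converted at 30.4375 days/month).
    """
    truth = truth.copy()
    truth["patient_id"] = truth["patient_id"].astype(str)
    onset_map = {
        r.patient_id: (pd.Timestamp(r.true_onset_date).date()
                       if pd.notna(r.true_onset_date) and str(r.true_onset_date) != "" else None)
        for r in truth.itertuples()
    }
    interval_map = (
        dict(zip(truth["patient_id"], truth["scan_interval_months"].astype(float)))
        if "scan_interval_months" in truth.columns
        else {}
    )
    tp = fn = fp = tn = 0
    onset_ok = onset_total = 0
    for rec in records:
        true_onset = onset_map.get(rec.patient_id, None)
        if true_onset is not None:
            if rec.growth_detected:
                tp += 1
                onset_total += 1
                tol_days = interval_map.get(rec.patient_id, interval_months) * DAYS_PER_MONTH
                if abs((rec.onset_date - true_onset).days) <= tol_days:
                    onset_ok += 1
            else:
                fn += 1
        else:
            if rec.growth_detected:
                fp += 1
            else:
                tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fp_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "onset_within_interval": onset_ok / onset_total if onset_total else float("nan"),
        "n_growth": tp + fn,
        "n_stable": fp + tn,
    }
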