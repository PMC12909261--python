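"""Synthetic longitudinal cohorts and segmentation masks.

The study's clinical imaging is restricted, so everything downstream is
exercised on simulated data that reproduces its *structure*:

* per-patient volume trajectories with at least 4 scans at irregular
  intervals: post-operative FLAIR elevation decaying exponentially to a
  plateau (the post-op nadir), an optional growth onset (exponential
  volume doubling or linear diameter expansion), and multiplicative
  lognormal measurement noise whose coefficient of variation is anchored to
  the segmentation variability reported for physician-reviewed (6.9%,
  intra-user) and raw AI (12.5%, inter-user) contours;
* two correlated measurement arms per patient — ``reviewed`` volumes are the
  noisy observation of the true path, ``raw_ai`` volumes add further
  contour noise on top, so that total raw variability matches the
  inter-user level;
* digitized ellipsoid masks and Dice-targeted boundary perturbations for the
  volumetric/agreement tests.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .monitoring import DAYS_PER_MONTH, Scan, VolumeSeries
from .volumetrics import SegmentationMask, dice

__all__ = [
    "TrajectoryParams",
    "SyntheticCohortSpec",
    "simulate_trajectory",
    "simulate_cohort",
    "write_cohort",
    "make_ellipsoid_mask",
    "perturb_mask_to_dice",
]

GROWTH_MODELS = ("exponential", "linear_diameter")


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth description of one patient's volume trajectory.

    Volumes in mm^3, times in months since the first post-operative scan.
    ``onset_month=None`` means the lesion plateaus and never grows.
    """

    v_preop: float = 20000.0
    decay_rate: float = 0.12          # per-month decay of post-op FLAIR elevation
    v_plateau: float = 10000.0
    onset_month: float | None = None
    growth_model: str = "exponential"
    doubling_time_months: float = 24.0
    mm_per_year: float = 4.0          # diameter growth for the linear model
    noise_cv: float = 0.069
    scan_interval_months: float = 4.0
    scan_jitter_months: float = 1.0
    n_scans: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.v_preop >= self.v_plateau > 0):
            raise ValueError("need v_preop >= v_plateau > 0")
        if self.decay_rate < 0 or self.noise_cv < 0:
            raise ValueError("decay_rate and noise_cv must be >= 0")
        if self.n_scans < 4:
            raise ValueError("n_scans must be >= 4 (study inclusion criterion)")
        if self.growth_model not in GROWTH_MODELS:
            raise ValueError(f"growth_model must be one of {GROWTH_MODELS}")
        if self.growth_model == "exponential" and self.doubling_time_months <= 0:
            raise ValueError("doubling_time_months must be > 0")
        if self.scan_interval_months <= 0 or self.scan_jitter_months < 0:
            raise ValueError("scan intervals must be positive, jitter >= 0")
        if self.scan_jitter_months >= self.scan_interval_months:
            raise ValueError("jitter must be smaller than the mean interval")


def _mean_volume(p: TrajectoryParams, t: float) -> float:
    """Noiseless volume at ``t`` months: decay to plateau, then growth."""
    decayed = max(p.v_plateau, p.v_preop * math.exp(-p.decay_rate * t))
    if p.onset_month is None or t < p.onset_month:
        return decayed
    dt = t - p.onset_month
    if p.growth_model == "exponential":
        grown = p.v_plateau * 2.0 ** (dt / p.doubling_time_months)
    else:
        d0 = 2.0 * (3.0 * p.v_plateau / (4.0 * math.pi)) ** (1.0 / 3.0)
        grown = p.v_plateau * ((d0 + p.mm_per_year * dt / 12.0) / d0) ** 3
    return max(decayed, grown)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``.

    Always consumes ``n`` normal draws so that runs differing only in ``cv``
    see identical underlying randomness (matched-seed comparisons).
    """
    z = rng.standard_normal(n)
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(sigma * z - 0.5 * sigma**2)


def _months_to_date(start: date, months: float) -> date:
    return start + timedelta(days=round(months * DAYS_PER_MONTH))


def simulate_trajectory(
    params: TrajectoryParams,
    patient_id: str = "SYN000",
    start_date: date = date(2012, 1, 1),
    source: str = "reviewed",
) -> tuple[VolumeSeries, date | None]:
    """Simulate one patient's observed volume series.

    Returns the series and the true growth-onset calendar date (``None`` for
    a stable trajectory).  Scan times are ``scan_interval_months`` apart with
    uniform jitter; observed volumes are the noiseless path times lognormal
    mean-1 noise.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    times = _scan_times(rng, params)
    noise = _lognormal_factors(rng, params.noise_cv, params.n_scans)
    volumes = np.array([_mean_volume(params, t) for t in times]) * noise
    scans = [
        Scan(_months_to_date(start_date, t), float(v), source)
        for t, v in zip(times, volumes)
    ]
    series = VolumeSeries(patient_id=patient_id, scans=scans)
    onset_date = (
        _months_to_date(start_date, params.onset_month) if params.onset_month is not None else None
    )
    return series, onset_date


def _scan_times(rng: np.random.Generator, p: TrajectoryParams) -> np.ndarray:
    jitter = rng.uniform(-p.scan_jitter_months, p.scan_jitter_months, p.n_scans - 1)
    intervals = p.scan_interval_months + jitter
    return np.concatenate([[0.0], np.cumsum(intervals)])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort layout mirroring the study's three groups.

    Progression patients grow from a random onset; stable and negative
    control patients plateau.  Controls were never resected, so their
    trajectory has no post-operative decay.  ``noise_cv_reviewed`` /
    ``noise_cv_raw`` are the total measurement CVs of the two arms; the raw
    arm is generated as extra contour noise on top of the reviewed volumes,
    keeping the arms correlated.
    """

    n_progression: int = 34
    n_stable: int = 22
    n_control: int = 7
    seed: int = 0
    noise_cv_reviewed: float = 0.069
    noise_cv_raw: float = 0.125
    scan_interval_months: float = 4.0
    scan_jitter_months: float = 1.0
    growth_model: str = "exponential"
    doubling_time_months: float = 24.0
    mm_per_year: float = 4.0
    median_plateau_mm3: float = 10000.0
    start_date: date = date(2012, 1, 1)

    def __post_init__(self) -> None:
        if min(self.n_progression, self.n_stable, self.n_control) < 0:
            raise ValueError("group sizes must be >= 0")
        if not (0 <= self.noise_cv_reviewed and 0 <= self.noise_cv_raw):
            raise ValueError("noise CVs must be >= 0")


def _extra_cv(cv_total: float, cv_base: float) -> float:
    """CV of the extra multiplicative noise lifting cv_base to cv_total."""
    if cv_total <= cv_base:
        return 0.0
    return math.sqrt((1.0 + cv_total**2) / (1.0 + cv_base**2) - 1.0)


_VOL_COLS = ["patient_id", "scan_date", "volume_mm3", "source"]
_LAB_COLS = ["patient_id", "group", "reference_date"]
_TRUTH_COLS = ["patient_id", "group", "true_onset_date", "scan_interval_months"]


def simulate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (volumes, labels, truth) tables for a synthetic cohort.

    Per-patient parameters are drawn from fixed distributions (see the
    methods note): plateau volumes lognormal about ``median_plateau_mm3``,
    post-op elevation 1.5–3x the plateau, decay rate 0.08–0.2 /month,
    10–16 scans, growth onset uniform between month 12 and 20 months before
    the end of follow-up, and a clinical reporting delay of 12–30 months
    after onset (capped at the last scan).  Reproducible given ``spec.seed``.
    """
    vol_rows: list[dict] = []
    lab_rows: list[dict] = []
    truth_rows: list[dict] = []

    roster = (
        [("clinical_progression", f"G{i:03d}") for i in range(spec.n_progression)]
        + [("clinically_stable", f"S{i:03d}") for i in range(spec.n_stable)]
        + [("negative_control", f"C{i:03d}") for i in range(spec.n_control)]
    )
    cv_extra = _extra_cv(spec.noise_cv_raw, spec.noise_cv_reviewed)

    for idx, (group, pid) in enumerate(roster):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, idx)))
        v_plateau = spec.median_plateau_mm3 * math.exp(rng.normal(0.0, 0.5))
        if group == "negative_control":
            v_preop, decay = v_plateau, 0.0
        else:
            v_preop, decay = v_plateau * rng.uniform(1.5, 3.0), rng.uniform(0.08, 0.2)
        n_scans = int(rng.integers(10, 17))
        params = TrajectoryParams(
            v_preop=v_preop,
            decay_rate=decay,
            v_plateau=v_plateau,
            onset_month=None,
            growth_model=spec.growth_model,
            doubling_time_months=spec.doubling_time_months,
            mm_per_year=spec.mm_per_year,
            noise_cv=spec.noise_cv_reviewed,
            scan_interval_months=spec.scan_interval_months,
            scan_jitter_months=spec.scan_jitter_months,
            n_scans=n_scans,
            seed=0,  # unused below; draws come from this patient's rng
        )
        times = _scan_times(rng, params)
        T = float(times[-1])
        onset = None
        if group == "clinical_progression":
            lo = min(12.0, 0.35 * T)
            hi = max(lo + 1.0, T - 20.0)
            onset = float(rng.uniform(lo, hi))
            params = replace(params, onset_month=onset)

        mean_path = np.array([_mean_volume(params, t) for t in times])
        reviewed = mean_path * _lognormal_factors(rng, spec.noise_cv_reviewed, n_scans)
        raw = reviewed * _lognormal_factors(rng, cv_extra, n_scans)

        start = spec.start_date + timedelta(days=int(rng.integers(0, 365)))
        dates = [_months_to_date(start, t) for t in times]
        for d, v_rev, v_raw in zip(dates, reviewed, raw):
            vol_rows.append(dict(patient_id=pid, scan_date=d.isoformat(),
                                 volume_mm3=float(v_rev), source="reviewed"))
            vol_rows.append(dict(patient_id=pid, scan_date=d.isoformat(),
                                 volume_mm3=float(v_raw), source="raw_ai"))

        if group == "clinical_progression":
            delay = float(rng.uniform(12.0, 30.0))
            ref = min(_months_to_date(start, onset + delay), dates[-1])
        else:
            ref = dates[-1]
        lab_rows.append(dict(patient_id=pid, group=group, reference_date=ref.isoformat()))
        truth_rows.append(dict(
            patient_id=pid,
            group=group,
            true_onset_date=_months_to_date(start, onset).isoformat() if onset is not None else "",
            scan_interval_months=float(np.mean(np.diff(times))),
        ))

    volumes = pd.DataFrame(vol_rows, columns=_VOL_COLS)
    labels = pd.DataFrame(lab_rows, columns=_LAB_COLS)
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLS)
    return volumes, labels, truth


def write_cohort(spec: SyntheticCohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Write volumes.csv, labels.csv and truth.csv for a cohort spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    volumes, labels, truth = simulate_cohort(spec)
    paths = {}
    for name, df in [("volumes", volumes), ("labels", labels), ("truth", truth)]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# synthetic masks
# ---------------------------------------------------------------------------


def make_ellipsoid_mask(
    semi_axes: tuple[float, float, float],
    spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int] | None = None,
    frame_id: str = "ellipsoid",
) -> SegmentationMask:
    """Digitized solid ellipsoid: a voxel is tumor iff its center lies inside.

    The ellipsoid is centered in the grid; the default grid adds a one-voxel
    margin around the ellipsoid.  Volume converges to 4/3*pi*abc as spacing
    shrinks.
    """
    semi_axes = tuple(float(a) for a in semi_axes)
    spacing = tuple(float(s) for s in spacing)
    if any(a <= 0 for a in semi_axes):
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if grid_shape is None:
        # odd extent keeps a voxel center at the ellipsoid center, so even
        # sub-voxel ellipsoids digitize to a nonempty mask
        grid_shape = tuple(
            (lambda n: n + 1 - n % 2)(int(math.ceil(2 * a / s)) + 2)
            for a, s in zip(semi_axes, spacing)
        )
    for a, s, n in zip(semi_axes, spacing, grid_shape):
        if 2 * a > n * s:
            raise ValueError(f"ellipsoid (semi-axis {a} mm) exceeds grid extent {n * s} mm")
    center = [n * s / 2.0 for n, s in zip(grid_shape, spacing)]
    coords = [
        (np.arange(n) + 0.5) * s - c for n, s, c in zip(grid_shape, spacing, center)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    inside = (
        (xx / semi_axes[0]) ** 2 + (yy / semi_axes[1]) ** 2 + (zz / semi_axes[2]) ** 2
    ) <= 1.0
    return SegmentationMask(voxels=inside.astype(np.uint8), spacing=spacing, frame_id=frame_id)


def perturb_mask_to_dice(
    mask: SegmentationMask,
    target: float,
    tolerance: float = 0.02,
    seed: int = 0,
    max_iter: int = 500,
) -> SegmentationMask:
    """Perturb a mask's boundary until its Dice with the original hits a target.

    Emulates an independent reviewer's re-contour of the same lesion: random
    boundary voxels are flipped in balanced add/remove steps, so the
    perturbed mask keeps approximately the original volume (inter-reader
    disagreement is boundary uncertainty, not systematic volume bias).
    Deterministic given ``seed``; raises if the target cannot be reached
    within ``max_iter`` steps (e.g. masks too small for balanced flips).
    """
    from scipy import ndimage

    if not (0.0 < target <= 1.0):
        raise ValueError("target Dice must be in (0, 1]")
    A = mask.voxels.astype(bool)
    n_a = int(A.sum())
    if n_a == 0:
        raise ValueError("cannot perturb an empty mask")
    if target == 1.0:
        return SegmentationMask(mask.voxels.copy(), mask.spacing, mask.frame_id + "-copy")

    rng = np.random.default_rng(seed)
    B = A.copy()
    size_lo = max(1, math.floor(0.9 * n_a))
    size_hi = math.ceil(1.1 * n_a)

    def current_dice() -> float:
        inter = int(np.logical_and(A, B).sum())
        return 2.0 * inter / (n_a + int(B.sum()))

    for _ in range(max_iter):
        d = current_dice()
        # aim for the center of the tolerance band to avoid edge bias from
        # the coarse flip granularity
        if abs(d - target) <= 0.5 * tolerance:
            return SegmentationMask(
                B.astype(np.uint8), mask.spacing, mask.frame_id + f"-dice{target:g}"
            )
        n_b = int(B.sum())
        step = max(1, int(0.25 * (n_a + n_b) * abs(d - target)))
        if d > target:
            # move away from A: shed boundary voxels, grow outward elsewhere
            removable = np.argwhere(B & ~ndimage.binary_erosion(B))
            addable = np.argwhere(ndimage.binary_dilation(B) & ~B & ~A)
        else:
            # overshoot: claw back toward A along the boundary
            removable = np.argwhere(B & ~A & ~ndimage.binary_erosion(B))
            addable = np.argwhere(A & ~B & ndimage.binary_dilation(B))
        n_remove = min(step // 2 + step % 2, len(removable), n_b - size_lo)
        n_add = min(step // 2, len(addable), size_hi - n_b)
        if n_remove <= 0 and n_add <= 0:
            break
        if n_remove > 0:
            picks = removable[rng.choice(len(removable), size=n_remove, replace=False)]
            B[tuple(picks.T)] = False
        if n_add > 0:
            picks = addable[rng.choice(len(addable), size=n_add, replace=False)]
            B[tuple(picks.T)] = True
    if abs(current_dice() - target) <= tolerance:
        return SegmentationMask(
            B.astype(np.uint8), mask.spacing, mask.frame_id + f"-dice{target:g}"
        )
    raise ValueError(
        f"could not reach Dice {target} +/- {tolerance} from a {n_a}-voxel mask "
        f"by balanced boundary flips (last Dice {current_dice():.3f})"
    )
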