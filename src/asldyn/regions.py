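"""High-CBF tumour subvolume definition, overlap metrics and weekly dynamics.

The highly perfused ("high-CBF") tumour region is defined by thresholding:
the cohort threshold is the across-patient median of each patient's 95%
quantile of CBF in contralateral grey matter at baseline (an estimate of the
maximum grey-matter blood flow).  Within the treatment-planning CTV, voxels
with CBF strictly above the threshold are selected and the largest connected
component is kept.  Patients enter the overlap analysis only if that region
exceeds 1 cm^3.

Overlap with the enhancing tumour (GTV) is summarised by two percentages:

    %GTV occupied by high-CBF = 100 * |hCBF & GTV| / |GTV|
    %high-CBF outside GTV     = 100 * |hCBF & ~GTV| / |hCBF|

and weekly dynamics by the relative change from the baseline week,
%dhCBF_k = 100 * (hCBF_k - hCBF_1) / hCBF_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .quantify import CbfMap
from .volume import Volume

__all__ = [
    "RegionSet",
    "HighCbfRegion",
    "OverlapMetrics",
    "DynamicsSeries",
    "gm_cbf_stats",
    "cohort_threshold",
    "segment_high_cbf",
    "overlap_metrics",
    "assign_week",
    "relative_change_series",
    "cohort_dynamics_summary",
    "CohortDynamics",
]

#: skimage connectivity order per neighbour count in 3D
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class RegionSet:
    """Radiotherapy target masks plus contralateral grey matter."""

    gtv: Volume
    ctv: Volume
    contralateral_gm: Volume

    def __post_init__(self) -> None:
        self.gtv.require_same_grid(self.ctv, what="CTV")
        self.gtv.require_same_grid(self.contralateral_gm, what="contralateral GM")
        if np.any(np.asarray(self.gtv.data, bool) & ~np.asarray(self.ctv.data, bool)):
            raise ValueError("GTV must be a subset of the CTV")


@dataclass(frozen=True)
class HighCbfRegion:
    """Largest connected suprathreshold component within the CTV."""

    mask: Volume
    volume_cm3: float
    threshold_used: float
    included: bool  # passes the > 1 cm^3 rule


@dataclass(frozen=True)
class OverlapMetrics:
    """Overlap of the high-CBF region with the GTV, in percent."""

    pct_gtv_occupied: float
    pct_outside_gtv: float | None  # None (flagged) when the region is empty
    empty_hcbf: bool = False


def gm_cbf_stats(cbf: CbfMap, gm_mask: Volume) -> tuple[float, float]:
    """Median and 95% quantile of CBF over a grey-matter mask.

    The quantile uses linear interpolation between order statistics.
    """
    cbf.values.require_same_grid(gm_mask, what="GM mask")
    sel = np.asarray(gm_mask.data, dtype=bool)
    if not sel.any():
        raise ValueError("grey-matter mask is empty")
    vals = np.asarray(cbf.values.data, dtype=float)[sel]
    return float(np.median(vals)), float(np.quantile(vals, 0.95))


def cohort_threshold(per_patient_q95: list[float]) -> float:
    """Across-patient median of baseline GM 95% quantiles (CBF_gm,max)."""
    if len(per_patient_q95) == 0:
        raise ValueError("need at least one per-patient q95 value")
    return float(np.median(np.asarray(per_patient_q95, dtype=float)))


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest connected component; size ties broken by smallest linear index."""
    labels = measure.label(mask, connectivity=_CONNECTIVITY[connectivity])
    n = labels.max()
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    flat = labels.ravel()
    sizes = np.bincount(flat)[1:]
    best = sizes.max()
    candidates = np.nonzero(sizes == best)[0] + 1
    if candidates.size == 1:
        keep = candidates[0]
    else:
        first_index = {
            lab: np.nonzero(flat == lab)[0][0] for lab in candidates
        }
        keep = min(candidates, key=lambda lab: first_index[lab])
    return labels == keep


def segment_high_cbf(
    cbf: CbfMap,
    regions: RegionSet,
    threshold: float,
    connectivity: int = 26,
    min_volume_cm3: float = 1.0,
) -> HighCbfRegion:
    """Segment the high-CBF region: CTV voxels with CBF > threshold, largest CC.

    The threshold is strict (CBF must exceed it).  An empty result is valid
    and simply fails the inclusion rule.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    cbf.values.require_same_grid(regions.ctv, what="CTV")
    supra = (
        (np.asarray(cbf.values.data, dtype=float) > threshold)
        & np.asarray(regions.ctv.data, dtype=bool)
        & np.asarray(cbf.mask_valid.data, dtype=bool)
    )
    component = _largest_component(supra, connectivity)
    vol = cbf.values.count_to_cm3(int(component.sum()))
    return HighCbfRegion(
        mask=cbf.values.with_data(component),
        volume_cm3=vol,
        threshold_used=float(threshold),
        included=vol > min_volume_cm3,
    )


def overlap_metrics(hcbf: HighCbfRegion, gtv_mask: Volume) -> OverlapMetrics:
    """Percent of GTV occupied by the high-CBF region and percent outside it."""
    hcbf.mask.require_same_grid(gtv_mask, what="GTV")
    h = np.asarray(hcbf.mask.data, dtype=bool)
    g = np.asarray(gtv_mask.data, dtype=bool)
    n_gtv = int(g.sum())
    if n_gtv == 0:
        raise ValueError("GTV mask is empty")
    n_h = int(h.sum())
    inter = int((h & g).sum())
    pct_gtv = 100.0 * inter / n_gtv
    if n_h == 0:
        return OverlapMetrics(pct_gtv_occupied=pct_gtv, pct_outside_gtv=None, empty_hcbf=True)
    return OverlapMetrics(
        pct_gtv_occupied=pct_gtv,
        pct_outside_gtv=100.0 * (n_h - inter) / n_h,
    )


def assign_week(day: int) -> int:
    """Treatment week containing a fraction day (day 1 starts week 1)."""
    day = int(day)
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    return (day - 1) // 7 + 1


@dataclass(frozen=True)
class DynamicsSeries:
    """Weekly high-CBF volumes and their percent change from week 1."""

    subject: str
    volumes_by_week: dict[int, float]
    pct_change: dict[int, float]


def relative_change_series(
    volumes_by_week: dict[int, float], subject: str = ""
) -> DynamicsSeries:
    """Percent change of high-CBF volume per week relative to week 1."""
    if 1 not in volumes_by_week:
        raise ValueError("week 1 (baseline) volume is required")
    v1 = float(volumes_by_week[1])
    if v1 <= 0:
        raise ValueError("baseline high-CBF volume must be positive")
    pct = {
        int(k): 100.0 * (float(v) - v1) / v1 for k, v in volumes_by_week.items()
    }
    pct[1] = 0.0
    return DynamicsSeries(
        subject=subject,
        volumes_by_week={int(k): float(v) for k, v in volumes_by_week.items()},
        pct_change=pct,
    )


@dataclass(frozen=True)
class CohortDynamics:
    """Per-week cohort medians of %change with a test against zero change."""

    median_pct_change: dict[int, float]
    p_values: dict[int, float]
    n_per_week: dict[int, int]
    included_subjects: tuple[str, ...]
    excluded: dict[str, str] = field(default_factory=dict)


def cohort_dynamics_summary(
    series: list[DynamicsSeries],
    schedules: list,
) -> CohortDynamics:
    """Cohort weekly dynamics with the clinical inclusion rules applied.

    A patient enters only if the baseline scan fell in week 1 and the patient
    has at least two scans.  Per week, the median %change across included
    patients is reported together with a one-sample t-test against zero
    (weeks with fewer than two patients get no p-value).
    """
    from .repeatability import one_sample_test

    by_subject = {sched.subject: sched for sched in schedules}
    included: list[DynamicsSeries] = []
    excluded: dict[str, str] = {}
    for ds in series:
        sched = by_subject.get(ds.subject)
        if sched is None:
            excluded[ds.subject] = "no scan schedule on record"
            continue
        if assign_week(sched.scan_days[0]) != 1:
            excluded[ds.subject] = (
                f"baseline scan on day {sched.scan_days[0]} is after week 1"
            )
            continue
        if len(sched.scan_days) < 2:
            excluded[ds.subject] = "fewer than two ASL scans"
            continue
        included.append(ds)
    if not included:
        detail = "; ".join(f"{s}: {r}" for s, r in excluded.items()) or "no series given"
        raise ValueError(f"no eligible patients for the dynamics analysis ({detail})")

    weeks = sorted({w for ds in included for w in ds.pct_change})
    medians: dict[int, float] = {}
    pvals: dict[int, float] = {}
    counts: dict[int, int] = {}
    for w in weeks:
        vals = [ds.pct_change[w] for ds in included if w in ds.pct_change]
        medians[w] = float(np.median(vals))
        counts[w] = len(vals)
        if w != 1 and len(vals) >= 2:
            _, pvals[w] = one_sample_test(vals, null_mean=0.0)
    return CohortDynamics(
        median_pct_change=medians,
        p_values=pvals,
        n_per_week=counts,
        included_subjects=tuple(ds.subject for ds in included),
        excluded=excluded,
    )
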