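"""End-to-end orchestration: simulate, quantify, segment, summarise.

The demo pipeline mirrors the clinical analysis chain on a synthetic cohort:

1. simulate a longitudinal ASL series per patient (shrinking high-CBF
   tumour subvolume, seeded noise);
2. estimate the labelling efficiency from simulated carotid Look-Locker
   signals, take the cohort median, and correct the CBF maps (maps are
   fitted at the consensus alpha = 0.85 and rescaled, which is exactly
   equivalent to fitting at the measured alpha);
3. collect grey-matter median / 95%-quantile CBF per scan, form the cohort
   high-CBF threshold from the baseline q95 values, segment the high-CBF
   region within the CTV per scan, and compute GTV overlap;
4. weekly volume dynamics relative to week 1, with cohort medians and
   t-tests against zero change;
5. within-subject repeatability of grey-matter CBF (wSD, wCV, RC) and
   per-patient change detection of the CTV 95% quantile against RC.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import labeff as le
from .config import PipelineConfig
from .io import save_acquisition, save_volume, write_json
from .phantom import PhantomSpec, ScheduleSpec
from .quantify import QuantParams, quantify_acquisition, rescale_alpha
from .regions import (
    RegionSet,
    assign_week,
    cohort_dynamics_summary,
    cohort_threshold,
    gm_cbf_stats,
    overlap_metrics,
    relative_change_series,
    segment_high_cbf,
)
from .repeatability import (
    RepeatedMeasures,
    detect_significant_change,
    fit_variance_components,
)
from .simulate import simulate_longitudinal, simulate_look_locker

logger = logging.getLogger("asldyn")

#: column -> dtype kind ('f' float, 'i' integer, 'b' bool, 'O' object)
COHORT_SCHEMA: dict[str, str] = {
    "subject": "O",
    "day": "i",
    "week": "i",
    "gm_median_cbf": "f",
    "gm_q95_cbf": "f",
    "ctv_q95_cbf": "f",
    "hcbf_volume_cm3": "f",
    "pct_change_from_week1": "f",
    "pct_gtv_occupied": "f",
    "pct_outside_gtv": "f",
    "true_hot_volume_cm3": "f",
}

__all__ = ["run_end_to_end", "validate_cohort_table", "COHORT_SCHEMA"]


def validate_cohort_table(df: pd.DataFrame) -> None:
    """Schema check before writing: columns, dtype kinds, unique keys, units."""
    missing = [c for c in COHORT_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    for col, kind in COHORT_SCHEMA.items():
        if df[col].dtype.kind not in (kind, "f" if kind == "i" else kind):
            raise ValueError(
                f"cohort table column {col!r} has dtype {df[col].dtype}, expected kind {kind!r}"
            )
    if df.duplicated(subset=["subject", "day"]).any():
        raise ValueError("cohort table rows must be uniquely keyed by (subject, day)")


def _patient_schedule(patient_index: int, n_weeks: int) -> ScheduleSpec:
    """Weekly scans; baseline day staggered across week 1 (one patient late).

    The last patient of every group of six gets a week-2 baseline so the
    dynamics inclusion filter always has something to exclude.
    """
    if patient_index % 6 == 5:
        first = 9  # week 2 baseline -> excluded from dynamics
    else:
        first = 1 + (patient_index % 5)
    days = [first + 7 * k for k in range(n_weeks)]
    return ScheduleSpec(subject=f"P{patient_index + 1:02d}", scan_days=tuple(days))


def _patient_phantom_spec(cfg: PipelineConfig, rng: np.random.Generator, seed: int) -> PhantomSpec:
    radius = float(rng.uniform(18.0, 24.0))
    return PhantomSpec(
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        tumour_radii_mm=(radius,) * 3,
        hot_fraction=float(rng.uniform(0.12, 0.2)),
        hot_outside_gtv_fraction=float(rng.uniform(0.3, 0.6)),
        weekly_hot_shrink=cfg.weekly_hot_shrink,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )


def run_end_to_end(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full synthetic-cohort pipeline; returns (cohort table, report)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_patients + 1)
    child_seeds = (child_seeds % np.uint32(2**31)).astype(np.int64)
    quant_consensus = QuantParams(
        alpha=cfg.alpha_consensus,
        lambda_bp=cfg.lambda_bp,
        t1_blood=cfg.t1_blood,
        tau=cfg.tau,
        pld=cfg.pld,
    )

    # --- simulate all patients and measure labelling efficiency -------------
    patients: dict[str, dict] = {}
    schedules: list[ScheduleSpec] = []
    alpha_estimates: list[le.LabEffEstimate] = []
    failures: dict[str, str] = {}
    for p in range(cfg.n_patients):
        sched = _patient_schedule(p, cfg.n_weeks)
        rng = np.random.default_rng(int(child_seeds[2 * p]))
        try:
            spec = _patient_phantom_spec(cfg, rng, int(child_seeds[2 * p + 1]))
            scans = simulate_longitudinal(
                spec, sched, quant_consensus, alpha_true=cfg.alpha_true
            )
            ll = simulate_look_locker(
                alpha_true=cfg.alpha_true,
                noise_sd=cfg.ll_noise_sd_frac * 1000.0,
                m0b=1000.0,
                seed=rng,
            )
            alpha_estimates.append(le.fit_labelling_efficiency(ll))
            patients[sched.subject] = {"spec": spec, "scans": scans}
            schedules.append(sched)
            logger.info("%s: simulated %d scans", sched.subject, len(scans))
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failures
            failures[sched.subject] = str(exc)
            logger.error("%s: simulation failed: %s", sched.subject, exc)
    if not patients:
        raise RuntimeError(f"all patients failed: {failures}")

    alpha_summary = le.summarize_alpha(alpha_estimates)
    alpha_used = alpha_summary.median if cfg.use_measured_alpha else cfg.alpha
    logger.info("cohort labelling efficiency: median %.3f (range %.3f-%.3f)",
                alpha_summary.median, alpha_summary.min, alpha_summary.max)

    # --- quantify: consensus-alpha maps rescaled to the alpha in use --------
    for subject, rec in patients.items():
        maps = []
        for scan in rec["scans"]:
            cbf = quantify_acquisition(
                scan.acquisition, quant_consensus, cfg.m0_threshold_frac
            )
            maps.append(rescale_alpha(cbf, alpha_used))
        rec["cbf_maps"] = maps

    # --- grey-matter statistics and the cohort threshold --------------------
    baseline_q95: list[float] = []
    for subject, rec in patients.items():
        stats_per_scan = []
        for scan, cbf in zip(rec["scans"], rec["cbf_maps"]):
            gm_med, gm_q95 = gm_cbf_stats(cbf, scan.truth.contralateral_gm_mask)
            ctv_vals = cbf.values.data[np.asarray(scan.truth.ctv_mask.data, bool)]
            stats_per_scan.append(
                {
                    "gm_median": gm_med,
                    "gm_q95": gm_q95,
                    "ctv_q95": float(np.quantile(ctv_vals, 0.95)),
                }
            )
        rec["stats"] = stats_per_scan
        baseline_q95.append(stats_per_scan[0]["gm_q95"])
    threshold = (
        cfg.threshold_override
        if cfg.threshold_override is not None
        else cohort_threshold(baseline_q95)
    )
    logger.info("high-CBF threshold: %.1f ml/100 g/min", threshold)

    # --- per-scan segmentation, overlap, dynamics ---------------------------
    rows: list[dict] = []
    dynamics_series = []
    pre_excluded: dict[str, str] = {}
    for subject, rec in patients.items():
        weekly_volumes: dict[int, list[float]] = {}
        for scan, cbf, st in zip(rec["scans"], rec["cbf_maps"], rec["stats"]):
            regions = RegionSet(
                gtv=scan.truth.gtv_mask,
                ctv=scan.truth.ctv_mask,
                contralateral_gm=scan.truth.contralateral_gm_mask,
            )
            hcbf = segment_high_cbf(
                cbf, regions, threshold,
                connectivity=cfg.connectivity,
                min_volume_cm3=cfg.min_hcbf_volume_cm3,
            )
            ov = overlap_metrics(hcbf, scan.truth.gtv_mask)
            weekly_volumes.setdefault(scan.week, []).append(hcbf.volume_cm3)
            rows.append(
                {
                    "subject": subject,
                    "day": scan.day,
                    "week": scan.week,
                    "gm_median_cbf": st["gm_median"],
                    "gm_q95_cbf": st["gm_q95"],
                    "ctv_q95_cbf": st["ctv_q95"],
                    "hcbf_volume_cm3": hcbf.volume_cm3,
                    "pct_change_from_week1": np.nan,
                    "pct_gtv_occupied": ov.pct_gtv_occupied,
                    "pct_outside_gtv": np.nan if ov.pct_outside_gtv is None else ov.pct_outside_gtv,
                    "true_hot_volume_cm3": scan.true_hot_volume_cm3,
                }
            )
        vols = {wk: float(np.mean(v)) for wk, v in weekly_volumes.items()}
        if 1 in vols and vols[1] > 0:
            dynamics_series.append(relative_change_series(vols, subject=subject))
        elif 1 not in vols:
            pre_excluded[subject] = "no week-1 baseline scan"
            logger.info("%s: excluded from dynamics (no week-1 baseline)", subject)
        else:
            pre_excluded[subject] = "empty high-CBF region at baseline"
            logger.info("%s: excluded from dynamics (empty baseline region)", subject)

    dynamics = cohort_dynamics_summary(dynamics_series, schedules)
    by_subject = {ds.subject: ds for ds in dynamics_series}
    for row in rows:
        ds = by_subject.get(row["subject"])
        if ds is not None and row["week"] in ds.pct_change:
            row["pct_change_from_week1"] = ds.pct_change[row["week"]]

    # --- repeatability of grey-matter CBF and per-patient change flags ------
    records = [
        (row["subject"], row["gm_median_cbf"]) for row in rows
    ]
    vc = fit_variance_components(RepeatedMeasures.from_records(records))
    changes = {}
    for subject, rec in patients.items():
        st = rec["stats"]
        if len(st) >= 2:
            assessment = detect_significant_change(
                st[0]["ctv_q95"], st[-1]["ctv_q95"], vc
            )
            changes[subject] = {
                "change_ctv_q95": assessment.change,
                "significant": assessment.significant,
                "direction": assessment.direction,
            }

    table = pd.DataFrame(rows)
    validate_cohort_table(table)
    table.to_csv(out_dir / "cohort.csv", index=False, float_format="%.6f")

    report = {
        "config": cfg.to_dict(),
        "n_patients_simulated": len(patients),
        "patient_failures": failures,
        "labelling_efficiency": {
            "median": alpha_summary.median,
            "min": alpha_summary.min,
            "max": alpha_summary.max,
            "n": alpha_summary.n,
            "alpha_used_for_maps": alpha_used,
        },
        "cohort_threshold_ml_per_100g_min": float(threshold),
        "dynamics": {
            "median_pct_change_by_week": {str(k): v for k, v in dynamics.median_pct_change.items()},
            "p_values_by_week": {str(k): v for k, v in dynamics.p_values.items()},
            "n_per_week": {str(k): v for k, v in dynamics.n_per_week.items()},
            "included_subjects": list(dynamics.included_subjects),
            "excluded": {**pre_excluded, **dynamics.excluded},
        },
        "repeatability": {
            "grand_mean": vc.grand_mean,
            "sigma_between": vc.sigma_between,
            "wsd": vc.wsd,
            "wcv_pct": vc.wcv_pct,
            "rc": vc.rc,
            "metric": "gm_median_cbf",
        },
        "change_detection_vs_rc": changes,
        "record_counts": {"cohort_rows": len(rows), "dynamics_series": len(dynamics_series)},
    }
    write_json(report, out_dir / "report.json")

    if cfg.save_nifti:
        for subject, rec in patients.items():
            pdir = out_dir / subject
            pdir.mkdir(exist_ok=True)
            for scan, cbf in zip(rec["scans"], rec["cbf_maps"]):
                stem = f"day{scan.day:03d}"
                save_acquisition(
                    scan.acquisition, pdir / f"{stem}_asl.nii.gz", pdir / f"{stem}_m0.nii.gz"
                )
                save_volume(cbf.values, pdir / f"{stem}_cbf.nii.gz")
                save_volume(scan.truth.gtv_mask, pdir / f"{stem}_gtv.nii.gz")
                save_volume(scan.truth.ctv_mask, pdir / f"{stem}_ctv.nii.gz")

    return table, report
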