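"""Forward simulation of ASL acquisitions from phantom ground truth.

The ASL simulator is the exact inverse of the quantification model: the
control frame is the M0 image plus noise, the label frame is M0 minus the
perfusion-weighted difference dM implied by the true CBF and the true
labelling efficiency, plus noise.  At zero noise the quantification stage
therefore recovers the true CBF to machine precision, which anchors all
round-trip tests.

The Look-Locker simulator produces dynamic carotid difference signals from
the same velocity-dependent inflow model used by the labelling-efficiency
fitter (:mod:`asldyn.labeff`); recovery tests are exact at zero noise by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeff import LookLockerSeries, VelocityModel, forward_ll_signal
from .phantom import GroundTruth, PhantomSpec, ScheduleSpec, build_phantom
from .quantify import AslAcquisition, QuantParams, cbf_scaling_factor
from .regions import assign_week
from .volume import Volume

__all__ = [
    "simulate_asl_acquisition",
    "simulate_look_locker",
    "simulate_longitudinal",
    "simulate_repeat_scans",
    "LongitudinalScan",
]


def true_perfusion_difference(
    truth: GroundTruth, quant: QuantParams, alpha_true: float
) -> np.ndarray:
    """Noise-free dM implied by the true CBF at labelling efficiency alpha_true."""
    params = QuantParams(
        alpha=alpha_true,
        lambda_bp=quant.lambda_bp,
        t1_blood=quant.t1_blood,
        tau=quant.tau,
        pld=quant.pld,
    )
    k = cbf_scaling_factor(params)
    return truth.true_cbf.data * truth.m0_true.data / k


def simulate_asl_acquisition(
    truth: GroundTruth,
    quant: QuantParams,
    alpha_true: float = 0.59,
    noise_sd: float = 0.0,
    n_pairs: int = 8,
    seed: int | np.random.Generator = 0,
) -> AslAcquisition:
    """Simulate an n-pair control/label acquisition plus M0 calibration.

    ``noise_sd`` is the additive Gaussian SD per frame in absolute signal
    units (a fraction of M0 times the phantom's m0_scale in practice).
    """
    if not (0.0 < alpha_true <= 1.0):
        raise ValueError(f"alpha_true must be in (0, 1], got {alpha_true}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m0 = truth.m0_true.data
    dm = true_perfusion_difference(truth, quant, alpha_true)
    vs = truth.m0_true.voxel_size_mm

    def noisy(base: np.ndarray) -> Volume:
        if noise_sd == 0:
            return Volume(base.copy(), vs)
        return Volume(base + rng.normal(0.0, noise_sd, size=base.shape), vs)

    control = tuple(noisy(m0) for _ in range(n_pairs))
    label = tuple(noisy(m0 - dm) for _ in range(n_pairs))
    return AslAcquisition(
        control_frames=control,
        label_frames=label,
        m0=Volume(m0.copy(), vs),
        tau=quant.tau,
        pld=quant.pld,
    )


def simulate_look_locker(
    alpha_true: float,
    weights: np.ndarray | list[float] | None = None,
    model: VelocityModel | None = None,
    m0b: float = 1000.0,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> LookLockerSeries:
    """Simulate left/right internal-carotid Look-Locker difference signals.

    The two arteries share the true labelling efficiency and velocity mixture
    but receive independent noise.  ``noise_sd`` is in absolute signal units
    (same units as ``m0b``).
    """
    model = model if model is not None else VelocityModel()
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size == 0:
            raise ValueError("weights must be nonempty")
        model = model.with_weights(w)
    if times is None:
        times = LookLockerSeries.default_times()
    times = np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = m0b * forward_ll_signal(alpha_true, model, times)
    noise = (
        rng.normal(0.0, noise_sd, size=(2, times.size)) if noise_sd > 0 else np.zeros((2, times.size))
    )
    return LookLockerSeries(
        times=times,
        signal_left=clean + noise[0],
        signal_right=clean + noise[1],
        m0b=m0b,
        alpha_true=alpha_true,
    )


@dataclass(frozen=True)
class LongitudinalScan:
    """One simulated scan of a longitudinal series with its ground truth."""

    day: int
    week: int
    acquisition: AslAcquisition
    truth: GroundTruth
    true_hot_volume_cm3: float


def simulate_longitudinal(
    spec: PhantomSpec,
    schedule: ScheduleSpec,
    quant: QuantParams,
    alpha_true: float = 0.59,
    seed: int | None = None,
) -> list[LongitudinalScan]:
    """Simulate a weekly-shrinking high-CBF subvolume over a scan schedule.

    The hot-subvolume radius is multiplied by ``spec.weekly_hot_shrink`` for
    each completed week (week 1 is unscaled); GTV and CTV stay at their
    baseline definition.  The noise level is ``spec.noise_sd`` times the
    phantom M0 scale per frame.
    """
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    scans: list[LongitudinalScan] = []
    for day in schedule.scan_days:
        week = assign_week(day)
        truth = build_phantom(spec, hot_scale=spec.weekly_hot_shrink ** (week - 1))
        acq = simulate_asl_acquisition(
            truth,
            quant,
            alpha_true=alpha_true,
            noise_sd=spec.noise_sd * spec.m0_scale,
            seed=rng,
        )
        scans.append(
            LongitudinalScan(
                day=day,
                week=week,
                acquisition=acq,
                truth=truth,
                true_hot_volume_cm3=truth.true_hot_volume_cm3,
            )
        )
    return scans


def simulate_repeat_scans(
    truth: GroundTruth,
    quant: QuantParams,
    alpha_true: float = 0.59,
    noise_sd: float = 0.0,
    n_repeats: int = 2,
    seed: int = 0,
) -> list[AslAcquisition]:
    """Repeat acquisitions of one fixed ground truth with independent noise."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 for repeatability estimation")
    rng = np.random.default_rng(seed)
    return [
        simulate_asl_acquisition(
            truth, quant, alpha_true=alpha_true, noise_sd=noise_sd, seed=rng
        )
        for _ in range(n_repeats)
    ]
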