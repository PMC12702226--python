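"""Single post-label-delay CBF quantification with labelling-efficiency correction.

Pseudo-continuous ASL tags arterial water at the neck; after a post-label
delay (PLD) the difference between control and label images is proportional
to perfusion.  This module converts a control/label series plus an M0
calibration volume into cerebral blood flow (CBF) in ml/100 g/min using the
standard single-PLD closed form

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          -----------------------------------------
          2 * alpha * T1b[s] * M0 * (1 - exp(-tau / T1b))

where ``dM`` is the mean control-label difference, ``lambda`` the blood-brain
partition coefficient, ``T1b`` the longitudinal relaxation time of arterial
blood, ``tau`` the label duration and ``alpha`` the labelling efficiency.
CBF is inversely proportional to alpha, so maps computed at one labelling
efficiency can be rescaled exactly to another (:func:`rescale_alpha`) — the
correction required to make MRI-linac CBF comparable to diagnostic scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume import Volume

__all__ = [
    "AslAcquisition",
    "QuantParams",
    "CbfMap",
    "perfusion_difference",
    "quantify_cbf",
    "rescale_alpha",
    "cbf_scaling_factor",
]


@dataclass(frozen=True)
class QuantParams:
    """Constants of the single-PLD quantification model.

    alpha : labelling efficiency, unitless in (0, 1]
    lambda_bp : blood-brain partition coefficient, ml/g
    t1_blood : longitudinal relaxation time of arterial blood, ms (1.5 T value)
    tau : label duration, ms
    pld : post-label delay, ms
    """

    alpha: float = 0.85
    lambda_bp: float = 0.9
    t1_blood: float = 1350.0
    tau: float = 1800.0
    pld: float = 2000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lambda_bp <= 0:
            raise ValueError("lambda_bp must be positive")
        if self.t1_blood <= 0:
            raise ValueError("t1_blood must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.pld < 0:
            raise ValueError("pld must be nonnegative")


@dataclass(frozen=True)
class AslAcquisition:
    """Paired control/label frames plus the M0 calibration volume."""

    control_frames: tuple[Volume, ...]
    label_frames: tuple[Volume, ...]
    m0: Volume
    tau: float = 1800.0
    pld: float = 2000.0

    def __post_init__(self) -> None:
        ctrl = tuple(self.control_frames)
        lab = tuple(self.label_frames)
        if len(ctrl) == 0 or len(ctrl) != len(lab):
            raise ValueError(
                f"need an equal, nonzero number of control and label frames; "
                f"got {len(ctrl)} control, {len(lab)} label"
            )
        for i, frame in enumerate(ctrl + lab):
            self.m0.require_same_grid(frame, what=f"frame {i}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.pld < 0:
            raise ValueError("pld must be nonnegative")
        object.__setattr__(self, "control_frames", ctrl)
        object.__setattr__(self, "label_frames", lab)

    @property
    def n_pairs(self) -> int:
        return len(self.control_frames)


@dataclass(frozen=True)
class CbfMap:
    """A CBF map in ml/100 g/min plus the constants used to compute it."""

    values: Volume
    params_used: QuantParams
    mask_valid: Volume

    def __post_init__(self) -> None:
        self.values.require_same_grid(self.mask_valid, what="validity mask")


def cbf_scaling_factor(params: QuantParams) -> float:
    """The multiplier K such that CBF = K * dM / M0 for the single-PLD model."""
    t1b_s = params.t1_blood / 1000.0
    return (
        6000.0
        * params.lambda_bp
        * np.exp(params.pld / params.t1_blood)
        / (2.0 * params.alpha * t1b_s * (1.0 - np.exp(-params.tau / params.t1_blood)))
    )


def perfusion_difference(acq: AslAcquisition) -> Volume:
    """Mean control-label difference dM over all pairs.

    The label image is darker where labelled (inverted) spins arrive, so
    control - label is nonnegative in expectation and proportional to
    perfusion.
    """
    ctrl = np.stack([f.data for f in acq.control_frames]).astype(float)
    lab = np.stack([f.data for f in acq.label_frames]).astype(float)
    return acq.m0.with_data((ctrl - lab).mean(axis=0))


def quantify_cbf(
    dM: Volume,
    m0: Volume,
    params: QuantParams,
    m0_threshold_frac: float = 0.1,
) -> CbfMap:
    """Convert a perfusion-weighted difference image to CBF in ml/100 g/min.

    Voxels whose M0 falls below ``m0_threshold_frac`` times a robust maximum
    of M0 (the 99th percentile) are marked invalid and set to 0: outside the
    head M0 is essentially noise and the division blows up.
    """
    dM.require_same_grid(m0, what="M0")
    m0_data = np.asarray(m0.data, dtype=float)
    if not np.any(m0_data > 0):
        raise ValueError("M0 volume is entirely non-positive; cannot quantify")
    robust_max = np.percentile(m0_data, 99.0)
    valid = m0_data >= m0_threshold_frac * robust_max
    k = cbf_scaling_factor(params)
    cbf = np.zeros_like(m0_data)
    np.divide(k * np.asarray(dM.data, dtype=float), m0_data, out=cbf, where=valid)
    cbf[~valid] = 0.0
    return CbfMap(
        values=dM.with_data(cbf),
        params_used=params,
        mask_valid=dM.with_data(valid),
    )


def quantify_acquisition(
    acq: AslAcquisition, params: QuantParams, m0_threshold_frac: float = 0.1
) -> CbfMap:
    """Convenience wrapper: perfusion_difference followed by quantify_cbf."""
    params = replace(params, tau=acq.tau, pld=acq.pld)
    return quantify_cbf(perfusion_difference(acq), acq.m0, params, m0_threshold_frac)


def rescale_alpha(cbf: CbfMap, alpha_new: float) -> CbfMap:
    """Rescale a CBF map to a different labelling efficiency.

    CBF is inversely proportional to alpha, so the map fitted at alpha_old
    times alpha_old / alpha_new equals the map fitted directly at alpha_new.
    """
    if not (0.0 < alpha_new <= 1.0):
        raise ValueError(f"alpha_new must be in (0, 1], got {alpha_new}")
    factor = cbf.params_used.alpha / alpha_new
    return CbfMap(
        values=cbf.values.with_data(np.asarray(cbf.values.data, dtype=float) * factor),
        params_used=replace(cbf.params_used, alpha=alpha_new),
        mask_valid=cbf.mask_valid,
    )
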