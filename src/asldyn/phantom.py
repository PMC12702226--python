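"""Digital head phantom with a perfused tumour for end-to-end testing.

The phantom is deliberately simple — an ellipsoidal brain with a grey-matter
shell, white-matter core and central ventricles, split into hemispheres at
the mid-sagittal plane, plus a spherical tumour in one hemisphere with
cavity / rim / high-CBF ("hot") compartments — but it exercises every mask
role the analysis needs: GTV (enhancing tumour + cavity), CTV (margin
expansion including the suspected non-enhancing hot subvolume) and
contralateral grey matter.  The hot subvolume deliberately straddles the GTV
boundary: a configurable fraction of it lies outside the GTV but inside the
CTV, emulating highly perfused non-enhancing tumour.

Every field is generated from a seeded RNG, so an identical spec + seed
yields bit-identical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["Tissue", "PhantomSpec", "GroundTruth", "ScheduleSpec", "build_phantom"]


class Tissue(IntEnum):
    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM = 3
    TUMOUR_RIM = 4
    TUMOUR_HOT = 5
    CAVITY = 6


#: mean CBF per tissue, ml/100 g/min
DEFAULT_TISSUE_CBF: dict[str, float] = {
    "CSF": 2.0,
    "GM": 45.0,
    "WM": 22.0,
    "TUMOUR_RIM": 55.0,
    "TUMOUR_HOT": 100.0,
    "CAVITY": 3.0,
}

#: multiplicative voxelwise spread of CBF per tissue (fraction of the mean).
#: The grey-matter value places the GM 95% quantile near 1.74x the mean,
#: i.e. ~79 ml/100 g/min for a 45 ml/100 g/min mean.
DEFAULT_CBF_JITTER_FRAC: dict[str, float] = {
    "CSF": 0.2,
    "GM": 0.45,
    "WM": 0.3,
    "TUMOUR_RIM": 0.1,
    "TUMOUR_HOT": 0.05,
    "CAVITY": 0.2,
}

#: M0 per tissue relative to grey matter (proton density / T1-weighting proxy)
M0_RELATIVE: dict[str, float] = {
    "CSF": 1.3,
    "GM": 1.0,
    "WM": 0.75,
    "TUMOUR_RIM": 0.9,
    "TUMOUR_HOT": 1.0,
    "CAVITY": 1.2,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    ``noise_sd`` is the additive Gaussian noise SD applied to each simulated
    control/label frame, expressed as a fraction of the grey-matter M0.
    ``hot_outside_gtv_fraction`` is the requested fraction of hot-subvolume
    voxels placed outside the GTV (realised up to voxel quantization).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    tissue_cbf: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_CBF))
    cbf_jitter_frac: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CBF_JITTER_FRAC)
    )
    tumour_centre_mm: tuple[float, float, float] | None = None  # None -> auto
    tumour_radii_mm: tuple[float, float, float] = (22.0, 22.0, 22.0)
    hot_fraction: float = 0.15
    hot_outside_gtv_fraction: float = 0.47
    weekly_hot_shrink: float = 0.8
    ctv_margin_mm: float = 5.0
    m0_scale: float = 1000.0
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if any(v < 0 for v in self.tissue_cbf.values()):
            raise ValueError("all tissue CBF values must be nonnegative")
        if not (0.0 <= self.hot_fraction <= 1.0):
            raise ValueError("hot_fraction must be in [0, 1]")
        if not (0.0 <= self.hot_outside_gtv_fraction <= 1.0):
            raise ValueError("hot_outside_gtv_fraction must be in [0, 1]")
        if not (0.0 < self.weekly_hot_shrink <= 1.0):
            raise ValueError("weekly_hot_shrink must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free ground truth for one simulated patient scan."""

    true_cbf: Volume
    tissue_labels: Volume
    gtv_mask: Volume
    ctv_mask: Volume
    contralateral_gm_mask: Volume
    m0_true: Volume
    hot_mask: Volume
    hemispheres: Volume  # 1 = left, 2 = right, 0 = background

    @property
    def true_hot_volume_cm3(self) -> float:
        return self.hot_mask.count_to_cm3(int(np.count_nonzero(self.hot_mask.data)))


@dataclass(frozen=True)
class ScheduleSpec:
    """ASL scan schedule for one subject; day 1 is the first fraction."""

    subject: str
    scan_days: tuple[int, ...]
    n_weeks: int | None = None

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.scan_days)
        if len(days) == 0:
            raise ValueError("scan_days must be nonempty")
        if any(d < 1 for d in days):
            raise ValueError("scan days must be >= 1 (day 1 = first fraction)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("scan_days must be strictly increasing")
        object.__setattr__(self, "scan_days", days)
        if self.n_weeks is None:
            object.__setattr__(self, "n_weeks", (days[-1] - 1) // 7 + 1)


def _coord_grids(spec: PhantomSpec) -> list[np.ndarray]:
    """Voxel-centre coordinates in mm along each axis (broadcastable)."""
    axes = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    return list(np.meshgrid(*axes, indexing="ij", sparse=True))


def _ellipsoid(coords, centre, radii) -> np.ndarray:
    q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, centre, radii))
    return q <= 1.0


def _metric_dilate(mask: np.ndarray, margin_mm: float, voxel_size) -> np.ndarray:
    """Dilate a boolean mask by a physical margin using a distance transform."""
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return dist <= margin_mm


def _hot_centre(spec: PhantomSpec, coords, tumour_centre, r_hot, gtv, brain, rng):
    """Place the hot sphere so the requested fraction of it lies outside the GTV.

    The sphere is moved along a seed-dependent ray from the tumour centre
    towards the brain interior; the offset is found by bisection on the
    voxelized outside-GTV fraction, so the realised fraction matches the
    request up to voxel quantization.
    """
    target = spec.hot_outside_gtv_fraction
    tilt = 0.3 * rng.uniform(-1.0, 1.0, size=2)
    side = 1.0 if tumour_centre[0] >= spec.fov_mm[0] / 2 else -1.0
    direction = np.array([-side, tilt[0], tilt[1]])
    direction /= np.linalg.norm(direction)

    def outside_frac(d: float) -> float:
        centre = np.asarray(tumour_centre) + d * direction
        hot = _ellipsoid(coords, centre, (r_hot,) * 3) & brain
        n = int(hot.sum())
        if n == 0:
            return 0.0
        return float((hot & ~gtv).sum()) / n

    if target == 0.0:
        return np.asarray(tumour_centre, dtype=float)
    lo, hi = 0.0, float(max(spec.tumour_radii_mm) + r_hot)
    if outside_frac(hi) < target:  # cannot push further without leaving brain
        return np.asarray(tumour_centre) + hi * direction
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if outside_frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.asarray(tumour_centre) + hi * direction


def build_phantom(spec: PhantomSpec, hot_scale: float = 1.0) -> GroundTruth:
    """Construct the ground-truth phantom for one scan.

    ``hot_scale`` multiplies the hot-subvolume radius (used by the
    longitudinal simulator to shrink the region week by week); the GTV and
    CTV are always defined from the baseline (``hot_scale = 1``) geometry,
    mirroring a fixed treatment-planning CTV.
    """
    if not (0.0 <= hot_scale <= 1.0):
        raise ValueError("hot_scale must be in [0, 1]")
    coords = _coord_grids(spec)
    fov = spec.fov_mm
    centre = [f / 2 for f in fov]

    brain_radii = [0.44 * f for f in fov]
    brain = _ellipsoid(coords, centre, brain_radii)
    wm = _ellipsoid(coords, centre, [0.72 * r for r in brain_radii])
    ventricles = _ellipsoid(coords, centre, (12.0, 30.0, 14.0))

    if spec.tumour_centre_mm is None:
        tumour_centre = (centre[0] + 0.5 * brain_radii[0], centre[1] + 8.0, centre[2])
    else:
        tumour_centre = tuple(float(c) for c in spec.tumour_centre_mm)

    # the tumour plus CTV margin must stay on the grid
    for ax, (c, r, f) in enumerate(
        zip(tumour_centre, spec.tumour_radii_mm, fov)
    ):
        if c - r - spec.ctv_margin_mm < 0 or c + r + spec.ctv_margin_mm > f:
            raise ValueError(
                f"tumour (centre {c:g} mm, radius {r:g} mm, margin "
                f"{spec.ctv_margin_mm:g} mm) extends beyond the grid along axis {ax} "
                f"(FOV {f:g} mm)"
            )

    tumour = _ellipsoid(coords, tumour_centre, spec.tumour_radii_mm)
    cavity = _ellipsoid(
        coords, tumour_centre, [0.35 * r for r in spec.tumour_radii_mm]
    )
    gtv = tumour & brain

    rng = np.random.default_rng(spec.seed)
    jitter_field = rng.standard_normal(spec.grid_shape)  # drawn before placement

    r_geo = float(np.prod(spec.tumour_radii_mm)) ** (1.0 / 3.0)
    r_hot_base = spec.hot_fraction ** (1.0 / 3.0) * r_geo
    hot_centre = _hot_centre(
        spec, coords, tumour_centre, r_hot_base, gtv, brain, rng
    )
    hot_base = _ellipsoid(coords, hot_centre, (r_hot_base,) * 3) & brain
    hot = (
        _ellipsoid(coords, hot_centre, (hot_scale * r_hot_base,) * 3) & brain
        if hot_scale < 1.0
        else hot_base
    )

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[brain] = Tissue.GM
    labels[brain & wm] = Tissue.WM
    labels[brain & ventricles] = Tissue.CSF
    labels[gtv] = Tissue.TUMOUR_RIM
    labels[gtv & cavity] = Tissue.CAVITY
    labels[hot] = Tissue.TUMOUR_HOT

    ctv = _metric_dilate(gtv | hot_base, spec.ctv_margin_mm, spec.voxel_size_mm)

    x = coords[0]
    mid = fov[0] / 2.0
    hemis = np.zeros(spec.grid_shape, dtype=np.uint8)
    left = np.broadcast_to(x < mid, spec.grid_shape)
    hemis[brain & left] = 1
    hemis[brain & ~left] = 2
    tumour_side = 2 if tumour_centre[0] >= mid else 1
    contra_side = 1 if tumour_side == 2 else 2
    contra_gm = (labels == Tissue.GM) & (hemis == contra_side) & ~ctv

    cbf = np.zeros(spec.grid_shape, dtype=float)
    m0 = np.zeros(spec.grid_shape, dtype=float)
    for tissue in Tissue:
        if tissue == Tissue.BACKGROUND:
            continue
        sel = labels == tissue
        mean = spec.tissue_cbf.get(tissue.name, 0.0)
        frac = spec.cbf_jitter_frac.get(tissue.name, 0.0)
        cbf[sel] = np.clip(mean * (1.0 + frac * jitter_field[sel]), 0.0, None)
        m0[sel] = spec.m0_scale * M0_RELATIVE.get(tissue.name, 1.0)

    vs = spec.voxel_size_mm
    return GroundTruth(
        true_cbf=Volume(cbf, vs),
        tissue_labels=Volume(labels, vs),
        gtv_mask=Volume(gtv, vs),
        ctv_mask=Volume(ctv, vs),
        contralateral_gm_mask=Volume(contra_gm, vs),
        m0_true=Volume(m0, vs),
        hot_mask=Volume(hot, vs),
        hemispheres=Volume(hemis, vs),
    )
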