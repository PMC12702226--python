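"""Pipeline configuration: a single YAML file with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end demo pipeline needs, in one place.

    Quantification constants follow the single-PLD model: ``alpha`` is the
    labelling efficiency used for the final maps (the consensus 0.85 maps are
    always computed first and rescaled when ``use_measured_alpha`` is on),
    ``lambda_bp`` the partition coefficient (ml/g), ``t1_blood`` (ms),
    ``tau``/``pld`` (ms).  Simulation settings control the synthetic cohort.
    """

    output_dir: str = "asldyn_out"
    seed: int = 0
    log_level: str = "INFO"

    # quantification constants
    alpha: float = 0.59
    alpha_consensus: float = 0.85
    use_measured_alpha: bool = True
    lambda_bp: float = 0.9
    t1_blood: float = 1350.0
    tau: float = 1800.0
    pld: float = 2000.0
    m0_threshold_frac: float = 0.1

    # region analysis
    threshold_override: float | None = None
    connectivity: int = 26
    min_hcbf_volume_cm3: float = 1.0

    # synthetic cohort
    n_patients: int = 6
    n_weeks: int = 4
    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    alpha_true: float = 0.59
    noise_sd: float = 0.002
    weekly_hot_shrink: float = 0.8
    ll_noise_sd_frac: float = 0.01  # Look-Locker noise as a fraction of m0b

    save_nifti: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_consensus", "alpha_true"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("lambda_bp", "t1_blood", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pld < 0:
            raise ValueError("pld must be nonnegative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0 or self.ll_noise_sd_frac < 0:
            raise ValueError("noise levels must be nonnegative")
        self.grid_shape = tuple(int(x) for x in self.grid_shape)
        self.voxel_size_mm = tuple(float(x) for x in self.voxel_size_mm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d
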