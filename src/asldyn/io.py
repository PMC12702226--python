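"""NIfTI / CSV / JSON input-output for the pipeline.

Volumes travel as NIfTI-1 with a diagonal affine built from the voxel sizes;
the voxel sizes on load are taken from the header zooms.  Control/label
series are stored as 4D NIfTI with frames interleaved
control_1, label_1, control_2, label_2, ...
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .labeff import LookLockerSeries
from .quantify import AslAcquisition
from .repeatability import RepeatedMeasures
from .volume import Volume

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "save_acquisition",
    "load_acquisition",
    "load_look_locker_csv",
    "load_repeated_measures_csv",
    "write_json",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_volume(vol: Volume, path: str | Path) -> None:
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol.voxel_size_mm))
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3D payload, got shape {data.shape}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=float), zooms)


def load_mask(path: str | Path) -> Volume:
    vol = load_volume(path)
    vals = np.unique(vol.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(
            f"{Path(path).name}: mask values must be 0/1, found {vals[:8]}"
        )
    return vol.with_data(vol.data.astype(bool))


def save_acquisition(acq: AslAcquisition, series_path: str | Path, m0_path: str | Path) -> None:
    """4D control/label series (interleaved) plus the M0 calibration volume."""
    frames = []
    for c, l in zip(acq.control_frames, acq.label_frames):
        frames.extend([c.data, l.data])
    arr = np.stack(frames, axis=-1)
    vs = acq.m0.voxel_size_mm
    img = nib.Nifti1Image(arr, _affine(vs))
    img.header.set_zooms(vs + (1.0,))
    nib.save(img, str(series_path))
    save_volume(acq.m0, m0_path)


def load_acquisition(
    series_path: str | Path, m0_path: str | Path, tau: float = 1800.0, pld: float = 2000.0
) -> AslAcquisition:
    img = nib.load(str(series_path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] % 2 != 0:
        raise ValueError(
            f"{Path(series_path).name}: expected 4D with an even frame count, "
            f"got shape {arr.shape}"
        )
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    m0 = load_volume(m0_path)
    if m0.shape != arr.shape[:3]:
        raise ValueError(
            f"grid mismatch: series {arr.shape[:3]} vs M0 {m0.shape}"
        )
    control = tuple(Volume(arr[..., i], vs) for i in range(0, arr.shape[-1], 2))
    label = tuple(Volume(arr[..., i], vs) for i in range(1, arr.shape[-1], 2))
    return AslAcquisition(
        control_frames=control, label_frames=label, m0=m0, tau=tau, pld=pld
    )


def load_look_locker_csv(csv_path: str | Path, m0b: float) -> LookLockerSeries:
    """Series CSV with columns time_ms, signal_left, signal_right."""
    df = pd.read_csv(csv_path)
    required = {"time_ms", "signal_left", "signal_right"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{Path(csv_path).name}: missing columns {sorted(missing)}")
    return LookLockerSeries(
        times=df["time_ms"].to_numpy(float),
        signal_left=df["signal_left"].to_numpy(float),
        signal_right=df["signal_right"].to_numpy(float),
        m0b=float(m0b),
    )


def load_repeated_measures_csv(csv_path: str | Path, value_col: str = "value") -> RepeatedMeasures:
    """Long-format CSV with columns subject, scan_day, value."""
    df = pd.read_csv(csv_path)
    for col in ("subject", value_col):
        if col not in df.columns:
            raise ValueError(f"{Path(csv_path).name}: missing column {col!r}")
    return RepeatedMeasures(
        subjects=tuple(df["subject"].astype(str)),
        values=tuple(df[value_col].astype(float)),
        metric=value_col,
    )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
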