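"""Minimal 3D volume container shared by every stage of the pipeline.

A :class:`Volume` couples a 3D array with its voxel dimensions in mm.  All
operations in this package refuse to mix volumes on different grids; the
voxel size is the single source of truth for converting voxel counts to
physical volumes (cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when volumes on incompatible grids are combined."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar or boolean grid with voxel dimensions in mm.

    Parameters
    ----------
    data:
        3D numpy array (any dtype; boolean for masks).
    voxel_size_mm:
        Edge lengths of one voxel along each axis, in mm.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {arr.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def count_to_cm3(self, n_voxels: int) -> float:
        """Convert a voxel count on this grid to a volume in cm^3."""
        return n_voxels * self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_same_grid(self, other: "Volume", what: str = "volume") -> None:
        if self.shape != other.shape:
            raise GridMismatchError(
                f"grid mismatch for {what}: {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.voxel_size_mm, other.voxel_size_mm):
            raise GridMismatchError(
                f"voxel-size mismatch for {what}: "
                f"{self.voxel_size_mm} vs {other.voxel_size_mm}"
            )

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid with different payload."""
        return Volume(data, self.voxel_size_mm)
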