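"""Shared CT data model.

A :class:`CTVolume` is a 3D grid of Hounsfield units with the acquisition
geometry needed for calcium quantification.  One convention is used
throughout the package and asserted at module boundaries:

* axis order is ``(slice, row, col)``;
* all indices are 0-based and all physical distances are in millimetres;
* the centre of voxel ``(k, i, j)`` lies at
  ``(k * slice_increment, i * pixel_size, j * pixel_size)`` mm;
* HU values are stored as floating point, even when the source was
  integer, so that noise models and slab averages are carried exactly.

With overlapping reconstructions (slice thickness larger than the
reconstruction increment) the increment, not the thickness, is the
through-plane dimension that tiles space; all volume computations in this
package therefore use ``pixel_size**2 * slice_increment`` as the voxel
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["CTVolume", "voxel_volume_mm3"]

_MODALITIES = ("native", "contrast")


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units plus its acquisition geometry.

    Parameters
    ----------
    voxels
        3D array of HU, axis order ``(slice, row, col)``.  Stored as
        ``float64``.
    pixel_size
        In-plane pixel edge length, mm (square pixels).
    slice_increment
        Distance between consecutive slice centres, mm.
    slice_thickness
        Nominal reconstructed slice thickness, mm; must be at least the
        increment (overlapping reconstruction is the common case).
    tube_voltage
        Tube voltage in kV (e.g. 120 for native calcium scoring scans,
        100 for contrast-enhanced acquisitions).  Optional metadata.
    modality
        ``"native"`` or ``"contrast"``.
    """

    voxels: np.ndarray
    pixel_size: float
    slice_increment: float
    slice_thickness: float
    tube_voltage: Optional[float] = None
    modality: str = "native"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3D (slice, row, col); got {self.voxels.ndim}D"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.slice_increment > 0):
            raise ValueError(
                f"slice_increment must be > 0, got {self.slice_increment}"
            )
        if self.slice_thickness < self.slice_increment:
            raise ValueError(
                "slice_thickness must be >= slice_increment "
                f"({self.slice_thickness} < {self.slice_increment})"
            )
        if self.modality not in _MODALITIES:
            raise ValueError(
                f"modality must be one of {_MODALITIES}, got {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume tiled by one voxel: pixel_size^2 * slice_increment."""
        return voxel_volume_mm3(self.pixel_size, self.slice_increment)

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Copy of this volume with the voxel grid replaced."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def slice_z_mm(self, index: int) -> float:
        """Physical z coordinate (mm) of a slice centre."""
        return index * self.slice_increment


def voxel_volume_mm3(pixel_size: float, slice_increment: float) -> float:
    return float(pixel_size) ** 2 * float(slice_increment)
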