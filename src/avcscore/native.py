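"""Agatston calcium scoring on native (non-contrast) CT.

The classic score is computed on 3 mm axial slabs: every 2D connected
component of pixels at or above 130 HU (the standard cutoff for 120 kV
acquisitions) and with area >= 1 mm^2 is a lesion; each contributes
``area_mm2 * w`` where the density weight ``w`` depends on the lesion's
maximum attenuation:

====================  ======
max HU                weight
====================  ======
130 - 199               1
200 - 299               2
300 - 399               3
>= 400                  4
====================  ======

Thin overlapping reconstructions (e.g. 1 mm thickness / 0.75 mm
increment) are first averaged into non-overlapping slabs; the calcium
*volume*, by contrast, is measured on the un-slabbed thin-slice volume
using the reconstruction increment as the through-plane voxel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .volume import CTVolume

__all__ = [
    "Lesion",
    "AgatstonResult",
    "DEFAULT_THRESHOLD_HU",
    "DEFAULT_MIN_AREA_MM2",
    "DEFAULT_SLAB_MM",
    "resample_slabs",
    "density_weight",
    "detect_lesions",
    "agatston_score",
    "apply_exclusion",
    "score_native",
]

logger = logging.getLogger("avcscore.native")

DEFAULT_THRESHOLD_HU = 130.0
DEFAULT_MIN_AREA_MM2 = 1.0
DEFAULT_SLAB_MM = 3.0

#: HU value used to blank excluded voxels; below any calcium threshold.
EXCLUDED_HU = -1024.0

# density-weight brackets: (lower bound of max HU, weight)
_WEIGHT_BRACKETS = ((400.0, 4), (300.0, 3), (200.0, 2), (130.0, 1))


@dataclass
class Lesion:
    """One connected calcified component on one slab."""

    slab_index: int
    n_pixels: int
    area_mm2: float
    max_hu: float
    weight: int
    score: float  # area_mm2 * weight

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgatstonResult:
    total_score: float
    volume_mm3: float
    lesions: list[Lesion]
    threshold_hu: float
    slab_thickness_mm: float
    n_suprathreshold_voxels: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesions"] = [l.to_dict() for l in self.lesions]
        return d


def resample_slabs(
    volume: CTVolume, slab_thickness_mm: float = DEFAULT_SLAB_MM
) -> CTVolume:
    """Average consecutive thin slices into non-overlapping thick slabs.

    The slab thickness must be an integer multiple of the slice increment
    (e.g. 3 mm slabs from a 0.75 mm increment -> groups of 4 slices).  A
    trailing incomplete group, if any, is averaged into a final thinner
    slab rather than discarded.
    """
    inc = volume.slice_increment
    group = slab_thickness_mm / inc
    n_per_slab = int(round(group))
    if n_per_slab < 1 or abs(group - n_per_slab) > 1e-9:
        raise ValueError(
            f"slab thickness {slab_thickness_mm} mm is not an integer "
            f"multiple of the slice increment {inc} mm"
        )
    if n_per_slab == 1:
        slabs = volume.voxels.copy()
    else:
        n = volume.n_slices
        n_full = n // n_per_slab
        parts = []
        if n_full:
            head = volume.voxels[: n_full * n_per_slab]
            parts.append(
                head.reshape(n_full, n_per_slab, *head.shape[1:]).mean(axis=1)
            )
        if n % n_per_slab:
            parts.append(
                volume.voxels[n_full * n_per_slab :].mean(axis=0, keepdims=True)
            )
        slabs = np.concatenate(parts, axis=0)
    return CTVolume(
        voxels=slabs,
        pixel_size=volume.pixel_size,
        slice_increment=slab_thickness_mm,
        slice_thickness=slab_thickness_mm,
        tube_voltage=volume.tube_voltage,
        modality=volume.modality,
    )


def density_weight(max_hu: float) -> int:
    """Agatston density weight from a lesion's maximum attenuation."""
    for lower, weight in _WEIGHT_BRACKETS:
        if max_hu >= lower:
            return weight
    raise ValueError(
        f"max HU {max_hu} is below the 130 HU calcium threshold; "
        "no lesion can exist there"
    )


def detect_lesions(
    slabs: CTVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    three_dimensional: bool = False,
) -> list[Lesion]:
    """Find calcified lesions on slabbed native CT.

    Default mode matches the classic definition: per-slab 2D connected
    components (8-connectivity) of pixels with HU >= ``threshold_hu``
    (inclusive), discarding components smaller than ``min_area_mm2``.

    ``three_dimensional=True`` switches to 26-connected 3D components
    across slabs (non-standard; the reported ``slab_index`` is then the
    first slab the component touches and the area is the total voxel
    footprint).
    """
    if slabs.modality != "native":
        raise ValueError(
            f"native lesion detection expects a native volume, "
            f"got modality={slabs.modality!r}"
        )
    pixel_area = slabs.pixel_size**2
    mask = slabs.voxels >= threshold_hu
    lesions: list[Lesion] = []

    def _component_lesion(slab_index, count, max_hu):
        area = count * pixel_area
        if area < min_area_mm2:
            return None
        weight = density_weight(max_hu)
        return Lesion(
            slab_index=int(slab_index),
            n_pixels=int(count),
            area_mm2=float(area),
            max_hu=float(max_hu),
            weight=weight,
            score=float(area * weight),
        )

    if three_dimensional:
        labels = measure.label(mask, connectivity=3)
        for lab in range(1, labels.max() + 1):
            where = labels == lab
            lesion = _component_lesion(
                np.argwhere(where)[:, 0].min(),
                where.sum(),
                slabs.voxels[where].max(),
            )
            if lesion:
                lesions.append(lesion)
        return lesions

    for k in range(slabs.n_slices):
        labels = measure.label(mask[k], connectivity=2)
        if labels.max() == 0:
            continue
        plane = slabs.voxels[k]
        for lab in range(1, labels.max() + 1):
            where = labels == lab
            lesion = _component_lesion(k, where.sum(), plane[where].max())
            if lesion:
                lesions.append(lesion)
    return lesions


def agatston_score(
    lesions: Sequence[Lesion],
    volume: CTVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    slab_thickness_mm: float = DEFAULT_SLAB_MM,
) -> AgatstonResult:
    """Total Agatston score plus calcium volume.

    The score sums per-lesion area x weight over ``lesions``; the calcium
    volume counts suprathreshold voxels of the *un-slabbed* volume times
    ``pixel_size^2 * slice_increment``.
    """
    total = float(sum(l.score for l in lesions))
    n_voxels = int(np.count_nonzero(volume.voxels >= threshold_hu))
    vol_mm3 = n_voxels * volume.voxel_volume_mm3
    return AgatstonResult(
        total_score=total,
        volume_mm3=float(vol_mm3),
        lesions=list(lesions),
        threshold_hu=float(threshold_hu),
        slab_thickness_mm=float(slab_thickness_mm),
        n_suprathreshold_voxels=n_voxels,
    )


def apply_exclusion(volume: CTVolume, exclusion_mask: np.ndarray) -> CTVolume:
    """Blank manually excluded structures (coronaries, aortic wall).

    Excluded voxels are set to -1024 HU, below any calcium threshold, so
    they can never seed or join a lesion.
    """
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if exclusion_mask.shape != volume.shape:
        raise ValueError(
            f"exclusion mask shape {exclusion_mask.shape} does not match "
            f"volume shape {volume.shape}"
        )
    voxels = volume.voxels.copy()
    voxels[exclusion_mask] = EXCLUDED_HU
    return volume.with_voxels(voxels)


def score_native(
    volume: CTVolume,
    exclusion_mask: Optional[np.ndarray] = None,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    slab_thickness_mm: float = DEFAULT_SLAB_MM,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    three_dimensional: bool = False,
) -> AgatstonResult:
    """Full native scoring pipeline: exclude, slab, detect, score."""
    if exclusion_mask is not None:
        volume = apply_exclusion(volume, exclusion_mask)
    slabs = resample_slabs(volume, slab_thickness_mm)
    lesions = detect_lesions(
        slabs, threshold_hu, min_area_mm2, three_dimensional=three_dimensional
    )
    result = agatston_score(lesions, volume, threshold_hu, slab_thickness_mm)
    logger.info(
        "native scoring: threshold=%g HU, slab=%g mm, %d lesions, "
        "score=%.1f, volume=%.1f mm3",
        threshold_hu,
        slab_thickness_mm,
        len(lesions),
        result.total_score,
        result.volume_mm3,
    )
    return result
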