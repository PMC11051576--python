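"""Calcium quantification on contrast-enhanced CT with a dynamic threshold.

Iodinated contrast raises the blood-pool attenuation far above the fixed
130 HU calcium cutoff, so calcium on CECT is segmented against a
patient-specific threshold derived from the luminal enhancement itself:
a circular ROI covering the central two-thirds of the ascending-aorta
lumen area, placed 30 mm above the aortic annulus, yields the luminal
mean and SD, and the threshold is

    threshold = mean + k * SD        (k = 4 by default).

Voxels at or above the threshold inside the valve region (and outside
any manual exclusions) form the contrast-derived calcium volume
AVC_CECT, reported in mm^3 with ``pixel_size^2 * slice_increment`` as
the voxel volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .native import apply_exclusion
from .volume import CTVolume

__all__ = [
    "ROISpec",
    "ROIStats",
    "CECTResult",
    "DEFAULT_K",
    "DEFAULT_ROI_OFFSET_MM",
    "DEFAULT_AREA_FRACTION",
    "place_roi",
    "roi_stats",
    "dynamic_threshold",
    "segment_calcium",
    "score_cect",
]

logger = logging.getLogger("avcscore.cect")

DEFAULT_K = 4.0
DEFAULT_ROI_OFFSET_MM = 30.0
DEFAULT_AREA_FRACTION = 2.0 / 3.0


@dataclass
class ROISpec:
    """A circular luminal reference ROI on one slice.

    ``center_mm`` is (row, col) in mm; the disc holds the voxels whose
    centres lie within ``radius_mm`` of it.
    """

    slice_index: int
    center_mm: tuple[float, float]
    radius_mm: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ROIStats:
    mean_hu: float
    sd_hu: float  # population SD (ddof=0), as scanner consoles report
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("ROI contains no voxels")
        if self.sd_hu < 0:
            raise ValueError("SD must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CECTResult:
    threshold_hu: float
    volume_mm3: float  # AVC_CECT
    n_voxels: int
    roi: Optional[ROIStats] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.roi is not None:
            d["roi"] = self.roi.to_dict()
        return d


def place_roi(
    volume: CTVolume,
    annulus_slice: int,
    lumen_center_mm: tuple[float, float],
    lumen_radius_mm: float,
    offset_mm: float = DEFAULT_ROI_OFFSET_MM,
    area_fraction: float = DEFAULT_AREA_FRACTION,
) -> ROISpec:
    """Place the luminal reference ROI above the annulus.

    The ROI is concentric with the lumen; covering a fraction ``f`` of
    the lumen area means a radius of ``lumen_radius * sqrt(f)``.  The
    slice index is ``annulus_slice + round(offset / slice_increment)``.
    """
    if not (0 < area_fraction <= 1):
        raise ValueError("area_fraction must be in (0, 1]")
    if lumen_radius_mm <= 0:
        raise ValueError("lumen_radius_mm must be > 0")
    slice_index = annulus_slice + int(round(offset_mm / volume.slice_increment))
    if not (0 <= slice_index < volume.n_slices):
        raise ValueError(
            f"ROI slice {slice_index} ({offset_mm} mm above slice "
            f"{annulus_slice}) is outside the {volume.n_slices}-slice volume"
        )
    radius = lumen_radius_mm * float(np.sqrt(area_fraction))
    if radius > lumen_radius_mm - volume.pixel_size:
        logger.warning(
            "ROI radius %.2f mm reaches within one pixel of the lumen "
            "boundary (lumen radius %.2f mm); wall voxels may contaminate "
            "the luminal statistics",
            radius,
            lumen_radius_mm,
        )
    return ROISpec(
        slice_index=slice_index,
        center_mm=tuple(float(c) for c in lumen_center_mm),
        radius_mm=float(radius),
    )


def _disc_mask(volume: CTVolume, roi: ROISpec) -> np.ndarray:
    _, nr, nc = volume.shape
    y = np.arange(nr) * volume.pixel_size
    x = np.arange(nc) * volume.pixel_size
    cy, cx = roi.center_mm
    return (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2 <= roi.radius_mm**2


def roi_stats(volume: CTVolume, roi: ROISpec) -> ROIStats:
    """Mean and population SD of the HU inside the ROI disc."""
    if not (0 <= roi.slice_index < volume.n_slices):
        raise ValueError(f"ROI slice {roi.slice_index} outside volume")
    disc = _disc_mask(volume, roi)
    values = volume.voxels[roi.slice_index][disc]
    if values.size == 0:
        raise ValueError("ROI disc contains no voxel centres")
    return ROIStats(
        mean_hu=float(values.mean()),
        sd_hu=float(values.std(ddof=0)),
        n_voxels=int(values.size),
    )


def dynamic_threshold(stats: ROIStats, k: float = DEFAULT_K) -> float:
    """Patient-specific calcium threshold: luminal mean + k * SD."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return float(stats.mean_hu + k * stats.sd_hu)


def segment_calcium(
    volume: CTVolume,
    threshold_hu: float,
    valve_mask: Optional[np.ndarray] = None,
    exclusion_mask: Optional[np.ndarray] = None,
    roi: Optional[ROIStats] = None,
) -> CECTResult:
    """Suprathreshold calcium volume within the valve region.

    Counts voxels with HU >= ``threshold_hu`` (inclusive) that lie inside
    ``valve_mask`` (the whole grid if None) and outside
    ``exclusion_mask``; the volume uses the reconstruction increment as
    the through-plane voxel dimension.
    """
    if volume.modality != "contrast":
        raise ValueError(
            f"dynamic-threshold segmentation expects a contrast volume, "
            f"got modality={volume.modality!r}"
        )
    if exclusion_mask is not None:
        volume = apply_exclusion(volume, exclusion_mask)
    supra = volume.voxels >= threshold_hu
    if valve_mask is not None:
        valve_mask = np.asarray(valve_mask, dtype=bool)
        if valve_mask.shape != volume.shape:
            raise ValueError(
                f"valve mask shape {valve_mask.shape} does not match "
                f"volume shape {volume.shape}"
            )
        supra &= valve_mask
    n = int(np.count_nonzero(supra))
    result = CECTResult(
        threshold_hu=float(threshold_hu),
        volume_mm3=float(n * volume.voxel_volume_mm3),
        n_voxels=n,
        roi=roi,
    )
    logger.info(
        "CECT segmentation: threshold=%.1f HU, %d voxels, volume=%.1f mm3",
        threshold_hu,
        n,
        result.volume_mm3,
    )
    return result


def score_cect(
    volume: CTVolume,
    annulus_slice: int,
    lumen_center_mm: tuple[float, float],
    lumen_radius_mm: float,
    k: float = DEFAULT_K,
    offset_mm: float = DEFAULT_ROI_OFFSET_MM,
    area_fraction: float = DEFAULT_AREA_FRACTION,
    valve_mask: Optional[np.ndarray] = None,
    exclusion_mask: Optional[np.ndarray] = None,
) -> CECTResult:
    """Full CECT pipeline: place ROI, measure lumen, threshold, segment."""
    roi = place_roi(
        volume,
        annulus_slice,
        lumen_center_mm,
        lumen_radius_mm,
        offset_mm=offset_mm,
        area_fraction=area_fraction,
    )
    stats = roi_stats(volume, roi)
    threshold = dynamic_threshold(stats, k=k)
    logger.info(
        "luminal ROI at slice %d: mean=%.1f HU, sd=%.1f HU (n=%d) -> "
        "threshold %.1f HU",
        roi.slice_index,
        stats.mean_hu,
        stats.sd_hu,
        stats.n_voxels,
        threshold,
    )
    return segment_calcium(
        volume,
        threshold,
        valve_mask=valve_mask,
        exclusion_mask=exclusion_mask,
        roi=stats,
    )
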