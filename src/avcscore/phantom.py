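"""Synthetic CT phantoms with known calcium ground truth.

The phantom is deliberately simple geometry — a contrast-enhanceable
cylindrical aortic lumen plus spherical calcific lesions at the valve
plane and optional distractor calcifications (coronary ostia, aortic
wall) outside it — rendered on the acquisition grid of a retrospectively
gated cardiac CT (square in-plane pixels, thin overlapping slices).
Because lesions are uniform-HU spheres and voxel membership is decided by
the voxel-centre-in-sphere rule, the noiseless volume and hence the
ground truth are exact and analytic, which is what makes the phantoms
usable as oracles for the scoring pipelines.

Geometry conventions (shared with the rest of the package): axis order
``(slice, row, col)``; the centre of voxel ``(k, i, j)`` is at physical
position ``(k * slice_increment, i * pixel_size, j * pixel_size)`` mm.

The module also provides:

* :func:`oracle_agatston` — an independent, deliberately naive per-voxel
  Agatston scorer (pure-Python flood fill, explicit weight brackets) used
  to compute each phantom's true score and to cross-check the production
  scorer;
* :func:`make_paired_cohort` — synthetic paired native-score /
  contrast-volume tables generated from a known linear conversion, for
  exercising calibration and agreement statistics;
* :func:`make_agreement_pairs` — paired measurements from a one-way
  variance-components model with a prescribed population intraclass
  correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .conversion import ConversionModel
from .volume import CTVolume, voxel_volume_mm3

__all__ = [
    "SphereLesion",
    "PhantomSpec",
    "PhantomTruth",
    "make_native_phantom",
    "make_cect_phantom",
    "make_paired_cohort",
    "make_agreement_pairs",
    "noise_sd_for_r2",
    "oracle_agatston",
    "NATIVE_CALCIUM_THRESHOLD_HU",
]

logger = logging.getLogger("avcscore.phantom")

#: Standard native calcium threshold (120 kV); defines the native truth mask.
NATIVE_CALCIUM_THRESHOLD_HU = 130.0


@dataclass
class SphereLesion:
    """A uniform-attenuation spherical calcification.

    ``center_mm`` is (z, row, col) in mm; ``peak_hu`` is the HU assigned
    to every voxel whose centre lies within ``radius_mm`` of the centre.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_hu: float

    def to_dict(self) -> dict:
        z, r, c = self.center_mm
        return {
            "z_mm": z,
            "row_mm": r,
            "col_mm": c,
            "radius_mm": self.radius_mm,
            "peak_hu": self.peak_hu,
        }


def _as_lesions(items: Sequence) -> list[SphereLesion]:
    out = []
    for item in items:
        if isinstance(item, SphereLesion):
            out.append(item)
        elif isinstance(item, dict):
            out.append(
                SphereLesion(
                    tuple(item["center_mm"]), item["radius_mm"], item["peak_hu"]
                )
            )
        else:  # (center, radius, peak) tuple
            center, radius, peak = item
            out.append(SphereLesion(tuple(center), float(radius), float(peak)))
    return out


@dataclass
class PhantomSpec:
    """Full description of a paired native/contrast phantom.

    Parameters
    ----------
    grid_shape
        (slices, rows, cols).
    pixel_size, slice_increment, slice_thickness
        Acquisition geometry in mm; defaults mirror a retrospectively
        gated cardiac protocol (1 mm slices reconstructed every 0.75 mm).
    lumen_center_mm, lumen_radius_mm
        In-plane centre (row, col) and radius of the ascending aorta.
    enhancement_hu
        Mean luminal attenuation on the contrast-enhanced scan.
    native_blood_hu
        Blood-pool attenuation on the native scan.
    background_hu
        Soft-tissue background everywhere else.
    lesions
        Valve calcifications; each must lie within the valve region
        (within ``valve_halfwidth_mm`` of the annulus plane, inside the
        aortic root footprint).
    distractors
        Calcifications outside the valve region (coronary, aortic wall).
    noise_sd
        SD of the additive white Gaussian noise, HU.
    annulus_slice_index
        Slice index of the aortic annulus plane.
    valve_halfwidth_mm
        Half-extent of the valve region along the slice axis.
    roi_offset_mm
        Where the luminal reference ROI will be placed above the annulus;
        the grid must extend at least this far.
    blur_sigma_mm
        Optional Gaussian smoothing of the noiseless volume to mimic
        partial-volume averaging.  Default 0 keeps the analytic truth
        exact.
    seed
        Seed for the noise generator; identical specs render identical
        volumes.
    """

    grid_shape: tuple[int, int, int]
    pixel_size: float = 0.5
    slice_increment: float = 0.75
    slice_thickness: float = 1.0
    lumen_center_mm: tuple[float, float] = (16.0, 16.0)
    lumen_radius_mm: float = 15.0
    enhancement_hu: float = 350.0
    native_blood_hu: float = 40.0
    background_hu: float = 30.0
    lesions: list = field(default_factory=list)
    distractors: list = field(default_factory=list)
    noise_sd: float = 25.0
    annulus_slice_index: int = 10
    valve_halfwidth_mm: float = 5.0
    roi_offset_mm: float = 30.0
    blur_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.lesions = _as_lesions(self.lesions)
        self.distractors = _as_lesions(self.distractors)
        self.validate()

    # -- geometry helpers -------------------------------------------------
    @property
    def annulus_z_mm(self) -> float:
        return self.annulus_slice_index * self.slice_increment

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        ns, nr, nc = self.grid_shape
        return (
            (ns - 1) * self.slice_increment,
            (nr - 1) * self.pixel_size,
            (nc - 1) * self.pixel_size,
        )

    def validate(self) -> None:
        ns, nr, nc = self.grid_shape
        if min(ns, nr, nc) < 1:
            raise ValueError(f"degenerate grid shape {self.grid_shape}")
        if self.pixel_size <= 0 or self.slice_increment <= 0:
            raise ValueError("pixel_size and slice_increment must be > 0")
        if self.slice_thickness < self.slice_increment:
            raise ValueError("slice_thickness must be >= slice_increment")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be > 0")
        if not (0 <= self.annulus_slice_index < ns):
            raise ValueError("annulus_slice_index outside grid")
        # the reference ROI 30 mm (roi_offset_mm) above the annulus must exist
        roi_slice = self.annulus_slice_index + int(
            round(self.roi_offset_mm / self.slice_increment)
        )
        if roi_slice >= ns:
            raise ValueError(
                f"grid too short: luminal ROI slice {roi_slice} "
                f"({self.roi_offset_mm} mm above the annulus) is outside "
                f"the {ns}-slice grid"
            )
        zmax, rmax, cmax = self.extent_mm
        cr, cc = self.lumen_center_mm
        if (
            cr - self.lumen_radius_mm < 0
            or cc - self.lumen_radius_mm < 0
            or cr + self.lumen_radius_mm > rmax
            or cc + self.lumen_radius_mm > cmax
        ):
            raise ValueError("lumen disc extends outside the in-plane grid")
        for kind, spheres in (("lesion", self.lesions), ("distractor", self.distractors)):
            for s in spheres:
                if s.radius_mm <= 0:
                    raise ValueError(f"{kind} radius must be > 0")
                if s.peak_hu <= self.background_hu:
                    raise ValueError(
                        f"{kind} peak HU {s.peak_hu} must exceed the "
                        f"background ({self.background_hu} HU)"
                    )
                z, r, c = s.center_mm
                if (
                    z - s.radius_mm < 0
                    or r - s.radius_mm < 0
                    or c - s.radius_mm < 0
                    or z + s.radius_mm > zmax
                    or r + s.radius_mm > rmax
                    or c + s.radius_mm > cmax
                ):
                    raise ValueError(f"{kind} sphere extends outside the grid")
        hw = self.valve_halfwidth_mm
        az = self.annulus_z_mm
        for s in self.lesions:
            z, r, c = s.center_mm
            in_plane = np.hypot(r - cr, c - cc)
            if abs(z - az) > hw or in_plane > self.lumen_radius_mm:
                raise ValueError(
                    f"lesion at z={z} mm lies outside the valve region "
                    f"(annulus {az} mm +/- {hw} mm, root radius "
                    f"{self.lumen_radius_mm} mm)"
                )
        for s in self.distractors:
            z, r, c = s.center_mm
            in_plane = np.hypot(r - cr, c - cc)
            touches_slab = abs(z - az) <= hw + s.radius_mm
            touches_root = in_plane <= self.lumen_radius_mm + s.radius_mm
            if touches_slab and touches_root:
                raise ValueError(
                    "distractor sphere intersects the valve region; place "
                    "distractors outside it"
                )
        for a in self.lesions:
            for b in self.distractors:
                dist = np.linalg.norm(
                    np.subtract(a.center_mm, b.center_mm)
                )
                if dist <= a.radius_mm + b.radius_mm:
                    raise ValueError(
                        "lesion and distractor spheres overlap; ground "
                        "truth would be ambiguous"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesions"] = [l.to_dict() for l in self.lesions]
        d["distractors"] = [l.to_dict() for l in self.distractors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("lesions", "distractors"):
            items = d.get(key, [])
            d[key] = [
                SphereLesion(
                    (it["z_mm"], it["row_mm"], it["col_mm"]),
                    it["radius_mm"],
                    it["peak_hu"],
                )
                if isinstance(it, dict) and "z_mm" in it
                else it
                for it in items
            ]
        d["grid_shape"] = tuple(d["grid_shape"])
        d["lumen_center_mm"] = tuple(d["lumen_center_mm"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom."""

    calcium_mask: np.ndarray  # bool, valve calcium only
    true_volume_mm3: float
    true_agatston: Optional[float]  # None for contrast phantoms
    lesion_table: pd.DataFrame
    valve_mask: np.ndarray  # bool, the valve region
    distractor_mask: np.ndarray  # bool
    threshold_hu: float  # the threshold defining calcium_mask

    def to_dict(self) -> dict:
        return {
            "true_volume_mm3": self.true_volume_mm3,
            "true_agatston": self.true_agatston,
            "threshold_hu": self.threshold_hu,
            "n_calcium_voxels": int(self.calcium_mask.sum()),
            "lesions": self.lesion_table.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# rendering


def _coords(spec: PhantomSpec):
    ns, nr, nc = spec.grid_shape
    z = np.arange(ns) * spec.slice_increment
    y = np.arange(nr) * spec.pixel_size
    x = np.arange(nc) * spec.pixel_size
    return z, y, x


def _sphere_mask(spec: PhantomSpec, sphere: SphereLesion) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the sphere."""
    z, y, x = _coords(spec)
    cz, cy, cx = sphere.center_mm
    dz2 = (z - cz)[:, None, None] ** 2
    dy2 = (y - cy)[None, :, None] ** 2
    dx2 = (x - cx)[None, None, :] ** 2
    return dz2 + dy2 + dx2 <= sphere.radius_mm**2


def _lumen_footprint(spec: PhantomSpec) -> np.ndarray:
    """In-plane disc of the aorta (2D bool)."""
    _, y, x = _coords(spec)
    cy, cx = spec.lumen_center_mm
    return (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2 <= spec.lumen_radius_mm**2


def _valve_mask(spec: PhantomSpec) -> np.ndarray:
    z, _, _ = _coords(spec)
    in_slab = np.abs(z - spec.annulus_z_mm) <= spec.valve_halfwidth_mm
    return in_slab[:, None, None] & _lumen_footprint(spec)[None, :, :]


def _render_noiseless(spec: PhantomSpec, lumen_hu: float):
    """Background + lumen cylinder + spheres; returns volume and masks.

    The contrast- or blood-filled lumen runs from just above the valve
    region to the top of the grid (the ascending aorta); the valve region
    itself holds leaflet-level tissue at background HU so that calcium is
    the only suprathreshold structure there.
    """
    vol = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    z, _, _ = _coords(spec)
    above_valve = z > spec.annulus_z_mm + spec.valve_halfwidth_mm
    footprint = _lumen_footprint(spec)
    vol[above_valve[:, None, None] & footprint[None, :, :]] = lumen_hu

    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    for s in spec.lesions:
        m = _sphere_mask(spec, s)
        lesion_mask |= m
        vol[m] = np.maximum(vol[m], s.peak_hu)
    distractor_mask = np.zeros(spec.grid_shape, dtype=bool)
    for s in spec.distractors:
        m = _sphere_mask(spec, s)
        distractor_mask |= m
        vol[m] = np.maximum(vol[m], s.peak_hu)

    if spec.blur_sigma_mm > 0:
        sigma_vox = (
            spec.blur_sigma_mm / spec.slice_increment,
            spec.blur_sigma_mm / spec.pixel_size,
            spec.blur_sigma_mm / spec.pixel_size,
        )
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    return vol, lesion_mask, distractor_mask


def _add_noise(noiseless: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sd == 0:
        return noiseless.copy()
    rng = np.random.default_rng(spec.seed)
    return noiseless + rng.normal(0.0, spec.noise_sd, size=noiseless.shape)


def _lesion_table(spec: PhantomSpec, lesion_mask, distractor_mask) -> pd.DataFrame:
    rows = []
    for kind, spheres in (("lesion", spec.lesions), ("distractor", spec.distractors)):
        for s in spheres:
            rec = s.to_dict()
            rec["kind"] = kind
            rec["n_voxels"] = int(_sphere_mask(spec, s).sum())
            rows.append(rec)
    cols = ["kind", "z_mm", "row_mm", "col_mm", "radius_mm", "peak_hu", "n_voxels"]
    return pd.DataFrame(rows, columns=cols)


def _truth(
    spec: PhantomSpec,
    noiseless: np.ndarray,
    lesion_mask: np.ndarray,
    distractor_mask: np.ndarray,
    threshold: float,
    strict: bool,
    agatston: Optional[float],
) -> PhantomTruth:
    if strict:
        supra = noiseless > threshold
    else:
        supra = noiseless >= threshold
    calcium = supra & lesion_mask & ~distractor_mask
    assert not (calcium & distractor_mask).any()
    vol = float(calcium.sum()) * voxel_volume_mm3(
        spec.pixel_size, spec.slice_increment
    )
    return PhantomTruth(
        calcium_mask=calcium,
        true_volume_mm3=vol,
        true_agatston=agatston,
        lesion_table=_lesion_table(spec, lesion_mask, distractor_mask),
        valve_mask=_valve_mask(spec),
        distractor_mask=distractor_mask,
        threshold_hu=float(threshold),
    )


def make_native_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render the native (non-contrast) phantom.

    The truth mask marks lesion voxels whose noiseless attenuation meets
    the standard 130 HU calcium threshold; the true Agatston score is
    computed by this module's brute-force oracle on the noiseless volume
    with distractors blanked (the phantom analogue of the manual
    exclusion step).
    """
    noiseless, lesion_mask, distractor_mask = _render_noiseless(
        spec, lumen_hu=spec.native_blood_hu
    )
    clean = noiseless.copy()
    clean[distractor_mask] = -1024.0
    score, _, _ = oracle_agatston(
        clean, spec.pixel_size, spec.slice_increment
    )
    truth = _truth(
        spec,
        noiseless,
        lesion_mask,
        distractor_mask,
        threshold=NATIVE_CALCIUM_THRESHOLD_HU,
        strict=False,
        agatston=score,
    )
    volume = CTVolume(
        voxels=_add_noise(noiseless, spec),
        pixel_size=spec.pixel_size,
        slice_increment=spec.slice_increment,
        slice_thickness=spec.slice_thickness,
        tube_voltage=120.0,
        modality="native",
    )
    return volume, truth


def make_cect_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render the contrast-enhanced phantom.

    The truth mask marks lesion voxels whose noiseless attenuation lies
    strictly above the patient-specific dynamic threshold
    ``enhancement_hu + 4 * noise_sd``.
    """
    noiseless, lesion_mask, distractor_mask = _render_noiseless(
        spec, lumen_hu=spec.enhancement_hu
    )
    threshold = spec.enhancement_hu + 4.0 * spec.noise_sd
    truth = _truth(
        spec,
        noiseless,
        lesion_mask,
        distractor_mask,
        threshold=threshold,
        strict=True,
        agatston=None,
    )
    volume = CTVolume(
        voxels=_add_noise(noiseless, spec),
        pixel_size=spec.pixel_size,
        slice_increment=spec.slice_increment,
        slice_thickness=spec.slice_thickness,
        tube_voltage=100.0,
        modality="contrast",
    )
    return volume, truth


# ---------------------------------------------------------------------------
# brute-force reference scorer


def oracle_agatston(
    voxels: np.ndarray,
    pixel_size: float,
    slice_increment: float,
    threshold_hu: float = NATIVE_CALCIUM_THRESHOLD_HU,
    min_area_mm2: float = 1.0,
    slab_mm: float = 3.0,
) -> tuple[float, float, list[dict]]:
    """Reference Agatston scorer: explicit loops, no image-analysis library.

    Slabs are means of consecutive thin slices (a trailing incomplete
    group becomes a final thinner slab); components are grown by an
    explicit 8-neighbour flood fill; density weights use the standard
    130/200/300/400 brackets.  Returns ``(score, volume_mm3, lesions)``.

    Intended as an independent oracle for the production scorer, and used
    to compute phantom ground-truth scores.  Complexity is linear in the
    suprathreshold voxel count, so it is fast on phantoms but naive by
    design.
    """
    voxels = np.asarray(voxels, dtype=float)
    group = slab_mm / slice_increment
    n_per = int(round(group))
    if n_per < 1 or abs(group - n_per) > 1e-9:
        raise ValueError("slab_mm must be an integer multiple of the increment")
    n = voxels.shape[0]
    slabs = []
    start = 0
    while start < n:
        stop = min(start + n_per, n)
        slabs.append(voxels[start:stop].mean(axis=0))
        start = stop

    pixel_area = pixel_size**2
    lesions: list[dict] = []
    score = 0.0
    for slab_index, plane in enumerate(slabs):
        above = plane >= threshold_hu
        coords = {(int(i), int(j)) for i, j in np.argwhere(above)}
        visited: set[tuple[int, int]] = set()
        for seed_pixel in sorted(coords):
            if seed_pixel in visited:
                continue
            stack = [seed_pixel]
            visited.add(seed_pixel)
            component = []
            while stack:
                i, j = stack.pop()
                component.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == 0 and dj == 0:
                            continue
                        nb = (i + di, j + dj)
                        if nb in coords and nb not in visited:
                            visited.add(nb)
                            stack.append(nb)
            area = len(component) * pixel_area
            if area < min_area_mm2:
                continue
            max_hu = max(plane[i, j] for i, j in component)
            if max_hu >= 400:
                weight = 4
            elif max_hu >= 300:
                weight = 3
            elif max_hu >= 200:
                weight = 2
            else:
                weight = 1
            contribution = area * weight
            score += contribution
            lesions.append(
                {
                    "slab_index": slab_index,
                    "n_pixels": len(component),
                    "area_mm2": area,
                    "max_hu": float(max_hu),
                    "weight": weight,
                    "score": contribution,
                }
            )
    volume = float(np.count_nonzero(voxels >= threshold_hu)) * pixel_area * slice_increment
    return float(score), volume, lesions


# ---------------------------------------------------------------------------
# synthetic cohorts for the statistical machinery


def make_paired_cohort(
    n: int,
    model: ConversionModel,
    volume_range_mm3: tuple[float, float] = (300.0, 2500.0),
    noise_sd: float = 400.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired native-Agatston / contrast-volume cohort.

    Contrast-derived calcium volumes are uniform on ``volume_range_mm3``;
    the native score is ``model.intercept + model.slope * volume`` plus
    Gaussian noise of SD ``noise_sd`` (Agatston units).  Defaults match a
    severe-aortic-stenosis planning population: volumes of a few hundred
    to a few thousand mm^3 and several hundred units of scatter about the
    conversion line.
    """
    if n < 3:
        raise ValueError("need at least 3 subjects for a calibratable cohort")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = volume_range_mm3
    if not (hi > lo >= 0):
        raise ValueError("volume_range_mm3 must be increasing and non-negative")
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(lo, hi, size=n)
    scores = model.intercept + model.slope * volumes
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "id": [f"S{i:03d}" for i in range(1, n + 1)],
            "native_agatston": scores,
            "cect_volume_mm3": volumes,
        }
    )


def noise_sd_for_r2(
    model: ConversionModel,
    r2: float,
    volume_range_mm3: tuple[float, float] = (300.0, 2500.0),
) -> float:
    """Noise SD giving a prescribed population R^2 for a paired cohort.

    For volumes uniform on (lo, hi), Var(V) = (hi - lo)^2 / 12 and the
    population coefficient of determination of score on volume is
    R^2 = b^2 Var(V) / (b^2 Var(V) + sigma^2).
    """
    if not (0 < r2 < 1):
        raise ValueError("r2 must be in (0, 1)")
    lo, hi = volume_range_mm3
    var_v = (hi - lo) ** 2 / 12.0
    signal = model.slope**2 * var_v
    return float(np.sqrt(signal * (1.0 - r2) / r2))


def make_agreement_pairs(
    n: int,
    icc: float,
    subject_sd: float = 1.0,
    grand_mean: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired measurements with a prescribed population ICC.

    Uses the one-way variance-components model
    ``y_ij = mu + s_i + e_ij`` with ``s_i ~ N(0, sigma_s^2)`` and
    ``e_ij ~ N(0, sigma_e^2)``; the population intraclass correlation is
    ``sigma_s^2 / (sigma_s^2 + sigma_e^2)``, so the error variance is
    solved from the requested value.  No systematic rater effect is
    simulated, making the result equally valid for the absolute-agreement
    two-way forms.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not (0 < icc <= 1):
        raise ValueError("population icc must be in (0, 1]")
    rng = np.random.default_rng(seed)
    var_s = subject_sd**2
    var_e = var_s * (1.0 - icc) / icc
    subj = rng.normal(0.0, subject_sd, size=n)
    e = rng.normal(0.0, np.sqrt(var_e), size=(2, n)) if var_e > 0 else np.zeros((2, n))
    a = grand_mean + subj + e[0]
    b = grand_mean + subj + e[1]
    return a, b
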