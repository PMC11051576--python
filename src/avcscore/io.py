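"""Reading and writing CT volumes, cohort tables and reports.

Volumes travel as NIfTI (``.nii``/``.nii.gz``) with the in-plane pixel
size and slice increment carried in the header zooms.  NIfTI has no
standard slot for slice thickness, tube voltage or modality, so
:func:`write_volume` also writes a small JSON sidecar (``<stem>.meta.json``)
which :func:`read_volume` picks up when present.  Voxels are stored as
float64 so a write/read round trip is bit-exact.

Cohort tables are CSV with columns ``id,native_agatston,cect_volume_mm3``
and optionally ``calc_agatston``.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volume import CTVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "write_mask",
    "read_mask",
    "read_cohort",
    "write_cohort",
    "write_report",
    "validate_report",
    "load_config",
    "COHORT_COLUMNS",
]

logger = logging.getLogger("avcscore.io")

COHORT_COLUMNS = ("id", "native_agatston", "cect_volume_mm3")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".meta.json")
    return path.with_suffix(".meta.json")


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI plus a JSON metadata sidecar.

    The NIfTI data array uses (col, row, slice) axis order — the fastest
    varying axis first, as nibabel expects — with zooms
    ``(pixel_size, pixel_size, slice_increment)``.
    """
    path = Path(path)
    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    affine = np.diag(
        [volume.pixel_size, volume.pixel_size, volume.slice_increment, 1.0]
    )
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms(
        (volume.pixel_size, volume.pixel_size, volume.slice_increment)
    )
    nib.save(img, str(path))
    meta = {
        "slice_thickness_mm": volume.slice_thickness,
        "tube_voltage_kv": volume.tube_voltage,
        "modality": volume.modality,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path: str | Path, modality: Optional[str] = None) -> CTVolume:
    """Read a NIfTI volume into a :class:`CTVolume`.

    Raises ``ValueError`` if the header carries no usable voxel spacing;
    spacing is never silently defaulted.
    """
    path = Path(path)
    img = nib.load(str(path))
    # nibabel silently repairs zero pixdims to 1.0 at load; inspect the
    # raw header so absent spacing is an error, never a silent default
    with nib.openers.ImageOpener(str(path)) as fobj:
        raw_header = nib.Nifti1Header.from_fileobj(fobj, check=False)
    zooms = raw_header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: missing or invalid voxel spacing in NIfTI header "
            f"(zooms={zooms}); refusing to guess"
        )
    px_x, px_y, inc = (float(z) for z in zooms)
    if not np.isclose(px_x, px_y):
        raise ValueError(
            f"{path}: anisotropic in-plane pixels ({px_x} x {px_y} mm) "
            "are not supported"
        )
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    voxels = data.transpose(2, 1, 0)

    thickness = inc
    voltage = None
    file_modality = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        thickness = float(meta.get("slice_thickness_mm", inc))
        voltage = meta.get("tube_voltage_kv")
        file_modality = meta.get("modality")
    return CTVolume(
        voxels=voxels,
        pixel_size=px_x,
        slice_increment=inc,
        slice_thickness=thickness,
        tube_voltage=voltage,
        modality=modality or file_modality or "native",
    )


def read_dicom_series(directory: str | Path, modality: str = "native") -> CTVolume:
    """Convenience reader for a single-series DICOM directory.

    Slices are sorted by ``ImagePositionPatient`` z, pixel values mapped to
    HU via RescaleSlope/RescaleIntercept.  Requires ``pydicom``.
    """
    import pydicom  # optional dependency

    directory = Path(directory)
    datasets = []
    for f in sorted(directory.iterdir()):
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:  # not a DICOM file
                continue
    if not datasets:
        raise ValueError(f"{directory}: no readable DICOM files")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    first = datasets[0]
    px = [float(v) for v in first.PixelSpacing]
    if not np.isclose(px[0], px[1]):
        raise ValueError("anisotropic in-plane pixels are not supported")
    zs = [float(d.ImagePositionPatient[2]) for d in datasets]
    increments = np.diff(zs)
    if len(increments) == 0:
        raise ValueError("need at least two slices to derive the increment")
    if not np.allclose(increments, increments[0], atol=1e-3):
        raise ValueError("non-uniform slice spacing")
    return CTVolume(
        voxels=np.stack(slices),
        pixel_size=px[0],
        slice_increment=float(increments[0]),
        slice_thickness=float(getattr(first, "SliceThickness", increments[0])),
        tube_voltage=float(first.KVP) if hasattr(first, "KVP") else None,
        modality=modality,
    )


def write_mask(
    mask: np.ndarray, pixel_size: float, slice_increment: float, path: str | Path
) -> None:
    """Write a boolean mask as a uint8 NIfTI with the volume's spacing."""
    mask = np.asarray(mask, dtype=np.uint8)
    data = np.ascontiguousarray(mask.transpose(2, 1, 0))
    affine = np.diag([pixel_size, pixel_size, slice_increment, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((pixel_size, pixel_size, slice_increment))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask NIfTI back to a boolean (slice, row, col) array."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data.transpose(2, 1, 0) != 0


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a paired-measurement cohort CSV into a validated DataFrame.

    Required columns: ``id``, ``native_agatston``, ``cect_volume_mm3``;
    optional ``calc_agatston``.  Malformed rows are reported with their
    0-based row index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("native_agatston", "cect_volume_mm3", "calc_agatston"):
        if col not in df.columns:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()].tolist()
        if values.isna().any():
            bad = df.index[values.isna()].tolist()
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at row(s) {bad}"
            )
        df[col] = values.astype(float)
    negative = df.index[df["cect_volume_mm3"] < 0].tolist()
    if negative:
        raise ValueError(
            f"{path}: negative cect_volume_mm3 at row(s) {negative}"
        )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes}")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def _load_report_schema() -> dict:
    text = (
        resources.files("avcscore")
        .joinpath("schemas/agreement_report.schema.json")
        .read_text()
    )
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Validate an agreement-report dict against the packaged schema.

    Checks required keys and primitive types (a deliberately small subset
    of JSON Schema, enough to catch a malformed report before it is
    written).
    """
    schema = _load_report_schema()
    _check_object(report, schema, path="report")


_TYPE_MAP = {
    "number": (int, float),
    "integer": int,
    "string": str,
    "array": (list, tuple),
    "object": dict,
}


def _check_object(obj: dict, schema: dict, path: str) -> None:
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{path}: missing required field {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key not in obj or obj[key] is None:
            continue
        value = obj[key]
        expected = sub.get("type")
        if expected and not isinstance(value, _TYPE_MAP[expected]):
            raise ValueError(
                f"{path}.{key}: expected {expected}, got {type(value).__name__}"
            )
        if expected == "object":
            _check_object(value, sub, f"{path}.{key}")
        if expected == "array" and "minItems" in sub:
            if len(value) < sub["minItems"]:
                raise ValueError(f"{path}.{key}: too few items")


def write_report(report: dict, path: str | Path) -> None:
    """Validate and write an agreement report as JSON."""
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, allow_nan=True))
    logger.info("wrote agreement report to %s", path)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration (thresholds, ROI parameters, phantom specs)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return cfg
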