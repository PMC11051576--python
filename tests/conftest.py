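"""Shared fixtures: programmatically generated phantoms, no stored data."""

from __future__ import annotations

import numpy as np
import pytest

from avcscore import CTVolume, PhantomSpec


def basic_spec(**overrides) -> PhantomSpec:
    """A small paired phantom: one valve lesion, default geometry."""
    kw = dict(
        grid_shape=(55, 80, 80),
        pixel_size=0.5,
        slice_increment=0.75,
        slice_thickness=1.0,
        lumen_center_mm=(20.0, 20.0),
        lumen_radius_mm=15.0,
        enhancement_hu=350.0,
        native_blood_hu=40.0,
        background_hu=30.0,
        lesions=[((7.5, 22.0, 22.0), 2.0, 800.0)],
        distractors=[],
        noise_sd=0.0,
        annulus_slice_index=10,
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def random_small_spec(rng: np.random.Generator, noise: bool = True) -> PhantomSpec:
    """Random compact phantom for oracle-equivalence sweeps.

    Uses a 1.5 mm increment so the grid stays small while still leaving
    the luminal reference plane (30 mm above the annulus) inside it.
    """
    n_lesions = int(rng.integers(1, 4))
    lesions = []
    annulus_z = 3.0  # slice 2 at 1.5 mm increment
    for _ in range(n_lesions):
        radius = float(rng.uniform(1.0, 3.0))
        z = float(rng.uniform(max(radius, annulus_z - 4.0), annulus_z + 4.0))
        r = float(rng.uniform(8.0, 16.0))
        c = float(rng.uniform(8.0, 16.0))
        peak = float(rng.uniform(150.0, 1200.0))
        lesions.append(((z, r, c), radius, peak))
    return PhantomSpec(
        grid_shape=(25, 48, 48),
        pixel_size=0.5,
        slice_increment=1.5,
        slice_thickness=1.5,
        lumen_center_mm=(12.0, 12.0),
        lumen_radius_mm=10.0,
        lesions=lesions,
        noise_sd=float(rng.uniform(0.0, 30.0)) if noise else 0.0,
        annulus_slice_index=2,
        valve_halfwidth_mm=6.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def flat_native_volume(
    plane_hu: np.ndarray, pixel_size: float = 0.5, n_slices: int = 1
) -> CTVolume:
    """Native volume built from one explicit HU plane, 3 mm slices."""
    voxels = np.repeat(plane_hu[np.newaxis].astype(float), n_slices, axis=0)
    return CTVolume(
        voxels=voxels,
        pixel_size=pixel_size,
        slice_increment=3.0,
        slice_thickness=3.0,
        modality="native",
    )


@pytest.fixture
def one_lesion_pair():
    """Noise-free native + contrast phantoms of the same geometry."""
    from avcscore import make_cect_phantom, make_native_phantom

    spec = basic_spec()
    return spec, make_native_phantom(spec), make_cect_phantom(spec)
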