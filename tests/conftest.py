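"""Shared fixtures: desk-scale geometries and a voxel-marching projection oracle."""

import numpy as np
import pytest

from darkfield import (
    DetectorModel,
    MaterialOptics,
    SpherePack,
    SystemGeometry,
    load_preset,
)

MURINE_TISSUE = MaterialOptics(delta=3.10e-07, beta=1.78e-10, label="muscle @ 27.7 keV")
MURINE_AIR = MaterialOptics(delta=2.71e-10, beta=1.42e-13, label="air @ 27.7 keV")


@pytest.fixture(scope="session")
def murine_desk_geometry() -> SystemGeometry:
    """Murine interferometer reduced to a 2x2-pixel field of view, 8 samples/p2."""
    return SystemGeometry(
        design_energy_kev=27.7,
        pixel_pitch=100e-6,
        field_of_view=(2, 2),
        fine_sampling=8,
    )


@pytest.fixture(scope="session")
def murine_detector() -> DetectorModel:
    return DetectorModel(pixel_pitch=100e-6)


@pytest.fixture(scope="session")
def murine_config():
    return load_preset("murine")


@pytest.fixture(scope="session")
def human_config():
    return load_preset("human")


def make_pack(centers, diameter, thickness, extent=1e-3, fraction=0.56, seed=0):
    """Hand-built sphere pack for targeted projection tests."""
    return SpherePack(
        centers=np.asarray(centers, dtype=float),
        diameter=diameter,
        slab_thickness=thickness,
        lateral_extent=((-extent, extent), (-extent, extent)),
        nominal_volume_fraction=fraction,
        seed=seed,
    )


def voxel_air_path(pack, xs, ys, dz):
    """Brute-force z-marching union oracle: march the beam in steps of ``dz``
    and count steps whose midpoint lies inside at least one sphere."""
    r2 = (pack.diameter / 2.0) ** 2
    z = np.arange(0.0, pack.slab_thickness, dz) + dz / 2.0
    out = np.zeros((len(ys), len(xs)))
    cx, cy, cz = pack.centers.T
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            rho2 = (cx - x) ** 2 + (cy - y) ** 2
            near = rho2 < r2
            if not near.any():
                continue
            h2 = r2 - rho2[near]
            inside = (z[:, None] - cz[near][None, :]) ** 2 < h2[None, :]
            out[j, i] = inside.any(axis=1).sum() * dz
    return out
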