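"""Shared fixtures: phantoms, analytic water cylinders, desk-scale configs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from surview3d.phantoms import ThoraxPhantomSpec, generate_phantom
from surview3d.volume import CTVolume


@pytest.fixture(scope="session")
def noiseless_spec() -> ThoraxPhantomSpec:
    return ThoraxPhantomSpec(noise_sigma_hu=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(ThoraxPhantomSpec(seed=7))


def make_water_cylinder(radius_mm: float, *, n_slices: int = 4, half_width_mm: float | None = None,
                        spacing_mm: float = 1.0) -> CTVolume:
    """Axial water cylinder (0 HU inside, air outside) on a 1 mm grid."""
    half = half_width_mm if half_width_mm is not None else radius_mm * 1.2
    n = int(round(2 * half / spacing_mm))
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    Y, X = np.meshgrid(coords, coords, indexing="ij")
    disc = (Y**2 + X**2) <= radius_mm**2
    hu = np.where(disc, 0.0, -1000.0)
    vol = np.broadcast_to(hu, (n_slices, n, n)).copy()
    origin = (0.0, float(coords[0]), float(coords[0]))
    return CTVolume(vol, (spacing_mm, spacing_mm, spacing_mm), origin)


def uniform_box_volume(side_mm: float = 100.0, spacing_mm: float = 4.0, hu: float = -800.0) -> CTVolume:
    """Uniform cube of the given HU centered at the origin, air-free."""
    n = int(round(side_mm / spacing_mm))
    vox = np.full((n, n, n), hu, dtype=np.float64)
    origin = tuple(-(n - 1) / 2.0 * spacing_mm for _ in range(3))
    return CTVolume(vox, (spacing_mm,) * 3, origin)


@pytest.fixture()
def desk_net_config():
    from surview3d.networks import NetworkScaleConfig

    return NetworkScaleConfig.desk_scale(seed=3)


def tiny_run_config(n: int = 6, max_epochs: int = 2, arch: str = "dual", seed: int = 0):
    """A minimal but complete RunConfig for pipeline tests."""
    from surview3d.config import RunConfig
    from surview3d.training import TrainConfig

    cfg = RunConfig()
    return dataclasses.replace(
        cfg,
        arch=arch,
        phantom=dataclasses.replace(cfg.phantom, n=n, seed=seed),
        train=TrainConfig(max_epochs=max_epochs, patience=max_epochs, seed=seed, split=(0.9, 0.1, 2)),
        network=dataclasses.replace(cfg.network, seed=seed),
    )
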