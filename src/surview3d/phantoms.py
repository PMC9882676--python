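"""Seeded synthetic thoracic phantoms with analytic ground-truth masks.

A phantom emulates the gross attenuation structure of a thoracic CT exam on a
small grid: an elliptical soft-tissue body cross-section, two low-attenuation
lung ellipsoids, a high-attenuation spine column near the posterior body wall,
and an air-filled trachea in the superior mediastinum. All shapes are analytic
quadrics rasterized by voxel-center inclusion, so exact ground-truth masks are
available for segmentation and water-equivalent-diameter oracles.

Coordinates are physical mm in the volume frame of :mod:`surview3d.volume`;
by default the volume center sits at the origin, z increases caudally,
y posteriorly, x toward the patient's left.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from .volume import CTVolume

#: Fields whose sizes are scaled multiplicatively by dataset jitter by default.
DEFAULT_JITTER = {
    "body_semi_axes_mm": 0.10,
    "lung_semi_axes_mm": 0.10,
    "lung_centers_mm": 0.05,
    "spine_radius_mm": 0.10,
}

_JITTERABLE = (
    "body_semi_axes_mm",
    "lung_semi_axes_mm",
    "lung_centers_mm",
    "spine_center_yx_mm",
    "spine_radius_mm",
    "trachea_radius_mm",
    "body_hu",
    "lung_hu",
    "spine_hu",
)


@dataclass
class ThoraxPhantomSpec:
    """Seeded parameter set that fully determines one phantom volume.

    Lengths in mm, intensities in HU. ``lung_centers_mm`` and
    ``lung_semi_axes_mm`` are (z, y, x) triples for the right and left lung;
    the trachea is an air cylinder of radius ``trachea_radius_mm`` on the
    midline (y = 0, x = 0) occupying the superior half of the volume.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semi_axes_mm: tuple[float, float] = (80.0, 105.0)  # (a_y, a_x)
    body_hu: float = 40.0
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, -50.0),  # patient right
        (0.0, 0.0, 50.0),  # patient left
    )
    lung_semi_axes_mm: tuple[tuple[float, float, float], ...] = (
        (85.0, 45.0, 30.0),
        (85.0, 45.0, 30.0),
    )
    lung_hu: float = -800.0
    spine_center_yx_mm: tuple[float, float] = (55.0, 0.0)
    spine_radius_mm: float = 12.0
    spine_hu: float = 700.0
    trachea_radius_mm: float = 8.0
    trachea_hu: float = -1000.0
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` on geometry that violates the phantom contract."""
        errors = []
        if any(int(n) < 2 for n in self.grid_shape):
            errors.append(f"grid_shape too small: {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            errors.append(f"non-positive spacing: {self.spacing_mm}")
        for name in ("spine_radius_mm", "trachea_radius_mm"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.noise_sigma_hu < 0:
            errors.append("noise_sigma_hu must be >= 0")
        a_y, a_x = self.body_semi_axes_mm
        if a_y <= 0 or a_x <= 0:
            errors.append(f"body semi-axes must be > 0: {self.body_semi_axes_mm}")
        # Lungs inside the body ellipse: sample each lung's (y, x) silhouette.
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        for k, (center, semi) in enumerate(zip(self.lung_centers_mm, self.lung_semi_axes_mm)):
            if any(s <= 0 for s in semi):
                errors.append(f"lung {k} semi-axes must be > 0: {semi}")
                continue
            _, cy, cx = center
            _, by, bx = semi
            y = cy + by * np.sin(theta)
            x = cx + bx * np.cos(theta)
            if np.any((y / a_y) ** 2 + (x / a_x) ** 2 > 1.0):
                errors.append(f"lung {k} not contained in body ellipse")
            # Spine disjoint from lungs, checked in the (y, x) plane: overlap
            # iff the spine center falls inside the lung silhouette or the
            # silhouette boundary comes within one spine radius of it.
            sy, sx = self.spine_center_yx_mm
            center_inside = ((cy - sy) / by) ** 2 + ((cx - sx) / bx) ** 2 <= 1.0
            if center_inside or np.any(np.hypot(y - sy, x - sx) < self.spine_radius_mm):
                errors.append(f"spine overlaps lung {k}")
        if errors:
            raise ValueError("invalid phantom spec: " + "; ".join(errors))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ThoraxPhantomSpec":
        raw = json.loads(text)

        def _tup(v):
            return tuple(_tup(x) for x in v) if isinstance(v, list) else v

        return cls(**{k: _tup(v) for k, v in raw.items()})


@dataclass
class PhantomSample:
    """A phantom volume with its analytic ground-truth masks."""

    volume: CTVolume
    lung_mask: np.ndarray
    body_mask: np.ndarray
    spec: ThoraxPhantomSpec

    def __post_init__(self) -> None:
        if self.lung_mask.shape != self.volume.shape or self.body_mask.shape != self.volume.shape:
            raise ValueError("masks and volume must share shape")
        if np.any(self.lung_mask & ~self.body_mask):
            raise ValueError("lung_mask must be a subset of body_mask")


def _physical_grids(spec: ThoraxPhantomSpec):
    """Per-axis voxel-center coordinates (mm), volume center at 0."""
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def phantom_origin_mm(spec: ThoraxPhantomSpec) -> tuple[float, float, float]:
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    return tuple(-(shape - 1) / 2.0 * spacing)


def generate_phantom(spec: ThoraxPhantomSpec) -> PhantomSample:
    """Rasterize a phantom spec into a volume plus ground-truth masks.

    Painting order (later wins): air background, body ellipse, lungs, spine,
    trachea. Masks are computed from the analytic shapes *before* noise, and
    the output is byte-identical for equal specs.
    """
    spec.validate()
    z, y, x = _physical_grids(spec)
    Y, X = np.meshgrid(y, x, indexing="ij")

    a_y, a_x = spec.body_semi_axes_mm
    body2d = (Y / a_y) ** 2 + (X / a_x) ** 2 <= 1.0
    body_mask = np.broadcast_to(body2d, spec.grid_shape).copy()

    hu = np.full(spec.grid_shape, -1000.0, dtype=np.float64)
    hu[body_mask] = spec.body_hu

    lung_mask = np.zeros(spec.grid_shape, dtype=bool)
    Z3 = z[:, None, None]
    for center, semi in zip(spec.lung_centers_mm, spec.lung_semi_axes_mm):
        cz, cy, cx = center
        az, ay_, ax_ = semi
        ell = (
            ((Z3 - cz) / az) ** 2
            + ((Y[None] - cy) / ay_) ** 2
            + ((X[None] - cx) / ax_) ** 2
        ) <= 1.0
        lung_mask |= ell
    hu[lung_mask] = spec.lung_hu

    sy, sx = spec.spine_center_yx_mm
    spine2d = (Y - sy) ** 2 + (X - sx) ** 2 <= spec.spine_radius_mm**2
    spine = np.broadcast_to(spine2d, spec.grid_shape) & body_mask
    hu[spine] = spec.spine_hu

    trachea2d = Y**2 + X**2 <= spec.trachea_radius_mm**2
    superior = (z <= 0.0)[:, None, None]
    trachea = np.broadcast_to(trachea2d, spec.grid_shape) & superior & body_mask
    hu[trachea] = spec.trachea_hu

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, size=spec.grid_shape)

    volume = CTVolume(hu, spec.spacing_mm, phantom_origin_mm(spec))
    return PhantomSample(volume, lung_mask, body_mask, spec)


def _jitter_value(value, factor_stream, frac: float):
    """Multiplicatively jitter every numeric component of a (nested) field."""
    if isinstance(value, tuple):
        return tuple(_jitter_value(v, factor_stream, frac) for v in value)
    return float(value) * (1.0 + frac * (2.0 * next(factor_stream) - 1.0))


def jittered_spec(base: ThoraxPhantomSpec, jitter: dict, rng: np.random.Generator) -> ThoraxPhantomSpec:
    """Draw one spec around ``base`` with per-field fractional jitter.

    Each numeric component of a jittered field is scaled by an independent
    uniform factor in ``[1 - f, 1 + f]``; zero-valued components (e.g. centered
    coordinates) are left untouched by construction.
    """
    updates = {}
    for name, frac in jitter.items():
        if name not in _JITTERABLE:
            raise KeyError(f"field {name!r} is not jitterable")
        if not 0.0 <= frac <= 0.5:
            raise ValueError(f"jitter fraction for {name!r} must be in [0, 0.5], got {frac}")
        if frac == 0.0:
            continue
        draws = iter(rng.uniform(0.0, 1.0, size=64).tolist())
        updates[name] = _jitter_value(getattr(base, name), draws, frac)
    updates["seed"] = int(rng.integers(0, 2**31 - 1))
    spec = dataclasses.replace(base, **updates)
    spec.validate()
    return spec


def generate_dataset(
    n: int,
    base_spec: ThoraxPhantomSpec | None = None,
    jitter: dict | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` jittered phantoms, each reproducible from ``(seed, i)``.

    Sample ``i`` draws its parameters from an independent stream seeded by
    ``(seed, i)``, so it is identical regardless of ``n`` and of the other
    samples. Raises if jitter pushes a spec outside its geometric invariants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec = base_spec if base_spec is not None else ThoraxPhantomSpec()
    jitter = DEFAULT_JITTER if jitter is None else jitter
    samples = []
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        try:
            spec = jittered_spec(base_spec, jitter, rng)
        except ValueError as err:
            raise ValueError(
                f"jitter produced an invalid spec for sample {i} (over-aggressive jitter): {err}"
            ) from err
        samples.append(generate_phantom(spec))
    return samples


# ---------------------------------------------------------------------------
# HDF5 dataset container
# ---------------------------------------------------------------------------

def save_dataset(samples: list[PhantomSample], path: str | os.PathLike, *, meta: dict | None = None) -> None:
    """Write phantoms to one HDF5 file (groups /samples/<i>/{volume,masks,meta})."""
    import h5py

    with h5py.File(os.fspath(path), "w") as f:
        for k, v in (meta or {}).items():
            f.attrs[k] = v
        for i, s in enumerate(samples):
            g = f.create_group(f"samples/{i:04d}")
            g.create_dataset("volume", data=s.volume.voxels)
            g.create_dataset("lung_mask", data=s.lung_mask.astype(np.uint8))
            g.create_dataset("body_mask", data=s.body_mask.astype(np.uint8))
            g.attrs["spacing_mm"] = s.volume.spacing
            g.attrs["origin_mm"] = s.volume.origin
            g.attrs["seed"] = s.spec.seed
            g.attrs["spec_json"] = s.spec.to_json()


def load_dataset(path: str | os.PathLike) -> list[PhantomSample]:
    import h5py

    samples = []
    with h5py.File(os.fspath(path), "r") as f:
        for name in sorted(f["samples"]):
            g = f[f"samples/{name}"]
            spec = ThoraxPhantomSpec.from_json(g.attrs["spec_json"])
            volume = CTVolume(
                g["volume"][()],
                tuple(float(s) for s in g.attrs["spacing_mm"]),
                tuple(float(o) for o in g.attrs["origin_mm"]),
            )
            samples.append(
                PhantomSample(volume, g["lung_mask"][()].astype(bool), g["body_mask"][()].astype(bool), spec)
            )
    return samples
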