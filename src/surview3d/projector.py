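"""Cone-beam topogram synthesis by exact voxel-border ray traversal.

A fixed X-ray point source illuminates a flat virtual detector behind the
patient. For each detector pixel, the ray from the source through the pixel
center is traversed voxel border to voxel border through the volume; the sum
of (intersection length x relative attenuation) over the visited voxels is the
ray's line integral, and the Beer-Lambert law

    I = I0 * exp(-mu_water * sum_i mu_rel(i) * dx_i)

turns it into a detector intensity. The traversal is exact for the
piecewise-constant voxel field (it is the classic plane-crossing / Siddon
construction): the crossing parameters of the ray with all x-, y- and z-grid
planes are merged and sorted, and each inter-crossing segment is attributed to
the voxel containing its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume import CTVolume, hu_to_relative_attenuation

#: Linear attenuation coefficient of water, mm^-1, at ~70 keV effective energy.
MU_WATER_PER_MM = 0.0192

_VIEWS = ("coronal", "sagittal")


@dataclass
class SourceDetectorGeometry:
    """Source / detector layout for one topogram view.

    The source sits on the anterior-posterior axis (coronal view) or on the
    left-right axis (sagittal view) through the volume center, at
    ``source_to_isocenter_mm`` from it; the detector plane is perpendicular to
    that axis at ``source_to_detector_mm`` from the source. Geometric
    magnification is ``source_to_detector_mm / source_to_isocenter_mm``.
    """

    view: str
    source_to_isocenter_mm: float = 600.0
    source_to_detector_mm: float = 1100.0
    detector_pixels: tuple[int, int] = (128, 128)
    detector_pitch_mm: float = 4.0
    i0: float = 1.0

    def __post_init__(self) -> None:
        if self.view not in _VIEWS:
            raise ValueError(f"view must be one of {_VIEWS}, got {self.view!r}")
        if not self.source_to_detector_mm > self.source_to_isocenter_mm > 0:
            raise ValueError(
                "need source_to_detector_mm > source_to_isocenter_mm > 0, got "
                f"{self.source_to_detector_mm}, {self.source_to_isocenter_mm}"
            )
        if any(int(p) < 1 for p in self.detector_pixels):
            raise ValueError(f"detector_pixels must be positive, got {self.detector_pixels}")
        if self.detector_pitch_mm <= 0:
            raise ValueError("detector_pitch_mm must be > 0")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm


@dataclass
class RayPath:
    """Ordered voxel visits of one ray: ``segments`` of (index triple, mm)."""

    segments: list[tuple[tuple[int, int, int], float]]
    entry_point: np.ndarray
    exit_point: np.ndarray

    @property
    def total_length_mm(self) -> float:
        return float(sum(dx for _, dx in self.segments))


@dataclass
class Topogram:
    """Detector-plane images of one view.

    ``line_integral`` is the dimensionless ``-ln(I/I0)`` image (i.e. already
    multiplied by mu_water); ``intensity`` is ``i0 * exp(-line_integral)``.
    Row 0 is superior; column 0 is the patient's left (coronal) or anterior
    (sagittal).
    """

    intensity: np.ndarray
    line_integral: np.ndarray
    geometry: SourceDetectorGeometry

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.line_integral = np.asarray(self.line_integral, dtype=np.float64)
        if self.intensity.shape != self.line_integral.shape:
            raise ValueError("intensity and line_integral must share shape")
        if np.any(self.line_integral < 0):
            raise ValueError("line_integral must be >= 0")
        expected = self.geometry.i0 * np.exp(-self.line_integral)
        if not np.allclose(self.intensity, expected, rtol=1e-6):
            raise ValueError("intensity inconsistent with i0 * exp(-line_integral)")

    def normalized(self) -> np.ndarray:
        """Min-max normalize the line-integral image to [0, 1] (network input)."""
        lo = float(self.line_integral.min())
        hi = float(self.line_integral.max())
        if hi <= lo:
            return np.zeros_like(self.line_integral, dtype=np.float32)
        return ((self.line_integral - lo) / (hi - lo)).astype(np.float32)


def build_geometry(
    view: str,
    volume: CTVolume,
    overrides: dict | None = None,
) -> SourceDetectorGeometry:
    """Default geometry for a view of ``volume``: 600/1100 mm distances and a
    detector pitch that spans 1.2x the magnified volume extent in both
    detector directions."""
    geo = SourceDetectorGeometry(view=view)
    overrides = dict(overrides or {})
    pitch_override = overrides.pop("detector_pitch_mm", None)
    geo = replace(geo, **overrides)
    rows, cols = (int(p) for p in geo.detector_pixels)
    extent = volume.extent_mm  # (z, y, x)
    col_extent = extent[2] if view == "coronal" else extent[1]
    m = geo.magnification
    pitch = max(1.2 * m * extent[0] / rows, 1.2 * m * col_extent / cols)
    geo = replace(geo, detector_pitch_mm=float(pitch_override if pitch_override is not None else pitch))
    return geo


def geometry_rays(geometry: SourceDetectorGeometry, volume: CTVolume):
    """Source position and per-pixel detector target coordinates (mm).

    Returns ``(source (3,), targets (rows*cols, 3))`` in volume coordinates
    (z, y, x). Row index runs superior -> inferior; column index runs patient
    left -> right (coronal) or anterior -> posterior (sagittal).
    """
    c = volume.center_mm
    rows, cols = (int(p) for p in geometry.detector_pixels)
    pitch = geometry.detector_pitch_mm
    source = c.copy()
    det_center = c.copy()
    axis = 1 if geometry.view == "coronal" else 2
    source[axis] = c[axis] - geometry.source_to_isocenter_mm
    det_center[axis] = c[axis] + (geometry.source_to_detector_mm - geometry.source_to_isocenter_mm)

    r = np.arange(rows)
    col = np.arange(cols)
    z_r = det_center[0] + (r - (rows - 1) / 2.0) * pitch  # row 0 superior
    if geometry.view == "coronal":
        # column 0 = patient left = largest x
        u_c = det_center[2] + ((cols - 1) / 2.0 - col) * pitch
        u_axis = 2
    else:
        # column 0 = anterior = smallest y
        u_c = det_center[1] + (col - (cols - 1) / 2.0) * pitch
        u_axis = 1
    Z, U = np.meshgrid(z_r, u_c, indexing="ij")
    targets = np.empty((rows * cols, 3), dtype=np.float64)
    targets[:, 0] = Z.ravel()
    targets[:, axis] = det_center[axis]
    targets[:, u_axis] = U.ravel()
    return source, targets


# ---------------------------------------------------------------------------
# Exact traversal
# ---------------------------------------------------------------------------

def _grid_bounds(shape, spacing, origin):
    lo = np.asarray(origin, dtype=np.float64) - np.asarray(spacing) / 2.0
    hi = lo + np.asarray(shape) * np.asarray(spacing)
    return lo, hi


def integrate_rays(
    mu: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    source: np.ndarray,
    targets: np.ndarray,
    chunk: int = 4096,
) -> np.ndarray:
    """Line integrals (mm) of ``mu`` along source->target segments, batched.

    Exact plane-crossing traversal, fully vectorized over rays. Rays that miss
    the volume contribute 0.
    """
    mu = np.asarray(mu, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    lo, hi = _grid_bounds(mu.shape, spacing, origin)
    planes = [lo[k] + np.arange(mu.shape[k] + 1) * spacing[k] for k in range(3)]

    out = np.zeros(len(targets))
    for start in range(0, len(targets), chunk):
        t = targets[start : start + chunk]
        d = t - source  # (R, 3)
        length = np.linalg.norm(d, axis=1)
        # slab clipping per axis
        amin = np.zeros(len(t))
        amax = np.ones(len(t))
        miss = length == 0
        for k in range(3):
            dk = d[:, k]
            with np.errstate(divide="ignore", invalid="ignore"):
                a1 = (lo[k] - source[k]) / dk
                a2 = (hi[k] - source[k]) / dk
            near = np.minimum(a1, a2)
            far = np.maximum(a1, a2)
            par = dk == 0
            inside = (source[k] >= lo[k]) & (source[k] <= hi[k])
            amin = np.where(par, amin, np.maximum(amin, near))
            amax = np.where(par, amax, np.minimum(amax, far))
            miss |= par & ~inside
        miss |= amin >= amax

        alphas = [np.broadcast_to(((planes[k][None, :] - source[k])), (len(t), len(planes[k]))) for k in range(3)]
        cols = []
        for k in range(3):
            dk = d[:, k]
            with np.errstate(divide="ignore", invalid="ignore"):
                a = alphas[k] / dk[:, None]
            a = np.where((dk == 0)[:, None] | ~np.isfinite(a), amin[:, None], a)
            cols.append(a)
        a_all = np.concatenate(cols + [amin[:, None], amax[:, None]], axis=1)
        a_all = np.clip(a_all, amin[:, None], amax[:, None])
        a_all.sort(axis=1)
        seg = np.diff(a_all, axis=1)  # (R, M)
        mids = (a_all[:, :-1] + a_all[:, 1:]) / 2.0
        # voxel index of each segment midpoint
        pos = source[None, None, :] + mids[:, :, None] * d[:, None, :]
        idx = np.floor((pos - lo[None, None, :]) / spacing[None, None, :]).astype(np.int64)
        valid = (seg > 1e-12) & np.all((idx >= 0) & (idx < np.asarray(mu.shape)), axis=2)
        idx = np.clip(idx, 0, np.asarray(mu.shape) - 1)
        vals = mu[idx[..., 0], idx[..., 1], idx[..., 2]]
        integ = np.sum(np.where(valid, vals * seg, 0.0), axis=1) * length
        out[start : start + chunk] = np.where(miss, 0.0, integ)
    return out


def trace_ray(
    mu: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    source,
    target,
) -> tuple[RayPath, float]:
    """Traverse one ray and return its voxel path and line integral (mm).

    The source must lie outside the volume bounding box. A ray that misses the
    volume returns an empty path and integral 0. Segment lengths are geometric
    intersection lengths with each voxel; crossing degeneracies (edges and
    corners) produce zero-length segments, which are dropped.
    """
    mu = np.asarray(mu, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    lo, hi = _grid_bounds(mu.shape, spacing, origin)
    if np.all((source >= lo) & (source <= hi)):
        raise ValueError("source lies inside the volume bounding box (undefined entry)")
    d = target - source
    length = float(np.linalg.norm(d))
    if length == 0:
        return RayPath([], source.copy(), source.copy()), 0.0

    amin, amax = 0.0, 1.0
    for k in range(3):
        if d[k] == 0:
            if not (lo[k] <= source[k] <= hi[k]):
                return RayPath([], source.copy(), source.copy()), 0.0
            continue
        a1 = (lo[k] - source[k]) / d[k]
        a2 = (hi[k] - source[k]) / d[k]
        amin = max(amin, min(a1, a2))
        amax = min(amax, max(a1, a2))
    if amin >= amax:
        return RayPath([], source.copy(), source.copy()), 0.0

    alphas = [np.array([amin, amax])]
    for k in range(3):
        if d[k] == 0:
            continue
        a = (lo[k] + np.arange(mu.shape[k] + 1) * spacing[k] - source[k]) / d[k]
        alphas.append(a[(a > amin) & (a < amax)])
    a_all = np.unique(np.concatenate(alphas))
    seg = np.diff(a_all)
    mids = (a_all[:-1] + a_all[1:]) / 2.0
    pos = source[None, :] + mids[:, None] * d[None, :]
    idx = np.floor((pos - lo[None, :]) / spacing[None, :]).astype(np.int64)

    segments: list[tuple[tuple[int, int, int], float]] = []
    integral = 0.0
    shape = mu.shape
    for m in range(len(seg)):
        dx = float(seg[m] * length)
        if dx <= 1e-12 * length:
            continue  # degenerate edge/corner crossing
        i, j, k = (int(idx[m, 0]), int(idx[m, 1]), int(idx[m, 2]))
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            continue
        segments.append(((i, j, k), dx))
        integral += mu[i, j, k] * dx
    entry = source + amin * d
    exit_ = source + amax * d
    return RayPath(segments, entry, exit_), float(integral)


def line_integral_oracle(
    mu: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    source,
    target,
    step_mm: float,
) -> float:
    """Independent Riemann-sum line integral (mm): nearest-voxel sampling at a
    uniform step along the segment. Converges to :func:`trace_ray`'s exact
    value as ``step_mm`` shrinks."""
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    mu = np.asarray(mu, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    d = target - source
    length = float(np.linalg.norm(d))
    if length == 0:
        return 0.0
    n = max(1, int(np.ceil(length / step_mm)))
    t = (np.arange(n) + 0.5) * (length / n)
    pts = source[None, :] + (t / length)[:, None] * d[None, :]
    idx = np.round((pts - origin[None, :]) / spacing[None, :]).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(mu.shape)), axis=1)
    idx = np.clip(idx, 0, np.asarray(mu.shape) - 1)
    vals = np.where(inside, mu[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
    return float(vals.sum() * (length / n))


def synthesize_topogram(
    volume: CTVolume,
    geometry: SourceDetectorGeometry,
    mu_water_per_mm: float = MU_WATER_PER_MM,
) -> Topogram:
    """Ray-trace one topogram of ``volume`` under ``geometry``.

    One ray per detector pixel, through the pixel center. The stored
    line-integral image is ``mu_water * sum mu_rel * dx`` (dimensionless), and
    ``intensity = i0 * exp(-line_integral)``.
    """
    mu = hu_to_relative_attenuation(volume)
    source, targets = geometry_rays(geometry, volume)
    ints_mm = integrate_rays(mu, volume.spacing, volume.origin, source, targets)
    line_integral = (mu_water_per_mm * ints_mm).reshape(geometry.detector_pixels)
    intensity = geometry.i0 * np.exp(-line_integral)
    return Topogram(intensity, line_integral, geometry)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_topogram_png(topogram: Topogram, path) -> None:
    """Write the line-integral image windowed to the full 16-bit range."""
    import imageio.v3 as iio

    img = topogram.line_integral
    lo, hi = float(img.min()), float(img.max())
    scale = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    iio.imwrite(path, (scale * 65535).astype(np.uint16))


def save_topogram_hdf5(topogram: Topogram, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=topogram.intensity)
        f.create_dataset("line_integral", data=topogram.line_integral)
        g = topogram.geometry
        for k in (
            "view",
            "source_to_isocenter_mm",
            "source_to_detector_mm",
            "detector_pitch_mm",
            "i0",
        ):
            f.attrs[k] = getattr(g, k)
        f.attrs["detector_pixels"] = g.detector_pixels
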