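"""Core CT volume data model, HU <-> attenuation conversion, and I/O.

Volumes are stored as ``(z, y, x)`` arrays of Hounsfield units (HU):

* ``z`` — axial / cranio-caudal axis, index 0 superior;
* ``y`` — anterior-posterior axis, index 0 anterior;
* ``x`` — left-right axis, index 0 patient right.

Voxel indices are 0-based and the physical coordinate of voxel ``i`` is
``origin + i * spacing`` (voxel-center convention), all in millimetres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

AXIS_LABELS = ("z", "y", "x")

#: Default HU window used to map volumes to the unit range seen by networks.
DEFAULT_WINDOW = (-1000.0, 1000.0)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels:
        3D float array of HU values, ordered ``(z, y, x)``.
    spacing:
        Per-axis voxel size in mm, same order as ``voxels``.
    origin:
        Physical coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    axis_labels:
        Permutation of ``("z", "y", "x")`` naming the array axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if sorted(self.axis_labels) != sorted(AXIS_LABELS):
            raise ValueError(
                f"axis_labels must be a permutation of {AXIS_LABELS}, got {self.axis_labels}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the volume along each axis (mm)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the volume center (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing, self.origin, self.axis_labels)


@dataclass
class NormalizedVolume:
    """A volume linearly mapped from an HU window onto [0, 1].

    ``voxels`` hold ``clip((HU - hu_min) / (hu_max - hu_min), 0, 1)``; the
    window is kept so the mapping can be inverted (values outside the window
    come back clipped, values inside come back exactly).
    """

    voxels: np.ndarray
    window: tuple[float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        lo, hi = (float(w) for w in self.window)
        if not lo < hi:
            raise ValueError(f"degenerate window {self.window}")
        self.window = (lo, hi)
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > 1):
            raise ValueError("normalized values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


def hu_to_relative_attenuation(volume: CTVolume | np.ndarray) -> np.ndarray:
    """Convert HU to relative attenuation mu/mu_water = 1 + HU/1000.

    Water (0 HU) maps to 1, air (-1000 HU) to 0. Values below -1000 HU (noise)
    are clipped to 0 since attenuation is physically non-negative.
    """
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    return np.clip(1.0 + hu / 1000.0, 0.0, None)


def normalize_volume(volume: CTVolume, window: tuple[float, float] = DEFAULT_WINDOW) -> NormalizedVolume:
    """Window-normalize a volume to [0, 1]."""
    lo, hi = (float(w) for w in window)
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    scaled = np.clip((volume.voxels - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedVolume(scaled, (lo, hi), volume.spacing, volume.origin)


def denormalize_volume(normalized: NormalizedVolume) -> CTVolume:
    """Invert :func:`normalize_volume`; exact for HU inside the window."""
    lo, hi = normalized.window
    hu = normalized.voxels.astype(np.float64) * (hi - lo) + lo
    return CTVolume(hu, normalized.spacing, normalized.origin)


def resample_to_grid(volume: CTVolume, target_shape: tuple[int, int, int]) -> CTVolume:
    """Trilinearly resample a volume onto a new grid of ``target_shape``.

    The physical extent is preserved: new spacing = extent / target_shape, and
    the volume center stays fixed. Target voxel ``j`` samples source index
    ``(j + 0.5) * N / M - 0.5`` (voxel-center alignment of the two grids).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 2 for t in target_shape):
        raise ValueError(f"target_shape entries must be >= 2, got {target_shape}")
    src_shape = np.asarray(volume.shape, dtype=float)
    tgt_shape = np.asarray(target_shape, dtype=float)
    axes = [
        (np.arange(m) + 0.5) * n / m - 0.5 for n, m in zip(src_shape, tgt_shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    resampled = ndimage.map_coordinates(
        volume.voxels.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )
    new_spacing = tuple(volume.extent_mm / tgt_shape)
    new_origin = tuple(volume.center_mm - (tgt_shape - 1) / 2.0 * np.asarray(new_spacing))
    return CTVolume(resampled, new_spacing, new_origin, volume.axis_labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI. The (z, y, x) array is stored as (x, y, z)."""
    import nibabel as nib

    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0))
    affine = np.diag(list(volume.spacing[::-1]) + [1.0])
    affine[:3, 3] = volume.origin[::-1]
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), os.fspath(path))


def save_hdf5(volume: CTVolume, path: str | os.PathLike, *, extra: dict | None = None) -> None:
    """Write a volume to the package's HDF5 container (group ``/volume``)."""
    import h5py

    with h5py.File(os.fspath(path), "w") as f:
        ds = f.create_dataset("volume", data=volume.voxels)
        ds.attrs["spacing_mm"] = volume.spacing
        ds.attrs["origin_mm"] = volume.origin
        ds.attrs["axis_labels"] = ",".join(volume.axis_labels)
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def _load_nifti(path: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin_xyz = tuple(float(v) for v in affine[:3, 3])
    return CTVolume(
        np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing=tuple(float(z) for z in zooms[::-1]),
        origin=origin_xyz[::-1],
    )


def _load_hdf5(path: str) -> CTVolume:
    import h5py

    with h5py.File(path, "r") as f:
        if "volume" not in f:
            raise ValueError(f"{path}: no /volume dataset")
        ds = f["volume"]
        spacing = tuple(float(s) for s in ds.attrs.get("spacing_mm", (1.0, 1.0, 1.0)))
        origin = tuple(float(o) for o in ds.attrs.get("origin_mm", (0.0, 0.0, 0.0)))
        labels = tuple(str(ds.attrs.get("axis_labels", "z,y,x")).split(","))
        return CTVolume(ds[()], spacing, origin, labels)


def _load_dicom_series(path: str, *, spacing_rtol: float = 1e-3) -> CTVolume:
    """Load a directory of single-frame CT DICOM slices as one volume.

    Slices are ordered by their position along the patient axis; a series
    whose inter-slice spacing is inconsistent (beyond ``spacing_rtol``) is
    rejected as corrupt. The HU rescale ``slope * stored + intercept`` is
    applied.
    """
    import pydicom

    files = sorted(
        p for p in Path(path).iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""}
    )
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(os.fspath(p)))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM slices in {path}")
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        z_positions = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    except AttributeError:
        datasets.sort(key=lambda d: int(d.InstanceNumber))
        z_positions = None

    slices = []
    for d in datasets:
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(d.pixel_array.astype(np.float64) * slope + intercept)
    vol = np.stack(slices, axis=0)

    first = datasets[0]
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if z_positions is not None and len(z_positions) > 1:
        dz = np.diff(z_positions)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], rtol=spacing_rtol):
            raise ValueError(f"{path}: inconsistent slice spacing (corrupt series)")
        z_mm = float(dz[0])
        origin_z = float(z_positions[0])
    else:
        z_mm = float(getattr(first, "SliceThickness", 1.0))
        origin_z = 0.0
    ipp = getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return CTVolume(
        vol,
        spacing=(z_mm, row_mm, col_mm),
        origin=(origin_z, float(ipp[1]), float(ipp[0])),
    )


def load_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Load a CT volume from NIfTI, a DICOM series directory, or HDF5.

    Parameters
    ----------
    path:
        File (NIfTI / HDF5) or directory (DICOM series).
    format:
        One of ``{"nifti", "dicom_series", "raw_hdf5"}``; inferred from the
        path when omitted.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        if os.path.isdir(path):
            format = "dicom_series"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.endswith((".h5", ".hdf5")):
            format = "raw_hdf5"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    if format == "raw_hdf5":
        return _load_hdf5(path)
    raise ValueError(f"unknown format {format!r}")
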