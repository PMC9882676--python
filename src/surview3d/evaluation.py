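"""Quantitative evaluation: image similarity, lung segmentation + DICE,
error maps, and water-equivalent area/diameter profiles.

The water-equivalent diameter of a CT slice is the diameter of the water
cylinder with the same total attenuation:

    A_w = A_pixel * sum_(x,y in mask) (CT#(x,y)/1000 + 1)
    D_w = 2 * sqrt(A_w / pi)

(the AAPM TG-220 convention: water contributes 1 per pixel, air 0). D_w per
axial slice is the standard patient-size input to tube-current dose modulation
and size-specific dose estimates (SSDE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .volume import CTVolume, NormalizedVolume

#: HU threshold above which a voxel is considered body (not air).
BODY_THRESHOLD_HU = -500.0
#: HU threshold below which a voxel inside the body is lung candidate.
LUNG_THRESHOLD_HU = -320.0
#: Minimum component size as a fraction of body volume for lung components.
LUNG_MIN_FRACTION = 0.01

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# tp_fp_fn_map labels
LABEL_BACKGROUND, LABEL_TP, LABEL_FP, LABEL_FN = 0, 1, 2, 3


@dataclass
class ImageSimilarityReport:
    mae: float
    mse: float
    ssim: float
    psnr: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "ssim": self.ssim, "psnr": self.psnr}


@dataclass
class SegmentationReport:
    dice: float
    tp_fp_fn_map: np.ndarray


@dataclass
class WaterEquivalentProfile:
    """Per-axial-slice water-equivalent area/diameter along the patient axis."""

    slice_index: np.ndarray
    a_w: np.ndarray  # mm^2
    d_w: np.ndarray  # mm
    a_pixel: float  # mm^2
    slice_thickness_mm: float = 1.0


@dataclass
class ProfileAgreement:
    mean_relative_abs_error: float
    pearson_r: float
    score: float  # 1 - mean relative absolute error

    def as_dict(self) -> dict:
        return {
            "mean_relative_abs_error": self.mean_relative_abs_error,
            "pearson_r": self.pearson_r,
            "score": self.score,
        }


def _unit_array(v) -> np.ndarray:
    a = v.voxels if isinstance(v, NormalizedVolume) else np.asarray(v)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("expected values in [0, 1]")
    return a.astype(np.float64)


def image_similarity(pred, truth, *, ssim_win_size: int = 11) -> ImageSimilarityReport:
    """MAE / MSE / SSIM / PSNR between two normalized volumes.

    SSIM is computed per axial slice with an 11-pixel Gaussian window
    (sigma 1.5, K1=0.01, K2=0.03, data range 1) and averaged; PSNR is
    ``10*log10(1/MSE)`` for unit data range (+inf when MSE is 0).
    """
    p, t = _unit_array(pred), _unit_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    diff = p - t
    mae = float(np.mean(np.abs(diff)))
    mse = float(np.mean(diff**2))
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(1.0 / mse))
    ssim_slices = [
        structural_similarity(
            t[k],
            p[k],
            win_size=ssim_win_size,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
        for k in range(p.shape[0])
    ]
    return ImageSimilarityReport(mae=mae, mse=mse, ssim=float(np.mean(ssim_slices)), psnr=psnr)


def body_mask(volume: CTVolume, threshold_hu: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Largest 26-connected component above the body threshold, with internal
    holes (lungs, trachea) filled per axial slice."""
    fg = volume.voxels > threshold_hu
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("empty body mask: no voxels above threshold (non-anatomical input)")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])
    return mask


def lung_segmentation(
    volume: CTVolume,
    *,
    lung_threshold_hu: float = LUNG_THRESHOLD_HU,
    body_threshold_hu: float = BODY_THRESHOLD_HU,
    min_fraction: float = LUNG_MIN_FRACTION,
) -> np.ndarray:
    """Threshold + connected-component lung segmentation.

    Voxels below ``lung_threshold_hu`` inside the body mask are grouped into
    26-connected components; components larger than ``min_fraction`` of the
    body volume are kept (capturing both lungs whether or not they connect
    through the airways).
    """
    body = body_mask(volume, body_threshold_hu)
    candidates = (volume.voxels < lung_threshold_hu) & body
    labels, n = ndimage.label(candidates, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("lung segmentation failure: no sub-threshold voxels inside body")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_fraction * body.sum()) + 1
    if keep.size == 0:
        raise ValueError("lung segmentation failure: no component above size threshold")
    return np.isin(labels, keep)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> SegmentationReport:
    """DICE = 2|A∩B| / (|A| + |B|) with an explicit TP/FP/FN label map.

    ``mask_a`` is the prediction, ``mask_b`` the truth. Two empty masks give
    DICE 1 (identical emptiness).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tp = a & b
    fp = a & ~b
    fn = ~a & b
    denom = 2 * tp.sum() + fp.sum() + fn.sum()
    score = 1.0 if denom == 0 else 2.0 * tp.sum() / denom
    label_map = np.zeros(a.shape, dtype=np.uint8)
    label_map[tp] = LABEL_TP
    label_map[fp] = LABEL_FP
    label_map[fn] = LABEL_FN
    return SegmentationReport(dice=float(score), tp_fp_fn_map=label_map)


def hu_error_map(pred: CTVolume, truth: CTVolume) -> np.ndarray:
    """Elementwise |HU difference| between two aligned volumes."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return np.abs(pred.voxels.astype(np.float64) - truth.voxels.astype(np.float64))


def water_equivalent_profile(volume: CTVolume, mask: np.ndarray | None = None) -> WaterEquivalentProfile:
    """Per-slice A_w and D_w along the patient (z) axis.

    ``mask`` restricts the sum to the patient (default: whole slice; with the
    +1 convention air contributes 0, so an unmasked air background adds only
    noise terms). Negative per-slice sums (noise below -1000 HU) clip to 0.
    """
    hu = volume.voxels.astype(np.float64)
    if mask is not None:
        if mask.shape != hu.shape:
            raise ValueError("mask must align with volume")
        hu = np.where(mask, hu, -1000.0)
    a_pixel = float(volume.spacing[1] * volume.spacing[2])
    contrib = hu / 1000.0 + 1.0
    a_w = np.clip(a_pixel * contrib.sum(axis=(1, 2)), 0.0, None)
    d_w = 2.0 * np.sqrt(a_w / np.pi)
    return WaterEquivalentProfile(
        slice_index=np.arange(hu.shape[0]),
        a_w=a_w,
        d_w=d_w,
        a_pixel=a_pixel,
        slice_thickness_mm=float(volume.spacing[0]),
    )


def profile_agreement(pred_profile: WaterEquivalentProfile, truth_profile: WaterEquivalentProfile) -> ProfileAgreement:
    """Compare two D_w profiles slice by slice.

    Returns the mean relative absolute D_w error (over slices with nonzero
    true D_w), the Pearson correlation of the profiles, and
    ``1 - mean relative absolute error`` as a scalar agreement score.
    """
    p, t = pred_profile.d_w, truth_profile.d_w
    if p.shape != t.shape:
        raise ValueError("profiles must have equal slice counts")
    nz = t > 0
    rel = float(np.mean(np.abs(p[nz] - t[nz]) / t[nz])) if nz.any() else float("nan")
    if np.std(p) == 0 or np.std(t) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(p, t)[0, 1])
    return ProfileAgreement(mean_relative_abs_error=rel, pearson_r=r, score=1.0 - rel)


def export_aw_mesh(profile: WaterEquivalentProfile, path, *, segments: int = 48):
    """Export the A_w profile as a closed surface: a stack of circles of
    radius D_w/2 per slice, triangulated and capped, written as OBJ/STL.

    Returns the ``trimesh.Trimesh`` for inspection (its volume approximates
    ``sum(A_w) * slice_thickness``).
    """
    import trimesh

    radii = profile.d_w / 2.0
    nz = np.flatnonzero(radii > 0)
    if nz.size == 0:
        raise ValueError("profile has no nonzero slices")
    z = profile.slice_index.astype(np.float64) * profile.slice_thickness_mm
    theta = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    verts = []
    rings = []
    for k in nz:
        ring0 = len(verts)
        for th in theta:
            verts.append((radii[k] * np.cos(th), radii[k] * np.sin(th), z[k]))
        rings.append(ring0)
    faces = []
    for a, b in zip(rings[:-1], rings[1:]):
        for s in range(segments):
            s2 = (s + 1) % segments
            faces.append((a + s, b + s, b + s2))
            faces.append((a + s, b + s2, a + s2))
    # caps
    top_center = len(verts)
    verts.append((0.0, 0.0, z[nz[0]]))
    bot_center = len(verts)
    verts.append((0.0, 0.0, z[nz[-1]]))
    for s in range(segments):
        s2 = (s + 1) % segments
        faces.append((top_center, rings[0] + s2, rings[0] + s))
        faces.append((bot_center, rings[-1] + s, rings[-1] + s2))
    mesh = trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces), process=False)
    if path is not None:
        mesh.export(path)
    return mesh
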