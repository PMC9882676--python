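"""End-to-end desk-scale pipeline: phantoms -> topograms -> training ->
evaluation, fully reproducible from a single config and seed."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from . import evaluation as ev
from .config import RunConfig
from .networks import build_network
from .phantoms import PhantomSample, generate_dataset
from .projector import Topogram, build_geometry, synthesize_topogram
from .training import split_dataset, train
from .volume import (
    CTVolume,
    NormalizedVolume,
    denormalize_volume,
    normalize_volume,
    resample_to_grid,
)

log = logging.getLogger("surview3d")


def resample_mask(mask: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinearly resample a binary mask and re-threshold at 0.5."""
    vol = CTVolume(mask.astype(np.float32), (1.0, 1.0, 1.0))
    return resample_to_grid(vol, target_shape).voxels > 0.5


@dataclass
class PreparedSample:
    """One phantom with its network inputs and target."""

    sample: PhantomSample
    coronal: Topogram
    sagittal: Topogram
    target: NormalizedVolume  # output_size^3, window-normalized

    def entry(self, arch: str) -> dict:
        x1 = self.coronal.normalized()[None]
        if arch == "single":
            return {"inputs": (x1,), "target": self.target.voxels[None]}
        return {"inputs": (x1, self.sagittal.normalized()[None]), "target": self.target.voxels[None]}


def prepare_from_phantoms(samples: list[PhantomSample], config: RunConfig) -> list[PreparedSample]:
    """Synthesize topogram pairs and normalized targets for given phantoms."""
    out = []
    overrides = config.geometry.overrides()
    d = config.network.output_size
    for s in samples:
        cor = synthesize_topogram(s.volume, build_geometry("coronal", s.volume, overrides))
        sag = synthesize_topogram(s.volume, build_geometry("sagittal", s.volume, overrides))
        target = normalize_volume(resample_to_grid(s.volume, (d, d, d)), config.evaluation.window)
        out.append(PreparedSample(s, cor, sag, target))
    return out


def prepare_samples(config: RunConfig) -> list[PreparedSample]:
    """Generate phantoms and synthesize their topogram pairs and targets."""
    samples = generate_dataset(
        config.phantom.n, config.phantom.base, config.phantom.jitter, config.phantom.seed
    )
    return prepare_from_phantoms(samples, config)


def predict_volume(model, prepared: PreparedSample, window) -> tuple[NormalizedVolume, CTVolume]:
    """Run inference for one sample; returns (normalized, HU) predictions."""
    entry = prepared.entry("dual" if model.dual else "single")
    inputs = [x[None] for x in entry["inputs"]]
    pred = model.forward(*inputs, training=False)[0, 0]
    target = prepared.target
    norm = NormalizedVolume(np.clip(pred, 0.0, 1.0), window, target.spacing, target.origin)
    return norm, denormalize_volume(norm)


def evaluate_sample(model, prepared: PreparedSample, config: RunConfig) -> dict:
    """All per-sample metrics: similarity, lung DICE, D_w agreement."""
    window = config.evaluation.window
    pred_norm, pred_hu = predict_volume(model, prepared, window)
    truth_norm = prepared.target
    truth_hu = denormalize_volume(truth_norm)

    sim = ev.image_similarity(pred_norm, truth_norm)
    metrics = sim.as_dict()

    kw = dict(
        lung_threshold_hu=config.evaluation.lung_threshold_hu,
        body_threshold_hu=config.evaluation.body_threshold_hu,
    )
    try:
        pred_lungs = ev.lung_segmentation(pred_hu, **kw)
        truth_lungs = ev.lung_segmentation(truth_hu, **kw)
        metrics["lung_dice"] = ev.dice(pred_lungs, truth_lungs).dice
        gt = resample_mask(prepared.sample.lung_mask, truth_hu.shape)
        metrics["lung_dice_vs_analytic"] = ev.dice(pred_lungs, gt).dice
    except ValueError as err:
        log.warning("lung segmentation failed: %s", err)
        metrics["lung_dice"] = 0.0
        metrics["lung_dice_vs_analytic"] = 0.0

    try:
        p_prof = ev.water_equivalent_profile(pred_hu, ev.body_mask(pred_hu, config.evaluation.body_threshold_hu))
        t_prof = ev.water_equivalent_profile(truth_hu, ev.body_mask(truth_hu, config.evaluation.body_threshold_hu))
        agreement = ev.profile_agreement(p_prof, t_prof)
        metrics["dw_score"] = agreement.score
        metrics["dw_relative_error"] = agreement.mean_relative_abs_error
        metrics["dw_pearson_r"] = agreement.pearson_r
    except ValueError as err:
        log.warning("D_w profile failed: %s", err)
        metrics["dw_score"] = float("nan")
    return metrics


def _mean_metrics(per_sample: list[dict]) -> dict:
    keys = per_sample[0].keys()
    out = {}
    for k in keys:
        vals = [m[k] for m in per_sample if np.isfinite(m[k])]
        out[k] = float(np.mean(vals)) if vals else float("nan")
    return out


def _figure_panel(model, prepared: PreparedSample, config: RunConfig, path) -> None:
    """Truth | prediction | TP/FP/FN | |dHU| panels for the central slices."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    window = config.evaluation.window
    pred_norm, pred_hu = predict_volume(model, prepared, window)
    truth_hu = denormalize_volume(prepared.target)
    try:
        seg = ev.dice(
            ev.lung_segmentation(pred_hu), ev.lung_segmentation(truth_hu)
        ).tp_fp_fn_map
    except ValueError:
        seg = np.zeros(pred_hu.shape, dtype=np.uint8)
    err = ev.hu_error_map(pred_hu, truth_hu)

    fig, axes = plt.subplots(3, 4, figsize=(12, 9))
    for row, axis in enumerate(range(3)):  # axial, coronal, sagittal planes
        k = pred_hu.shape[axis] // 2
        sl = [slice(None)] * 3
        sl[axis] = k
        sl = tuple(sl)
        panels = [truth_hu.voxels[sl], pred_hu.voxels[sl], seg[sl], err[sl]]
        cmaps = ["gray", "gray", "viridis", "magma"]
        for col, (img, cmap) in enumerate(zip(panels, cmaps)):
            axes[row, col].imshow(img, cmap=cmap)
            axes[row, col].axis("off")
    for col, title in enumerate(["truth", "prediction", "TP/FP/FN", "|dHU|"]):
        axes[0, col].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline and write report.json plus per-arch artifacts.

    Returns ``{"report": ..., "prepared": [...], "models": {...},
    "histories": {...}}``; the report (also written as JSON) carries the
    config hash and seeds so a run is reconstructable from its output
    directory alone.
    """
    config.require_valid()
    os.makedirs(config.out_dir, exist_ok=True)
    log.info("stage 1/4: generating %d phantoms", config.phantom.n)
    try:
        prepared = prepare_samples(config)
    except Exception as err:
        raise RuntimeError(f"stage phantoms/topograms failed: {err}") from err

    log.info("stage 2/4: splitting dataset")
    train_s, val_s, test_s = split_dataset(prepared, config.train)

    archs = ["single", "dual"] if config.arch == "both" else [config.arch]
    report = {
        "config_hash": config.config_hash(),
        "seeds": {
            "phantom": config.phantom.seed,
            "train": config.train.seed,
            "network": config.network.seed,
        },
        "n_samples": config.phantom.n,
        "splits": {"train": len(train_s), "val": len(val_s), "test": len(test_s)},
        "config": config.to_dict(),
        "architectures": {},
    }
    models, histories = {}, {}
    for arch in archs:
        log.info("stage 3/4: training %s-view model", arch)
        model = build_network(arch, config.network)
        entries = [p.entry(arch) for p in train_s]
        val_entries = [p.entry(arch) for p in val_s] or None
        try:
            best, history = train(
                model, entries, config.train, val_data=val_entries,
                out_dir=os.path.join(config.out_dir, arch),
            )
        except RuntimeError as err:
            raise RuntimeError(f"stage training ({arch}) failed: {err}") from err
        model.load_state_dict(best)
        history.to_csv(os.path.join(config.out_dir, f"history_{arch}.csv"))

        log.info("stage 4/4: evaluating %s-view model on %d test samples", arch, len(test_s))
        per_sample = [evaluate_sample(model, p, config) for p in test_s]
        report["architectures"][arch] = {
            "test_metrics_mean": _mean_metrics(per_sample),
            "test_metrics_per_sample": per_sample,
            "best_epoch": history.best_epoch,
            "best_val_loss": history.best_val_loss,
            "epochs_run": len(history),
            "final_train_loss": history.train_loss[-1],
        }
        models[arch], histories[arch] = model, history
        if config.make_figures and test_s:
            _figure_panel(model, test_s[0], config, os.path.join(config.out_dir, f"panel_{arch}.png"))

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    log.info("report written to %s", report_path)
    return {"report": report, "prepared": prepared, "models": models, "histories": histories}
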