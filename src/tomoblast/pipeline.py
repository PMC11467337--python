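"""End-to-end pipeline driver: simulate -> measure -> stats -> train ->
predict -> screen.

Each stage writes its artifacts under the configured output directory and
can be run independently (the CLI exposes one verb per stage).  All
randomness flows from the single config seed through named per-stage
substreams; rerunning with the same config reproduces every non-training
artifact bit for bit (training is deterministic too on a fixed BLAS, but
floating-point reduction order can vary across builds).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig, save_config
from . import morphometry
from .io import read_labels, read_tomogram
from .morphometry import SegmentationMask, SegmentationParams, measure_cell
from .nn.train import predict_batch, save_checkpoint, train
from .phantom import CohortManifest, generate_cohort
from .screening import patient_ratios, roc_auc
from .stats import compare_groups

__all__ = ["StageError", "run_pipeline", "stage_simulate", "stage_measure",
           "stage_stats", "stage_train", "stage_predict", "stage_screen"]

log = logging.getLogger("tomoblast")

#: Stage-specific RNG substream ids (seeded as [config.seed, STREAM[stage]]).
_STREAMS = {"simulate": 1, "train": 2}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.__cause__ = cause


def _stage_rng(config: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stage]])


def stage_simulate(config: PipelineConfig, out: Path) -> CohortManifest:
    manifest, _ = generate_cohort(
        wt=config.wt, mut=config.mut, rng=_stage_rng(config, "simulate"),
        out_dir=out / "cohort", split=config.split, write_tomograms=True,
        grid_shape=config.grid_shape, voxel_spacing=config.voxel_spacing,
        medium_ri=config.medium_ri, noise_sd=config.noise_sd,
        min_voxel_span=config.min_voxel_span,
    )
    log.info("simulate: %d images, %d patients", len(manifest.images),
             len(manifest.patients))
    return manifest


def stage_measure(config: PipelineConfig, out: Path,
                  manifest: CohortManifest) -> "object":
    import pandas as pd

    from .morphometry import segment_rule_based

    seg_params = SegmentationParams(noise_sd=config.noise_sd)
    rows = []
    for _, rec in manifest.images.iterrows():
        tomo = read_tomogram(rec["path"])
        if config.segmentation == "ground_truth":
            mask = read_labels(rec["path"])
        else:
            mask = segment_rule_based(tomo, seg_params)
        m = measure_cell(tomo, mask, alpha=config.alpha)
        row = {"image_id": rec["image_id"]}
        row.update(m.to_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "morphometry.csv", index=False)
    log.info("measure: %d cells, %d parameters", len(table), table.shape[1] - 1)
    return table


def stage_stats(config: PipelineConfig, out: Path, manifest: CohortManifest,
                morpho) -> "object":
    merged = morpho.merge(manifest.images[["image_id", "genotype"]], on="image_id")
    comparisons = compare_groups(
        merged.drop(columns=["image_id", "genotype"]), merged["genotype"]
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)
    log.info("stats: %d parameters compared", len(comparisons))
    return comparisons


def _load_split(config: PipelineConfig, manifest: CohortManifest, splits):
    sub = manifest.split_images(*splits)
    images = np.stack([
        (read_tomogram(p).ri - config.medium_ri) / 0.05 for p in sub["path"]
    ]).astype(np.float32)
    labels = np.array([0 if g == "WT" else 1 for g in sub["genotype"]])
    return sub, images, labels


def stage_train(config: PipelineConfig, out: Path, manifest: CohortManifest):
    sub, images, labels = _load_split(config, manifest,
                                      ("optimization", "generalization"))
    model, history = train(images, labels, sub["split"].to_numpy(),
                           config.arch, config.train)
    save_checkpoint(out / "model.npz", model, config.train)
    history.to_csv(out / "history.csv", index=False)
    sel = history[history.selected].iloc[0]
    log.info("train: selected epoch %d (opt %.3f, gen %.3f)",
             int(sel.epoch), sel.opt_acc, sel.gen_acc)
    return model, history


def stage_predict(config: PipelineConfig, out: Path, manifest: CohortManifest,
                  model) -> "object":
    import h5py
    import pandas as pd

    sub, images, _ = _load_split(config, manifest, (config.screen_split,))
    preds = predict_batch(model, images, sub["image_id"].tolist())
    table = pd.DataFrame([{
        "image_id": p.image_id, "out_wt": p.out_wt, "out_mut": p.out_mut,
        "predicted_label": p.predicted_label,
    } for p in preds])
    table.to_csv(out / "predictions.csv", index=False)
    with h5py.File(out / "latents.h5", "w") as f:
        f.create_dataset("latent", data=np.stack([p.latent for p in preds]))
        f.create_dataset("image_id", data=np.array([p.image_id for p in preds],
                                                   dtype="S"))
    log.info("predict: %d images", len(table))
    return table


def stage_screen(config: PipelineConfig, out: Path, manifest: CohortManifest,
                 predictions) -> dict:
    import pandas as pd

    sdir = out / "screen"
    sdir.mkdir(exist_ok=True)
    results = patient_ratios(predictions, manifest.images)
    pd.DataFrame([r.__dict__ for r in results]).to_csv(sdir / "patients.csv",
                                                       index=False)
    roc = roc_auc(results)
    pd.DataFrame([p.__dict__ for p in roc.points]).to_csv(sdir / "roc.csv",
                                                          index=False)
    op = roc.operating_points()
    summary = {
        "auc": roc.auc,
        "n_wt_patients": roc.n_wt,
        "n_mut_patients": roc.n_mut,
        "tpr_at_zero_fpr": op.tpr_at_zero_fpr,
        "tpr_at_zero_fpr_thresholds": list(op.tpr_at_zero_fpr_thresholds),
        "fpr_at_full_tpr": op.fpr_at_full_tpr,
        "fpr_at_full_tpr_thresholds": list(op.fpr_at_full_tpr_thresholds),
    }
    (sdir / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("screen: AUC %.4f over %d patients", roc.auc, roc.n_wt + roc.n_mut)
    return summary


def run_pipeline(config: PipelineConfig, out_dir=None) -> Path:
    """Run all six stages in order; halts with a stage-named error and
    preserves partial outputs on failure."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    state: dict = {}
    stages = [
        ("simulate", lambda: state.update(manifest=stage_simulate(config, out))),
        ("measure", lambda: state.update(
            morpho=stage_measure(config, out, state["manifest"]))),
        ("stats", lambda: state.update(
            comparisons=stage_stats(config, out, state["manifest"], state["morpho"]))),
        ("train", lambda: state.update(model=stage_train(config, out, state["manifest"])[0])),
        ("predict", lambda: state.update(
            predictions=stage_predict(config, out, state["manifest"], state["model"]))),
        ("screen", lambda: state.update(
            summary=stage_screen(config, out, state["manifest"], state["predictions"]))),
    ]
    for name, fn in stages:
        log.info("stage %s ...", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    return out
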