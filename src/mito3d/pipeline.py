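"""End-to-end pipeline: simulate → preprocess → train → predict → connect →
evaluate → morph, driven by one YAML configuration.

Every default lives in ``defaults.yaml`` (packaged alongside this module);
a user config overrides a subset of those keys and unknown keys are
rejected. Each run writes a manifest recording the inputs, produced
artifacts, configuration hash, package version and seed, so a run can be
reproduced exactly.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connect3d import ConnectConfig, connect, filter_small
from .evaluation import (
    DetectionConfig,
    detection_scores,
    match_instances,
    segmentation_scores,
    threshold_sweep,
)
from .inference import TileSpec, binarize, predict_volume, tta_predict
from .io_preprocess import PatchSpec, equalize_histogram, read_labels, read_stack, write_stack
from .morphology import measure_instances, records_to_frame, summarize
from .network import NetworkConfig, build_model, load_checkpoint, save_checkpoint
from .synthetic_data import SceneConfig, generate_scene
from .training import TrainConfig, make_training_set, train
from .volume import LabelVolume, VoxelSpacing, Volume

__all__ = ["load_config", "default_config", "config_hash", "run_pipeline", "PipelineError"]

log = logging.getLogger("mito3d")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def default_config() -> dict:
    text = resources.files("mito3d").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by an optional YAML file, then by ``overrides``."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# config -> typed objects
# ---------------------------------------------------------------------------

def _spacing(cfg: dict) -> VoxelSpacing:
    sz, sy, sx = cfg["spacing_nm"]
    return VoxelSpacing(sz, sy, sx)


def _scene_config(cfg: dict) -> SceneConfig:
    sc = cfg["scene"]
    return SceneConfig(
        shape=tuple(sc["shape"]),
        spacing=_spacing(cfg),
        n_objects=tuple(sc["n_objects"]),
        object_kinds=tuple(sc["object_kinds"]),
        radius_um=tuple(sc["radius_um"]),
        tube_length_um=tuple(sc["tube_length_um"]),
        margin_vox=sc["margin_vox"],
        noise_sigma=sc["noise_sigma"],
        slice_jitter=sc["slice_jitter"],
    )


def _network_config(cfg: dict) -> NetworkConfig:
    net = cfg["network"]
    preset = net["preset"]
    if preset == "tiny":
        base = NetworkConfig.tiny(net["base_channels"])
        return NetworkConfig(
            widths=base.widths,
            encoder_blocks=base.encoder_blocks,
            pool_strides=base.pool_strides,
            aux_levels=base.aux_levels,
            aux_weights=tuple(net["aux_weights"])[: len(base.aux_levels)],
            lambda_reg=net["lambda_reg"],
        )
    if preset == "isotropic":
        return NetworkConfig.isotropic(
            widths=tuple(net["widths"]),
            aux_weights=tuple(net["aux_weights"]),
            lambda_reg=net["lambda_reg"],
        )
    if preset == "default":
        return NetworkConfig(
            widths=tuple(net["widths"]),
            aux_weights=tuple(net["aux_weights"]),
            lambda_reg=net["lambda_reg"],
        )
    raise ValueError(f"unknown network preset {preset!r}")


def _train_config(cfg: dict, seed: int) -> TrainConfig:
    tr = cfg["train"]
    return TrainConfig(
        learning_rate=tr["learning_rate"],
        beta1=tr["beta1"],
        beta2=tr["beta2"],
        eps=tr["eps"],
        batch_size=tr["batch_size"],
        epochs=tr["epochs"],
        seed=seed,
    )


def _tile_spec(cfg: dict) -> TileSpec:
    t = cfg["tiles"]
    return TileSpec(shape=tuple(t["shape"]), overlap=tuple(t["overlap"]))


def _connect_config(cfg: dict) -> ConnectConfig:
    c = cfg["connect"]
    return ConnectConfig(
        iou_threshold=c["iou_threshold"],
        connectivity=c["connectivity"],
        min_voxels=c["min_voxels"],
    )


def _detection_config(cfg: dict) -> DetectionConfig:
    d = cfg["detection"]
    return DetectionConfig(
        overlap_threshold=d["overlap_threshold"],
        overlap=d["overlap"],
        sweep_grid=tuple(d["sweep_grid"]),
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, workdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    workdir = Path(workdir or cfg["paths"]["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    spacing = _spacing(cfg)
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "seed": seed,
        "stages": {},
    }

    volume: Volume | None = None
    gt_instances: LabelVolume | None = None
    model = None
    prob: Volume | None = None
    instances: LabelVolume | None = None

    def record(stage: str, **outputs) -> None:
        manifest["stages"][stage] = {k: str(v) for k, v in outputs.items()}
        log.info("stage %s done: %s", stage, outputs)

    try:
        if stages["simulate"]:
            volume, gt_instances, objects = generate_scene(_scene_config(cfg), seed=seed)
            vol_path = workdir / "volume.h5"
            inst_path = workdir / "instances.h5"
            write_stack(volume, vol_path)
            write_stack(gt_instances, inst_path)
            scene_manifest = [
                {
                    "instance_id": o.instance_id,
                    "kind": o.kind,
                    "center_um": o.center_um,
                    "analytic_volume_um3": o.analytic_volume_um3,
                    **o.params,
                }
                for o in objects
            ]
            (workdir / "scene.json").write_text(json.dumps(scene_manifest, indent=2))
            record("simulate", volume=vol_path, instances=inst_path, n_objects=len(objects))
        elif cfg["paths"]["volume"]:
            volume = read_stack(cfg["paths"]["volume"], spacing=spacing)
            if cfg["paths"]["labels"]:
                gt_instances = read_labels(
                    cfg["paths"]["labels"], spacing=spacing, semantics="instance"
                )

        if stages["preprocess"]:
            if volume is None:
                raise PipelineError("preprocess: no input volume (enable simulate or set paths.volume)")
            if cfg["preprocess"]["equalize"]:
                volume = equalize_histogram(volume, n_levels=cfg["preprocess"]["n_levels"])
            pre_path = workdir / "preprocessed.h5"
            write_stack(volume, pre_path)
            record("preprocess", volume=pre_path)

        if stages["train"]:
            if volume is None or gt_instances is None:
                raise PipelineError("train: requires a volume and labels")
            patch = cfg["patch"]
            spec = PatchSpec(
                shape=tuple(patch["shape"]),
                stride=tuple(patch["stride"]) if patch["stride"] else None,
            )
            binary = LabelVolume(
                (gt_instances.data > 0).astype(np.uint8), spacing, semantics="binary"
            )
            dataset = make_training_set(volume, binary, spec, augment=patch["augment"], seed=seed)
            model = build_model(_network_config(cfg), seed=seed)
            model, history = train(model, dataset, _train_config(cfg, seed))
            ckpt = workdir / "model.npz"
            save_checkpoint(model, ckpt)
            history.to_csv(workdir / "history.csv")
            record("train", checkpoint=ckpt, history=workdir / "history.csv",
                   final_loss=history.epoch_loss[-1] if history.epoch_loss else None)

        if stages["predict"]:
            if volume is None:
                raise PipelineError("predict: no input volume")
            if model is None:
                ckpt = workdir / "model.npz"
                if not ckpt.exists():
                    raise PipelineError("predict: no trained model (enable train stage)")
                model = load_checkpoint(ckpt)
            tiles = _tile_spec(cfg)
            variants = int(cfg["tiles"]["tta_variants"])
            if variants == 1:
                prob = predict_volume(model, volume, tiles)
            else:
                prob = tta_predict(model, volume, tiles, variants=variants)
            prob_path = workdir / "probability.h5"
            write_stack(prob, prob_path)
            record("predict", probability=prob_path, tta_variants=variants)

        if stages["connect"]:
            if prob is None:
                raise PipelineError("connect: no probability map (enable predict stage)")
            mask = binarize(prob, threshold=cfg["tiles"]["threshold"])
            instances = connect(mask, _connect_config(cfg))
            inst_path = workdir / "predicted_instances.h5"
            write_stack(instances, inst_path)
            record("connect", instances=inst_path, n_instances=int(instances.data.max()))

        if stages["evaluate"]:
            if gt_instances is None:
                raise PipelineError("evaluate: no ground truth available")
            results: dict = {}
            if prob is not None:
                mask = binarize(prob, threshold=cfg["tiles"]["threshold"])
                seg = segmentation_scores(mask, (gt_instances.data > 0))
                results["segmentation"] = {
                    "jaccard": seg.jaccard,
                    "dice": seg.dice,
                    "conformity": seg.conformity,
                }
            if instances is None:
                raise PipelineError(
                    "evaluate: detection metrics need predicted instances — "
                    "enable the connect stage"
                )
            det_cfg = _detection_config(cfg)
            filt = filter_small(instances, _connect_config(cfg).min_voxels)
            counts = match_instances(filt, gt_instances, det_cfg)
            precision, recall, f1 = detection_scores(counts)
            results["detection"] = {
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "precision": precision, "recall": recall, "f1": f1,
            }
            sweep = threshold_sweep(filt, gt_instances, config=det_cfg)
            sweep.to_csv(workdir / "detection_sweep.csv", index=False)
            eval_path = workdir / "evaluation.json"
            eval_path.write_text(json.dumps(results, indent=2))
            record("evaluate", evaluation=eval_path, sweep=workdir / "detection_sweep.csv")

        if stages["morph"]:
            target = instances if instances is not None else gt_instances
            if target is None or target.data.max() == 0:
                raise PipelineError("morph: no instances to measure")
            records = measure_instances(target, spacing)
            frame = records_to_frame(records)
            frame.to_csv(workdir / "morphometry.csv", index=False)
            extent = np.array(target.shape) * np.array(spacing.as_tuple()) * 1e-3
            summary = summarize(records, float(np.prod(extent)))
            (workdir / "morphometry_summary.json").write_text(
                json.dumps(
                    {
                        "count": summary.count,
                        "density_per_um3": summary.density_per_um3,
                        "total_volume_um3": summary.total_volume_um3,
                        "means": summary.means,
                        "stds": summary.stds,
                    },
                    indent=2,
                )
            )
            record("morph", table=workdir / "morphometry.csv",
                   summary=workdir / "morphometry_summary.json")
    except PipelineError:
        raise
    except Exception as exc:
        stage = next(
            (s for s in ("simulate", "preprocess", "train", "predict", "connect",
                         "evaluate", "morph")
             if stages.get(s) and s not in manifest["stages"]),
            "unknown",
        )
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return manifest
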