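"""Run configuration: strict YAML schema over the component configs.

A run file has nested sections (model / csla / blsd / soeb / augment /
train / data / profile) plus a master seed and output directory.  Unknown
keys are rejected; every default is visible in ``DEFAULTS``; the resolved
configuration is written into each run directory so a run can be
re-executed bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .csla import CslaConfig
from .model import ModelConfig
from .soeb import SoebConfig
from .synthetic import SceneSpec
from .train import TrainConfig

__all__ = ["DEFAULTS", "ConfigError", "load_run_config", "default_run_config",
           "build_model_config", "build_train_config", "build_scene_spec",
           "build_augment_config", "dump_run_config", "config_hash"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs/run",
    "model": {
        "num_classes": 3,
        "width_ratio": 1.0,
        "head_width": 64,
        "head_tower_depth": 1,
        "context_width": 504,
        "context_ffn_ratio": 2,
    },
    "csla": {
        "enabled": True,
        "compression_ratio": 4,
        "scales": [1, 2, 4],
        "rank": None,
        "blocks_per_level": 4,
    },
    "blsd": {
        "enabled": False,
        "expansion_ratio": 4,
        "loss_weight": 1.0,
        "substitution_end_fraction": 0.5,
        "top_m": 4,
        "descriptor_grid": 10,
        "teacher_epochs": 24,
        "distill_weight": 0.1,
    },
    "soeb": {
        "enabled": True,
        "kernel_set": [3, 5, 7],
    },
    "augment": {
        "enabled": True,
        "mixup_beta": 1.0,
        "max_paste_iou": 0.2,
        "small_threshold": 20.0,
    },
    "train": {
        "batch_size": 32,
        "lr": 1.0e-3,
        "weight_decay": 0.01,
        "epochs": 24,
        "schedule": "cosine",
        "optimizer": "adamw",
        "split_ratio": [0.7, 0.2, 0.1],
        "folds": None,
        "box_weight": 2.0,
        "ctr_weight": 1.0,
        "img_cls_weight": 0.2,
    },
    "data": {
        "source": "synthetic",       # or a path to a COCO annotations.json
        "n_images": 600,
        "canvas": 320,
        "difficulty": "benchmark",   # easy | hard | benchmark | default
        "object_rate": 4.0,
    },
    "profile": {
        "input_size": 640,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        where = f"{path}.{k}" if path else k
        if k not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[k] = _merge(base[k], v, where)
        else:
            out[k] = v
    return out


def default_run_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_run_config(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("run config must be a YAML mapping")
    return _merge(DEFAULTS, doc)


def build_model_config(rc: dict, seed: int | None = None) -> ModelConfig:
    m, c, s = rc["model"], rc["csla"], rc["soeb"]
    return ModelConfig(
        num_classes=m["num_classes"],
        width_ratio=m["width_ratio"],
        csla=CslaConfig(compression_ratio=c["compression_ratio"],
                        scales=tuple(c["scales"]),
                        rank=c["rank"],
                        blocks_per_level=c["blocks_per_level"]),
        soeb=SoebConfig(kernel_set=tuple(s["kernel_set"])),
        use_csla=bool(c["enabled"]),
        use_soeb=bool(s["enabled"]),
        head_width=m["head_width"],
        head_tower_depth=m["head_tower_depth"],
        context_width=m["context_width"],
        context_ffn_ratio=m["context_ffn_ratio"],
        seed=rc["seed"] if seed is None else seed,
    )


def build_train_config(rc: dict) -> TrainConfig:
    t = rc["train"]
    return TrainConfig(
        batch_size=t["batch_size"], lr=t["lr"],
        weight_decay=t["weight_decay"], epochs=t["epochs"],
        schedule=t["schedule"], split_ratio=tuple(t["split_ratio"]),
        folds=t["folds"], seed=rc["seed"], box_weight=t["box_weight"],
        ctr_weight=t["ctr_weight"], img_cls_weight=t["img_cls_weight"],
        distill_weight=rc["blsd"]["distill_weight"],
        augment=build_augment_config(rc),
    )


def build_augment_config(rc: dict) -> AugmentConfig | None:
    a = rc["augment"]
    if not a["enabled"]:
        return None
    return AugmentConfig(mixup_beta=a["mixup_beta"],
                         max_paste_iou=a["max_paste_iou"],
                         small_threshold=a["small_threshold"],
                         seed=rc["seed"] + 2)


def build_scene_spec(rc: dict) -> SceneSpec:
    d = rc["data"]
    canvas = int(d["canvas"])
    kind = d["difficulty"]
    if kind == "easy":
        spec = SceneSpec.easy(canvas_size=(canvas, canvas))
    elif kind == "hard":
        spec = SceneSpec.hard(canvas_size=(canvas, canvas))
    elif kind == "benchmark":
        spec = SceneSpec.benchmark(canvas=canvas)
    else:
        spec = SceneSpec(canvas_size=(canvas, canvas))
    spec.object_rate = float(d["object_rate"])
    return spec


def config_hash(rc: dict) -> str:
    return hashlib.sha256(json.dumps(rc, sort_keys=True).encode()).hexdigest()[:16]


def dump_run_config(rc: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(rc, sort_keys=True))
    (out / "config.hash").write_text(config_hash(rc))
    return path
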