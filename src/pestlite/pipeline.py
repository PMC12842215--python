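"""End-to-end experiment runners: ablation and sensitivity tables.

``run_ablation`` retrains the detector on the synthetic benchmark for each
requested module subset (CSLA / BLSD / SOEB toggles, identical seeds and
data across rows) and reports detection metrics plus profiler counts.
``run_sensitivity`` sweeps one architecture axis — the CSLA compression
ratio or the SOEB kernel set — reporting FLOPs/params always and metrics
when training is enabled.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import replace

import numpy as np

from .backbone import Backbone
from .blsd import DistillState
from .config import (build_model_config, build_scene_spec, build_train_config,
                     ConfigError)
from .model import DetectionModel, ModelConfig
from .profiler import profile_model
from .synthetic import generate_dataset
from .train import Trainer, evaluate_model, stratified_split

__all__ = ["run_ablation", "run_sensitivity", "ABLATION_MODULES",
           "build_from_run", "make_benchmark_data"]

ABLATION_MODULES = ("CSLA", "BLSD", "SOEB")


def build_from_run(rc: dict, seed: int | None = None) -> DetectionModel:
    return DetectionModel(build_model_config(rc, seed=seed))


def make_benchmark_data(rc: dict, seed: int | None = None):
    """Generate the benchmark scenes and return (train, val) image lists."""
    spec = build_scene_spec(rc)
    n = int(rc["data"]["n_images"])
    images = generate_dataset(spec, n, seed=rc["seed"] if seed is None else seed)
    tr, va, te = stratified_split(images, tuple(rc["train"]["split_ratio"]),
                                  rc["seed"])
    return tr, va + te


def _make_teacher(rc: dict, model_cfg: ModelConfig, train_images, val_images):
    """Teacher backbone for distillation: double-width, briefly trained."""
    t_cfg = replace(model_cfg, width_ratio=model_cfg.width_ratio * 2.0,
                    use_csla=False, use_soeb=False, seed=model_cfg.seed + 11)
    teacher_model = DetectionModel(t_cfg)
    epochs = int(rc["blsd"]["teacher_epochs"])
    if epochs > 0:
        tc = build_train_config(rc)
        tc = replace(tc, epochs=epochs, augment=None)
        Trainer(teacher_model, tc).fit(train_images, None)
    teacher = teacher_model.backbone
    teacher.requires_grad_(False)
    return teacher


def _train_row(rc: dict, toggles: frozenset, train_images, val_images,
               teacher=None) -> dict:
    mc = build_model_config(rc)
    mc = replace(mc, use_csla="CSLA" in toggles, use_soeb="SOEB" in toggles)
    model = DetectionModel(mc)
    tc = build_train_config(rc)
    state = None
    if "BLSD" not in toggles:
        teacher = None
    if "BLSD" in toggles:
        if teacher is None:
            teacher = _make_teacher(rc, mc, train_images, val_images)
        b = rc["blsd"]
        from . import nn
        with nn.init_rng(mc.seed + 13):
            state = DistillState(
                teacher, model.backbone,
                expansion_ratio=b["expansion_ratio"],
                substitution_end_fraction=b["substitution_end_fraction"],
                top_m=b["top_m"], descriptor_grid=b["descriptor_grid"],
                loss_weights=np.full(12, b["loss_weight"]))
    trainer = Trainer(model, tc, teacher=teacher, distill_state=state)
    trainer.fit(train_images, None)
    rep = evaluate_model(model, val_images)
    prof = profile_model(model, rc["profile"]["input_size"])
    name = " + ".join(m for m in ABLATION_MODULES if m in toggles) or "baseline"
    return {"config": name, "toggles": sorted(toggles),
            "map50": rep.map50, "map_small": rep.map_small,
            "params": prof.total_params, "gflops": prof.gflops}


def run_ablation(rc: dict, toggles: list[set[str]] | None = None,
                 data=None, teacher=None) -> list[dict]:
    """One row per module subset, identically seeded except for the toggles.

    ``toggles`` defaults to the canonical progression: baseline, each module
    alone, pairs, and the full model.  A pre-trained frozen ``teacher``
    backbone may be supplied for the BLSD rows; otherwise one is trained
    per the run configuration.
    """
    if toggles is None:
        toggles = [set()] + [set(c) for r in (1, 2, 3)
                             for c in itertools.combinations(ABLATION_MODULES, r)]
    seen = set()
    for t in toggles:
        bad = set(t) - set(ABLATION_MODULES)
        if bad:
            raise ConfigError(f"unknown ablation toggles: {sorted(bad)}")
        key = frozenset(t)
        if key in seen:
            raise ConfigError(f"duplicate toggle subset: {sorted(t)}")
        seen.add(key)
    if data is None:
        train_images, val_images = make_benchmark_data(rc)
    else:
        train_images, val_images = data
    return [_train_row(rc, frozenset(t), train_images, val_images,
                       teacher=teacher)
            for t in toggles]


def run_sensitivity(rc: dict, axis: str, values: list,
                    train_metrics: bool = False, data=None) -> list[dict]:
    """Sweep ``axis`` ∈ {csla.compression_ratio, soeb.kernel_set}."""
    rows = []
    for v in values:
        rc_v = copy.deepcopy(rc)
        if axis == "csla.compression_ratio":
            if v not in (2, 4, 8, 16):
                raise ConfigError(f"invalid compression ratio {v}")
            rc_v["csla"]["compression_ratio"] = int(v)
            label = {"compression_ratio": int(v)}
        elif axis == "soeb.kernel_set":
            ks = tuple(int(k) for k in v)
            if not ks or any(k % 2 == 0 for k in ks):
                raise ConfigError(f"invalid kernel set {v}")
            rc_v["soeb"]["kernel_set"] = list(ks)
            label = {"kernel_set": list(ks)}
        else:
            raise ConfigError(f"unknown sensitivity axis: {axis}")
        model = build_from_run(rc_v)
        prof = profile_model(model, rc_v["profile"]["input_size"])
        row = {**label, "gflops": prof.gflops, "params": prof.total_params,
               "mparams": prof.mparams}
        if train_metrics:
            if data is None:
                data = make_benchmark_data(rc)
            tr, va = data
            tc = build_train_config(rc_v)
            Trainer(model, tc).fit(tr, None)
            rep = evaluate_model(model, va)
            row.update({"map50": rep.map50, "map_small": rep.map_small})
        rows.append(row)
    return rows
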