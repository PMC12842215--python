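"""Full-model assembly, config plumbing, sensitivity tables and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from pestlite.cli import main
from pestlite.config import (ConfigError, DEFAULTS, build_model_config,
                             config_hash, default_run_config, dump_run_config,
                             load_run_config)
from pestlite.model import DetectionModel, ModelConfig, build_model
from pestlite.pipeline import run_ablation, run_sensitivity
from pestlite.profiler import profile_model


def test_model_emits_three_head_levels_and_image_logits(tiny_model):
    x = np.zeros((1, 3, 96, 96))
    levels, img_logits = tiny_model(x)
    assert set(levels) == {4, 8, 16}
    assert levels[4][0].shape == (1, 3, 24, 24)
    assert img_logits.shape == (1, 3)


def test_model_forward_deterministic(tiny_model):
    x = np.random.default_rng(0).normal(size=(1, 3, 64, 64))
    a = tiny_model(x)[0][4][0].data
    b = tiny_model(x)[0][4][0].data
    assert np.array_equal(a, b)


def test_module_toggles_change_head_input_width():
    base = build_model(ModelConfig(width_ratio=0.25, seed=0,
                                   use_csla=False, use_soeb=False))
    full = build_model(ModelConfig(width_ratio=0.25, seed=0))
    assert base.head.stems[0].cin == 16          # raw backbone stride-4 width
    assert full.head.stems[0].cin == 32          # enhancement-branch output


def test_inference_graph_free_of_distillation_params():
    model = build_model(ModelConfig(width_ratio=0.25, seed=0))
    names = [k for k, _ in model.named_parameters()]
    assert not any("mapping" in n or "substitution" in n for n in names)


def test_distilled_guidance_rejected_in_eval_mode(tiny_model):
    with pytest.raises(ValueError, match="train-only"):
        tiny_model.extract(np.zeros((1, 3, 64, 64)),
                           d_blk=np.zeros((1, 32, 16, 16)))


# ---------------------------------------------------------------------------
# run config
# ---------------------------------------------------------------------------

def test_unknown_keys_rejected(tmp_path):
    p = tmp_path / "run.yaml"
    p.write_text("modle:\n  num_classes: 2\n")
    with pytest.raises(ConfigError, match="modle"):
        load_run_config(p)
    p.write_text("csla:\n  compression: 2\n")
    with pytest.raises(ConfigError, match="csla.compression"):
        load_run_config(p)


def test_overrides_merge_into_defaults(tmp_path):
    p = tmp_path / "run.yaml"
    p.write_text("seed: 9\ncsla:\n  compression_ratio: 8\n")
    rc = load_run_config(p)
    assert rc["seed"] == 9
    assert rc["csla"]["compression_ratio"] == 8
    assert rc["train"]["batch_size"] == DEFAULTS["train"]["batch_size"]
    mc = build_model_config(rc)
    assert mc.csla.compression_ratio == 8 and mc.seed == 9


def test_resolved_config_dump_and_hash(tmp_path):
    rc = default_run_config()
    path = dump_run_config(rc, tmp_path)
    assert path.exists()
    assert (tmp_path / "config.hash").read_text() == config_hash(rc)
    assert config_hash(rc) != config_hash({**rc, "seed": 1})


# ---------------------------------------------------------------------------
# sensitivity / ablation plumbing
# ---------------------------------------------------------------------------

def _fast_rc():
    rc = default_run_config()
    rc["model"]["width_ratio"] = 1.0
    rc["profile"]["input_size"] = 128
    return rc


def test_sensitivity_flops_strictly_decrease_with_compression():
    rows = run_sensitivity(_fast_rc(), "csla.compression_ratio", [2, 4, 8, 16])
    flops = [r["gflops"] for r in rows]
    assert flops == sorted(flops, reverse=True) and len(set(flops)) == 4


def test_sensitivity_params_strictly_increase_with_kernels():
    rows = run_sensitivity(_fast_rc(), "soeb.kernel_set",
                           [[3], [3, 5], [3, 5, 7], [5, 7, 9]])
    params = [r["params"] for r in rows]
    assert params == sorted(params) and len(set(params)) == 4


def test_sensitivity_single_value_single_row():
    rows = run_sensitivity(_fast_rc(), "csla.compression_ratio", [4])
    assert len(rows) == 1


def test_sensitivity_invalid_axis_and_value():
    with pytest.raises(ConfigError, match="axis"):
        run_sensitivity(_fast_rc(), "head.width", [1])
    with pytest.raises(ConfigError, match="ratio"):
        run_sensitivity(_fast_rc(), "csla.compression_ratio", [3])


def _tiny_train_rc():
    rc = default_run_config()
    rc["model"]["width_ratio"] = 0.25
    rc["data"].update({"n_images": 30, "canvas": 64, "object_rate": 5.0})
    rc["train"].update({"epochs": 1, "batch_size": 4})
    rc["blsd"]["teacher_epochs"] = 0
    rc["profile"]["input_size"] = 64
    return rc


def test_ablation_rows_structure_and_param_monotonicity():
    rc = _tiny_train_rc()
    rows = run_ablation(rc, toggles=[set(), {"SOEB"}, {"CSLA", "SOEB"},
                                     {"CSLA", "BLSD", "SOEB"}])
    assert [r["config"] for r in rows] == [
        "baseline", "SOEB", "CSLA + SOEB", "CSLA + BLSD + SOEB"]
    assert rows[0]["params"] < rows[1]["params"] < rows[2]["params"]
    # distillation adds no inference-graph parameters
    assert rows[3]["params"] == rows[2]["params"]


def test_ablation_rejects_bad_toggles():
    rc = _tiny_train_rc()
    with pytest.raises(ConfigError, match="unknown"):
        run_ablation(rc, toggles=[{"SOFA"}])
    with pytest.raises(ConfigError, match="duplicate"):
        run_ablation(rc, toggles=[{"SOEB"}, {"SOEB"}])


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_generate_split_profile(tmp_path):
    runner = CliRunner()
    cfg = tmp_path / "run.yaml"
    cfg.write_text("model:\n  width_ratio: 0.25\n"
                   "data:\n  n_images: 30\n  canvas: 64\n  object_rate: 5.0\n"
                   "profile:\n  input_size: 64\n")
    res = runner.invoke(main, ["generate-data", "--config", str(cfg),
                               "--out", str(tmp_path / "d"), "--n", "30"])
    assert res.exit_code == 0, res.output
    ann = tmp_path / "d" / "annotations.json"
    assert ann.exists()

    res = runner.invoke(main, ["split", "--data", str(ann)])
    assert res.exit_code == 0
    counts = json.loads(res.output)
    assert counts["train"] + counts["val"] + counts["test"] == 30

    res = runner.invoke(main, ["profile", "--config", str(cfg)])
    assert res.exit_code == 0
    assert "total" in res.output


def test_cli_config_error_exit_code(tmp_path):
    cfg = tmp_path / "bad.yaml"
    cfg.write_text("nonsense: 1\n")
    runner = CliRunner()
    res = runner.invoke(main, ["profile", "--config", str(cfg)])
    assert res.exit_code == 2
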