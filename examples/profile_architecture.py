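"""Profile the default detector and the two sensitivity axes.

Builds the calibrated full model, counts MACs/params for one 640x640
forward pass, then sweeps the attention compression ratio (FLOPs axis) and
the small-object-branch kernel set (params axis).
"""

from pestlite.config import default_run_config
from pestlite.pipeline import build_from_run, run_sensitivity
from pestlite.profiler import profile_model

rc = default_run_config()
model = build_from_run(rc).eval()
rep = profile_model(model, 640)
print(rep.table())
print(f"\ndefault model: {rep.gflops:.3f} G FLOPs, {rep.mparams:.3f} M params")

print("\nCSLA compression ratio sweep (larger ratio -> cheaper attention):")
for row in run_sensitivity(rc, "csla.compression_ratio", [2, 4, 8, 16]):
    print(f"  ratio {row['compression_ratio']:>2}: {row['gflops']:.3f} G FLOPs")

print("\nSOEB kernel-set sweep (larger kernels -> more generator params):")
for row in run_sensitivity(rc, "soeb.kernel_set",
                           [[3], [3, 5], [3, 5, 7], [5, 7, 9]]):
    print(f"  kernels {row['kernel_set']}: {row['mparams']:.3f} M params")

print("\nEach FLOPs number is MACs/1e9 for one forward pass; params count "
      "the trainable inference graph.")
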