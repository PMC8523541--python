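"""Run every stage end to end on one simulated study.

`simulate_dataset` writes a complete synthetic study to disk (MTX count trio
with WT/MT labels, spliced/unspliced layers, a bulk responder cohort, and a
ground-truth JSON); `run_pipeline` then executes composition testing, DEG
calling, velocity transitions, metacell correlation, deconvolution and
interaction scoring from a single config, with per-stage outputs and a
machine-readable run report.
"""

import json
import tempfile
from pathlib import Path

from sclandscape import RunConfig, run_pipeline, simulate_dataset

workdir = Path(tempfile.mkdtemp(prefix="sclandscape_demo_"))
paths = simulate_dataset(None, seed=1, out_dir=workdir / "data")
print(f"simulated study written under {workdir / 'data'}")

config = RunConfig(
    manifest=paths["manifest"],
    out_dir=str(workdir / "run"),
    seed=1,
    bulk_tsv=paths["bulk"],
    response_tsv=paths["response"],
    n_perm=200,
)
report = run_pipeline(config)

print("\nstage summary:")
for stage, entry in report.stages.items():
    print(f"  {stage:14s} {entry['status']:8s} {entry['wall_clock_s']:6.2f}s")

comp = json.loads((workdir / "run" / "composition_summary.json").read_text())
print("\ncomposition calls (MT vs WT):",
      {k: v for k, v in comp["calls"].items() if v != "unchanged"})
vel = json.loads((workdir / "run" / "velocity_params.json").read_text())
print("C2 persistence by group:",
      {g: vel["persistence"][g]["C2"] for g in vel["persistence"]})
print("\nThe simulator planted depletions of C2/C8/C9, an augmentation of "
      "C1, and eroded C2 persistence in MT; subsets whose residual lands "
      "inside the conservative |r| <= 3.5 band in a given draw stay "
      "'unchanged'. Every stage output lives under", workdir / "run")
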