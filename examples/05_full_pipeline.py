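"""Run the whole analysis as one reproducible pipeline.

Equivalent to `islet-identity run-all --out islet_run --seed 7` from a
shell: simulate -> QC -> normalize -> cell typing -> identity scoring ->
trajectories -> DE -> over-representation -> RRHO, all into one run
directory with a machine-readable summary.
"""
import json
from pathlib import Path

from islet_identity import PipelineConfig, PopulationConfig, run_all

config = PipelineConfig(
    out_dir="scratch/example_run",
    seed=7,
    generator=PopulationConfig(n_beta=300, n_alpha=300, n_traced=800,
                               seed=7),
)
run_dir = run_all(config)

summary = json.loads((run_dir / "summary.json").read_text())
for key in ("n_cells_pass_qc", "traced_total", "traced_intermediate",
            "intermediate_pct", "peak_XBP1", "peak_DDIT3",
            "de_intermediate_vs_traced_beta_significant"):
    if key in summary:
        print(f"{key:45s} {summary[key]}")
print(f"outputs: {sorted(p.name for p in Path(run_dir).iterdir())}")
print("-> the same seed always reproduces this summary byte-for-byte; "
      "every stage's table is a TSV in the run directory.")
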