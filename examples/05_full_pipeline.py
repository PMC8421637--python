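"""One-command end-to-end run on simulated inputs.

Simulates a small cohort to TSV/CSV files, then runs connectivity,
community detection, switching rates, and statistics, leaving per-scan
partitions/profiles, a tidy stats table, and a reproducibility manifest
under the output directory.
"""

import json
import tempfile
from pathlib import Path

from netswitch import MultilayerParams, RunConfig, SlidingWindowConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "demo_run"
config = RunConfig(
    out_dir=str(out),
    window=SlidingWindowConfig(width=30, step=5, trim_initial=5),
    multilayer=MultilayerParams(n_repetitions=3, seed=0),
    seed=42,
    simulate={"n_per_group": (4, 4), "n_nodes": 10, "n_modules": 2, "n_volumes": 80},
)
manifest = run_pipeline(config)

for stage in manifest["stages"]:
    print(f"stage {stage['name']:<10} {stage['seconds']:6.2f} s")
layers = set(manifest["stages"][1]["layer_counts"].values())
print(f"layers per scan: {layers}")
print(f"outputs under {out}:")
for f in sorted(out.rglob("*.csv"))[:3]:
    print(f"  {f.relative_to(out)}")
stats = (out / "stats.csv").read_text().splitlines()
print("first stats rows:")
print("\n".join(stats[:3]))
print("-> rerunning with the same config reproduces these files byte for byte")
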