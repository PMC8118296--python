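"""Run the whole analysis pipeline from a config and list its outputs.

Produces, for a PR-interval-like scenario, every publication-style table:
score-ECG association, quintile display with floated CIs, per-5 ms
estimates for AF / lone-AF / SVT analogues, ion-channel subset, the
sensitivity-estimator table, funnel coordinates, meta-analysis,
bidirectional analysis and the instrument-strength report.
"""

import ecgmr
from ecgmr.pipeline import read_table

cfg = ecgmr.PipelineConfig(
    scenarios=["pr"], n_individuals=15_000, seed=9,
    outdir="scratch/pipeline_demo", n_boot=200, n_sim=500,
)
outputs = ecgmr.run_pipeline(cfg)

for name, path in sorted(outputs.items()):
    print(f"{name:24s} {path}")

sens = read_table(outputs["pr_sensitivity"])
print("\nsensitivity table (per-ms log-OR scale):")
print(sens[["method", "beta", "se", "p", "flag"]].to_string(index=False))
# Re-running with the same config and seed reproduces every table
# byte-identically; the run log records one line per operation call.
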