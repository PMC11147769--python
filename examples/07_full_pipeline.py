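"""Run the whole pipeline end to end on a synthetic cohort.

simulate -> classify -> attribute -> germline HRD -> fitness -> single cell
-> cohort statistics, writing per-stage TSVs and a manifest into out/demo.
"""

import json

from chdyn.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(
    PipelineConfig(out_dir="out/demo", seed=42, n_patients=30)
)
print(json.dumps(manifest["stages"], indent=2, default=str))
print("outputs in out/demo/ (classified.tsv, fitness.tsv, manifest.json, ...)")
# The manifest records the seed and every threshold, so the run is exactly
# reproducible; rerunning with the same config gives byte-identical tables.
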