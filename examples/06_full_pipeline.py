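"""Run the complete synthetic workflow end to end.

Simulation -> rank-product DE -> interactome/hubs -> phi weights ->
Boolean scoring/shortlist -> co-expression -> clinical, writing all
stage TSVs and a provenance manifest into ./pipeline_run.
"""

import json

from boolerank import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_genes=500, n_tumor=8, n_normal=8),
    n_perm=50,
    seed=11,
)
manifest = run_pipeline(cfg, "pipeline_run")

print("Stages executed:", ", ".join(manifest["stages"]))
print("Differentially expressed genes:", manifest["n_de_genes"])
print("High-confidence edges:", manifest["n_hc_edges"], "| hubs:", manifest["n_hubs"])
print("Shortlisted DE genes:", manifest["shortlist_de"][:10], "...")
print("Log-rank on the simulated cohort:", json.dumps(manifest["logrank"]))
print("\nOutputs written to ./pipeline_run (see manifest.json for provenance;")
print("rerunning with the same config and seed is byte-identical).")
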