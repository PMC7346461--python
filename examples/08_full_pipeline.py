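"""Run the complete analysis pipeline on a synthetic bundle.

Derives traits, screens for cranium-size scaling, builds the signal
table, runs pPCAs, colubrid PGLS, mode and main-prey ANOVAs, diet
analyses and both ancestral-state reconstructions, and writes a
manifest whose seeds make the whole run byte-for-byte reproducible.
"""

import json
import warnings

from snakedent import PipelineConfig, SimConfig, run_full_analysis, sim_bundle

bundle = sim_bundle(SimConfig(seed=5, n_species=100, n_unknown_mode=4))
bdir = bundle.write("scratch/example_pipeline_bundle")

cfg = PipelineConfig(seed=17, nsim=500, nperm=499, asr_ngen=10_000, asr_burnin=2_000)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_full_analysis(bdir, cfg)

for stage in manifest.stages:
    print(f"{stage['name']:22s} {stage['status']}")
print(f"\nspecies removed for unknown subjugation mode: "
      f"{manifest.filter_log['removed_unknown_mode']}")
diet = next(s for s in manifest.stages if s["name"] == "diet")["results"]
print(f"Mantel (phylo scheme): r = {diet['mantel_r_phylo']:+.3f}, "
      f"p = {diet['mantel_p_phylo']:.3f}")
asr = next(s for s in manifest.stages if s["name"] == "asr")["results"]
print("root P(grooved), threshold model, 3-state coding:",
      round(asr["3state"]["root_posterior_threshold"].get("grooved", 0.0), 3))
print(f"\nall outputs under {bdir}/results; re-running with the same config "
      "reproduces them byte-for-byte")
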