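"""Run the whole pipeline from one config and inspect the manifest.

Simulation -> ROI annotation -> ams scoring -> per-subtype DMR calling
-> context/specificity -> quadrant integration -> candidate screen ->
composite-risk survival.  Every output lands in the output directory
with a checksum manifest; rerunning with the same seed reproduces the
checksums bit-exactly.
"""

import json

from methylquad import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(),
    outdir="scratch/pipeline_demo",
    seed=0,
)
manifest = run_pipeline(cfg)

print("stage summaries:")
print(json.dumps(manifest["stages"], indent=1))
print(f"\n{len(manifest['files'])} output files written to {cfg.outdir}")
surv = manifest["stages"]["survival"]
print(f"\ntop candidate / marker: {surv['marker_gene']}")
print(f"composite-risk log-rank p = {surv['logrank_p']:.3g} "
      f"({surv['n_high_risk']} high-risk vs {surv['n_low_risk']} low-risk subjects)")
# With planted effects at their defaults the top-ranked candidate is the
# generator's designated marker and its risk stratification is strongly
# significant in the simulated validation cohort.
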