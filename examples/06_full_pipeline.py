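"""Configuration-driven pipeline: build -> simulate -> analyze.

Runs a scaled-down mixture end to end and prints the analysis summary.
All artifacts (trajectory, per-frame cluster composition, profile fits,
manifest with config hash and seed) land in ./scratch/pipeline_demo.
"""

import json

from pdcondensate import RunConfig, run_pipeline

config = RunConfig.from_dict({
    "system": {"n_protein": 36, "dna_length": 12, "dna_bead_budget": 36,
               "box_edge": 650.0, "placement_radius": 150.0, "seed": 5},
    "forcefield": {"lambda_PP": 4.0, "lambda_PD": 2.0},
    "dynamics": {"t_damp": 1.0, "n_steps": 1000, "sample_every": 100},
    "analysis": {"bin_width": 15.0},
})

summary = run_pipeline(config, "scratch/pipeline_demo")
print("\nanalysis summary:")
print(json.dumps(summary, indent=2, default=float))
print("\nRe-running with the same config and seed reproduces the manifest")
print("and every analysis output bit for bit.")
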