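"""Run the complete pipeline on a small synthetic campaign.

Simulates sessions with a known distance decay of 0.5 per km, writes the
standard output files, and prints the recovered factor.
"""
import tempfile

import numpy as np

import nearsource as ns

cfg = ns.ScenarioConfig(seed=5, n_sessions=6, sample_interval_s=2.0,
                        session_duration_h=(1.5, 3.0),
                        true_beta=(0.0, 0.3, 0.5, 0.4, float(np.log(0.5))))
sessions, wind, route, truth = ns.simulate_scenario(cfg)

outdir = tempfile.mkdtemp(prefix="nearsource_example_")
pc = ns.PipelineConfig(output_dir=outdir, seed=5)
res = ns.run_pipeline(pc, sessions=sessions, wind=wind, route=route)

print(f"config hash {res.config_hash}; outputs in {outdir}")
print(f"mean background fraction across sessions: "
      f"{res.background_table['background_fraction'].mean():.2f}")
print(f"{len(res.aggregated)} aggregated rows after filters")

for model in ("independent", "spatial"):
    fr = res.fits["NO"][model]
    print(f"{model:12s} distance factor per km: {np.exp(fr.beta[4]):.3f} "
          f"(truth 0.500), SE of beta4 {fr.se[4]:.3f}")
print("files written: aggregated.csv, fits.json, coefficients.csv, "
      "background_summary.csv, correlations.csv")
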