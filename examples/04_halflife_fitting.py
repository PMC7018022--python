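"""Half-life estimation from a metabolic-labeling decay timecourse.

Simulates a 10-timepoint chase with spike-in distortion and 10%
multiplicative noise, normalizes by the spike-ins, fits growth-corrected
exponential decays by least absolute deviations, and applies the filters.
"""

import pandas as pd

import codonstab as cs

config = cs.SimulationConfig(n_transcripts=200, seed=9)  # sigma = 0.1 noise
_, manifest = cs.generate_transcriptome(config)
halflives = cs.generate_halflives(manifest, config)
raw, spike_reads, total_reads = cs.generate_timecourse(halflives, config, manifest)

tc = cs.spike_in_normalize(raw, spike_reads, total_reads)
print("per-timepoint spike factors (relative to t0):")
print("  " + "  ".join(f"{t:g}h:{f:.2f}" for t, f in tc.spike_factors.items()))

estimates = cs.fit_timecourse(tc, doubling_time=config.doubling_time)
passing, rejections = cs.filter_estimates(estimates)
print(f"\n{len(passing)}/{len(estimates)} fits pass the filters "
      f"(half-life <= 18 h, mean |residual| <= 20); rejections: {rejections or 'none'}")

fits = pd.Series({e.transcript_id: e.half_life for e in estimates})
rel = ((fits - manifest.half_life) / manifest.half_life).abs()
print(f"median relative error vs simulated truth: {100 * rel.median():.1f}% "
      f"(the growth-dilution correction removes the apparent decay from the "
      f"{config.doubling_time:g} h doubling time)")

one = passing[0]
print(f"\nexample fit {one.transcript_id}: half-life {one.half_life:.2f} h "
      f"(true {manifest.half_life[one.transcript_id]:.2f} h), "
      f"mean |residual| {one.mean_abs_residual:.2f} on the t0=100 scale")
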