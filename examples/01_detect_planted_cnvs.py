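"""Simulate a 1 Mbp depth track with planted CNVs and call them back.

Generates ten planted gains/losses from the standard size pool at 2x
coverage with 2% sequencing error, runs the scale-space caller with default
parameters, and prints each call next to the planted truth plus base-pair
error rates. FNR is the fraction of planted CNV bases missed; FPR the
fraction of background bases wrongly called.
"""

import numpy as np

from cnvscale import (
    SimulationConfig,
    detect_cnvs,
    sample_cnv_layout,
    score_calls,
    simulate_coverage,
)

config = SimulationConfig(coverage=2.0, error_rate=0.02)
rng = np.random.default_rng(7)

truth = sample_cnv_layout(config, rng)
coverage = simulate_coverage(config, truth, rng)
calls = detect_cnvs(coverage)

print(f"mean depth {coverage.values.mean():.2f} (C * rho = "
      f"{config.coverage * 0.965:.2f} expected outside CNVs)\n")
print("planted CNVs:")
for s, e, kind in truth.regions:
    print(f"  {s:>8}-{e:<8} {kind:4} {e - s:>6} bp")
print("\ncalls (detection layer k, sigma_k, score = |mean - m*| / delta*):")
for c in calls:
    print(f"  {c.start:>8}-{c.end:<8} {c.cnv_type:4} {c.length:>6} bp   "
          f"k={c.detection_layer:2d} sigma={c.detection_sigma:8.0f} "
          f"score={c.score:5.1f}")

res = score_calls(calls, truth, config.genome_length)
print(f"\nFNR {res.fnr:.2f}%   FPR {res.fpr:.2f}%   "
      f"(tp={res.tp_bases} fn={res.fn_bases} fp={res.fp_bases} bp)")
print("Large CNVs are declared at coarse layers (high k), small ones at "
      "fine layers; events under ~1.5 kb sit below the 3-sigma band and "
      "are expected misses.")
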