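"""Anatomy of one detection: layers, crossings, baselines, tracing.

Builds a small noisy track with a single 15 kb gain, decomposes it into
scale-space layers, and shows for a few layers how many curvature
zero-crossings survive, where the baseline band sits, and how the interval
found at a coarse layer traces back to sharp boundaries at layer 0.
"""

import numpy as np

from cnvscale import ReadCoverage, ScaleParams, detect_cnvs, median_filter
from cnvscale._multiscale import compute_multiscale_layers
from cnvscale.segmentation import DetectorParams, LayerBaselines

rng = np.random.default_rng(11)
n, start, end = 200_000, 90_000, 105_000
lam = np.full(n, 3.0)
lam[start:end] *= 2.0
cov = ReadCoverage("demo", rng.poisson(lam))

filtered = median_filter(cov)
params = ScaleParams(layers=30)
views = compute_multiscale_layers(filtered.values.astype(float), params)

print("layer  sigma(bp)  stride  crossings  band (m*-3d*, m*+3d*)")
for k in (0, 5, 10, 15, 20, 25, 29):
    v = views[k]
    bl = LayerBaselines.from_layer(k, v.values)
    print(f"{k:5d} {v.sigma:9.0f} {v.stride:7d} {len(v.cross_pos):10d}  "
          f"({bl.lower:5.2f}, {bl.upper:5.2f})")

calls = detect_cnvs(cov, DetectorParams(scale=params))
print(f"\nplanted gain: {start}-{end} (15 kb)")
for c in calls:
    print(f"called {c.cnv_type}: {c.start}-{c.end} at layer {c.detection_layer} "
          f"(sigma {c.detection_sigma:.0f}); boundary errors "
          f"{c.start - start:+d} / {c.end - end:+d} bp")
print("Crossings thin out as sigma grows (causality); the call is declared "
      "where the smoothed event clears the band, then traced down to "
      "recover un-blurred edges.")
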