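"""A miniature FNR/FPR sweep over coverage levels.

Runs the simulate -> detect -> score loop at three coverage levels with a
handful of replicates each and prints the mean base-pair error rates. The
full benchmark protocol (more cells, 10-20 replicates) lives in
scripts/acceptance.py.
"""

from cnvscale.evaluation import run_sweep

cells = [(0.5, 0.02), (1.0, 0.02), (3.0, 0.02)]
table = run_sweep(cells, replicates=4, master_seed=99)
print(table.to_string(index=False))
print("\nFNR generally falls as coverage rises; replicate-to-replicate "
      "spread is large because each replicate draws a different CNV "
      "layout, and layouts that concentrate large same-type CNVs are "
      "intrinsically hard for the trimmed per-layer baselines.")
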