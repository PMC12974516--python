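"""Estimate the size-control strategy of simulated lineages.

An adder (a = 0.5) adds a fixed mean mass per cycle.  The script estimates
the autoregressive parameter a, its covariance twin alpha, and the
growth-rate share alpha_lambda, pooled across lineages with length weighting.
"""

import lineagegrowth as lg

lset, _ = lg.generate_dataset(lg.SyntheticConfig(
    n_lineages=12, cells_per_lineage=30, dt=1 / 20, seed=2))
segged = [lg.segment_cycles(ln.trace) for ln in lset]
stats = [lg.size_control_stats(ln) for ln in segged if ln.n_full >= 8]

pooled = lg.pooled_weighted_summary(stats, min_cells=8).set_index("statistic")
for name in ("a_autoregressive", "alpha", "alpha_lambda"):
    row = pooled.loc[name]
    print(f"{name:18s} = {row['mean']:+.3f} +/- {row['se']:.3f} "
          f"(N={int(row['n_lineages'])} lineages, p vs 0: {row['p_vs_0']:.3g})")
print("alpha near 0.5 indicates adder size control (per-lineage estimates sit "
      "slightly above it on finite lineages: the usual autoregression "
      "small-sample bias); alpha_lambda near 0 means homeostasis acts through "
      "the generation time, not growth-rate modulation.")
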