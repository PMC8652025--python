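"""Simulate zero-inflated replicate tracks and inspect their mean-variance trend.

Generates two negative-binomial replicates over chr21+chr22, writes them as
bedGraph, and tabulates the binned mean/sd of one replicate against the
other — the raw material the curve fit consumes.
"""

import numpy as np

from vss import SimConfig, build_base_aux, mean_variance_diagnostic, simulate_replicates, write_simulation

config = SimConfig(n_positions=100_000, seed=2026)
reps, truth = simulate_replicates(config)
paths = write_simulation("example_output/sim", reps, truth)

values = reps.tracks[0].values
print(f"replicates        : {reps.m_replicates} tracks x {reps.n_positions} bins "
      f"({config.bin_width} bp each) on {reps.tracks[0].chrom_names}")
print(f"zero-inflation    : {np.mean(values == 0):.1%} of replicate-1 bins read exactly 0")
print(f"written           : {', '.join(sorted(paths.values()))}")

table = mean_variance_diagnostic(build_base_aux(reps), b=5_000)
print("\nbinned mean-variance trend (bin sd of one replicate vs the other):")
print(table.round(2).to_string(index=False))
print("\nsd rises faster than sqrt(mean): the signal is not variance-stabilized,")
print("so equal read-count differences are not equally surprising along the genome.")
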