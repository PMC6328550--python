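"""Check estimator normalization on the CSR null model.

For three independent homogeneous channels every correlation function is 1 by
definition.  This generates such data (100 points/µm² per channel on a
10 x 10 µm² canvas), estimates the pair and triple correlations in the exact
guard-zone edge mode, and reports how many bins sit within 3 Monte-Carlo
standard errors of 1 — about 99.7% is ideal.
"""

import numpy as np

import tricorr as tc
from tricorr import presets

sets = tc.csr(presets.csr_spec(seed=1))
tri = tc.compute_triple_correlation(sets["R"], sets["B"], sets["G"], edge="guard")
pair = tc.compute_pair_correlation(sets["B"], sets["G"], edge="guard")

print(f"triple correlation: {tri.n_valid} valid bins")
print(f"  mean g over valid bins: {np.nanmean(tri.g[tri.mask]):.4f} (ideal 1)")
print(f"  fraction within 3 SE of 1: {tc.fraction_within_csr_noise(tri):.3f}")
print(f"pair correlation B-G:")
print(f"  mean g: {np.nanmean(pair.g[pair.mask]):.4f}")
print(f"  fraction within 3 SE of 1: {tc.fraction_within_csr_noise(pair):.3f}")
print(
    "\nValues near 1 with ~99% of bins inside the 3 SE band mean the\n"
    "canvas-area / density normalization and the edge correction are\n"
    "calibrated: any structure reported on real data is signal, not bias."
)
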