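"""Detect two planted three-color configurations in dense synthetic SMLM data.

Simulates the headline benchmark — two distinct triangle patterns (equilateral
150 nm and scalene 60/100/80 nm), ~1000 instances mixed at random positions
and orientations on a 10240 x 10240 nm² canvas, ~10 localizations per molecule
per channel — then estimates the triple correlation and mines its significant
local maxima.  Expected: exactly the two planted distance triples, each within
one 10 nm bin.
"""

import tricorr as tc
from tricorr import presets

sets, manifest = tc.simulate(presets.two_pattern_mixture_spec(seed=42))
for ch, s in sorted(sets.items()):
    print(f"channel {ch}: {s.n} localizations, {s.density_per_um2():.0f}/um^2")

profile = tc.compute_triple_correlation(sets["R"], sets["B"], sets["G"])
peaks = tc.find_peaks(profile, z_threshold=2.5)

print(f"\n{len(peaks)} significant configuration(s):")
for p in peaks:
    print(
        f"  (r_RB, r_RG, r_BG) = ({p.r_rb:.0f}, {p.r_rg:.0f}, {p.r_bg:.0f}) nm, "
        f"amplitude g = {p.amplitude:.0f}, z = {p.z_score:.1f}"
    )
print(
    "\nEach line is one recovered molecular geometry: the bin-center distance\n"
    "triple of a triangle formed by the three species, its correlation\n"
    "amplitude (fold enrichment over complete spatial randomness), and how\n"
    "many SDs it stands above the profile's fluctuation."
)
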