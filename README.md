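# tricorr

Coordinate-based pair- and triple-correlation analysis of multiplexed
single-molecule localization microscopy (SMLM) data.

## The problem

Multicolor SMLM yields, per color channel, a list of molecular localization
coordinates at ~10 nm precision.  When three labeled species assemble into a
complex — say a helicase, a polymerase clamp and a single-strand-binding
protein at a DNA replication fork — the assembly's geometry is encoded in the
data but invisible to the eye once thousands of complexes, repeated
localizations and background molecules overlap in a nucleus.  Second-order
statistics (pair cross-correlation) can certify that two species interact at
a preferred distance, but cannot distinguish a genuine three-species
configuration from three coincidental pairwise attractions.  The third-order
(triple) correlation can, yet computing it by the classic Fourier/bispectrum
route requires rendering coordinates into megapixel images and a 4D
transform, which is prohibitively slow and throws away sub-pixel accuracy.

`tricorr` estimates both correlation functions *directly from coordinates*:

* **Pair correlation** — for species A, B and radial bins of width `dr`:

      g(r) = A / (N_A N_B) * Σ_{i∈A} n_B(annulus r ± dr/2 around i)
                              / (2π r dr e_i(r))

  with canvas area `A`, counts `N`, and `e_i(r)` the exact in-canvas arc
  fraction of the circle of radius `r` around point i (edge correction).

* **Triple correlation** — every localization of an origin species R is
  visited; satellites B at displacement (r₁, θ) and G at (r₂, θ + Δθ) are
  accumulated over all angles with a KD-tree cutoff, normalized so that three
  independent homogeneous (CSR) channels give g ≡ 1:

      g(r₁, r₂, Δθ) = A² / (N_R N_B N_G) * W(r₁, r₂, Δθ)
                        / (2π r₁ dr · r₂ dr · 2ΔΘ)

  and re-indexed by the law of cosines into the chirality-free triangle
  representation g(r_RB, r_RG, r_BG).

On top of the estimators the package provides: significant-configuration
mining (local maxima ≥ mean + 2.5 SD of the profile's fluctuation), triangle
reconstruction and multi-profile overlays with edge filtering, conditional
probability / local density of a third species at a two-species complex
(P = g_TC<sup>max</sup> / g_PC(d), ρ(C|AB) = ρ_C · P), a ground-truth
simulator for planted molecular patterns, second-order polynomial chromatic
registration from fiducial beads, and two independent validation oracles
(naive O(N³) brute force, and a pixel-rendered FFT/bispectrum route).

## Worked example

`examples/01_two_pattern_mixture.py` plants two distinct three-color triangle
geometries — equilateral 150 nm and scalene (60, 100, 80) nm — ~1000
instances mixed at random positions/orientations on a 10240 × 10240 nm²
canvas with ~10 localizations per molecule per channel, then recovers them:

```text
channel B: 10088 localizations, 96/um^2
channel G: 10155 localizations, 97/um^2
channel R: 10228 localizations, 98/um^2

2 significant configuration(s):
  (r_RB, r_RG, r_BG) = (55, 95, 75) nm, amplitude g = 494, z = 51.6
  (r_RB, r_RG, r_BG) = (145, 145, 145) nm, amplitude g = 261, z = 27.2
```

Both planted geometries are recovered as the only two significant maxima,
each in the 10 nm bin containing its true distance triple (bin centers 55/95/75
and 145/145/145 correspond to the planted 60/100/80 and 150/150/150).  The
amplitude is the fold enrichment of that configuration over complete spatial
randomness; z is its height above the profile's fluctuation in SD units.

The other examples demonstrate CSR null calibration (`02`), chromatic
registration (`03`), and conditional density at a complex (`04`) — each
prints its numbers with a short interpretation.

A thin CLI mirrors the library for shell pipelines:

```sh
tricorr simulate --config spec.yaml --out locs.csv
tricorr tc --in locs.csv --roles R=R,B=B,G=G --out tc.h5
tricorr peaks --in tc.h5 --z 2.5 --out peaks.json
tricorr overlay --peaks peaks.json --filter BG:100 --align RG --out overlay.csv
```

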