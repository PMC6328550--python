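# Methods

This note documents the statistical model behind `tricorr`, the estimator
conventions, the numerical choices that were genuinely open, what the
synthetic benchmarks do and do not demonstrate, and known limitations.

## Data model

The input is a marked spatial point pattern: per color channel, a list of 2D
localization coordinates in nanometres on a closed rectangular canvas
(origin lower-left, y up; boundary points are inside).  Coordinates are
treated as continuous throughout — no pixel convention exists anywhere in
the analysis path; only the Fourier validation oracle rasterizes.  A real
SMLM localization list differs from an ideal molecular point pattern in two
ways the estimators must tolerate: each molecule is sampled several times
(localization clusters of radius σ, the localization precision), and
unbound/background molecules contribute an approximately homogeneous
Poisson component.

## Pair correlation

For channels A (origins) and B (satellites) with counts N_A, N_B on a canvas
of area A, half-open radial bins (0, r_max] of width dr, and bin centers r_c:

    ĝ(r) = A / (N_A N_B) · Σ_{i∈A} n_B(annulus r_c ± dr/2 around i)
                             / (2π r_c dr · e_i(r_c))

Under independence (CSR) the expectation of each term is 1.  In the
auto-correlation (A = B) self-pairs are excluded, which leaves the usual
(N−1)/N bias; it is not corrected.  Coincident cross-channel points at zero
distance fall below the first bin and drop out.

### Edge correction

`e_i(r)` is the exact fraction of the circle of radius r around origin i
lying inside the canvas, in closed form: a circle point is outside the
closed rectangle iff it violates one of the four half-plane constraints;
each violated wall excludes an arc of half-width arccos(d/r) about the
outward normal, every half-width is ≤ π/2, so only arcs of adjacent walls
overlap and the union has an explicit expression.  Fractions below 0.05 are
clamped (with a logged warning) so a single pathological origin cannot
dominate a bin.

Two modes are exposed:

* `arc` (default) — every origin is used, weighted by 1/e_i.  For the pair
  estimator this is unbiased.  For the *triple* estimator the separable
  weight 1/(e_i(r₁)e_i(r₂)) is unbiased in the angular total but slightly
  redistributes expectation across Δθ near edges, because the in-canvas
  angular windows of the two satellites are correlated; on a 10 × 10 µm²
  canvas with r_max = 300 nm the per-bin bias is a few tenths of a percent
  — negligible against configuration peaks (amplitudes 10²–10³) but visible
  in a deep null calibration.
* `guard` — origins within r_max of the boundary are discarded and no
  weights applied; exactly unbiased at the cost of ~12% of origins in the
  geometry above.  Calibration tests use this mode; mining uses `arc`.

## Triple correlation

Each origin localization u_i of channel R is visited; for satellites v_j ∈ B
and w_k ∈ G within r_max (KD-tree range search — never the all-pairs
product), the pair of displacement vectors defines (r₁, r₂, Δθ) with
Δθ ∈ [0, π] the unsigned angle between them.  The accumulator W adds the
weight 1/(e_i(r₁c)·e_i(r₂c)) into that bin, and

    ĝ(r₁, r₂, Δθ) = A² / (N_R N_B N_G) · W / (2π r₁c dr · r₂c dr · 2ΔΘ)

The 2ΔΘ folds the two signs of Δθ.  Unsigned Δθ deliberately collapses
chirality: the target representation — the three pairwise distances
{r_RB, r_RG, r_BG} of the triangle — cannot encode handedness either.

### Re-indexing to triangle distances

Each Δθ slice maps to r_BG = √(r₁c² + r₂c² − 2 r₁c r₂c cos Δθc), evaluated
at bin centers, and is assigned to the r_BG bin containing that value (the
r_BG axis extends to 2·r_max).  Several Δθ bins mapping to one r_BG bin are
combined by CSR-expectation weighting — accumulators (W, its CSR
expectation, and its CSR variance) are summed, then divided — which keeps
the CSR value at exactly 1.  All geometric factors use bin centers, never
per-point values, so the brute-force oracle is bit-comparable to the
KD-tree implementation (they accumulate identical terms in identical
order; measured agreement is exact, not merely ≤ 1e-9).

### Angular resolution

Defaults: dr = 10 nm, r_max = 300 nm, and ΔΘ = π/72.  The angular width is
tied to the re-index: the mapping advances by |∂r₃/∂θ|·ΔΘ ≤ min(r₁,r₂)·ΔΘ
per angular bin, so with ΔΘ = π/72 no r_BG bin is skipped for radii up to
≈ 230 nm.  A coarser ΔΘ = π/36 leaves unpopulated ("gap") r_BG bins already
at r ≈ 150 nm, which can split one physical maximum into two spurious local
maxima; this drove the default.

### Validity mask and expected-count floor

A bin is valid when (a) its centers satisfy the triangle inequality, (b) at
least one angular bin maps into it, and (c) its CSR-expected count is at
least `min_expected` (default 10; 0 disables).  The floor exists because the
significance rule (below) compares bins against a single global fluctuation
scale, while the per-bin sampling error scales as 1/√E: a bin expecting
0.3 triples turns a single random triple into g ≈ 3, and a dense grid
contains thousands of such bins.  Ten expected counts cap the relative
Monte-Carlo error near 30% and make the global-SD rule meaningful.  The
oracle-equivalence tests disable the floor so every populated bin is
compared.

### Monte-Carlo standard errors

Each profile carries, per bin, the analytic CSR-null expectation E[W] and
variance E[W²] of its accumulator (the variance accumulates the squared edge
weights).  The null z-score (W − E)/√E[W²] is the basis of the calibration
tests: on pooled CSR replicates ~99.4% of valid bins fall within 3 SE
(nominal 99.7%; the shortfall is bin-center discretization).  Replicate
profiles pool by summing accumulators, equivalent to expectation-weighted
averaging.

## Configuration mining

A configuration peak is a valid bin strictly greater than all valid bins in
its 26-neighborhood (masked neighbors ignored; plateau ties collapse to the
lexicographically smallest index) with amplitude ≥ mean + z·SD, z = 2.5 by
default, where mean and SD are taken over *all* valid bins including peaks —
the simplest defensible reading of "significantly above the fluctuation";
with strong peaks this inflates the SD and makes the threshold conservative.
Each peak's distance triple is reconstructed as a triangle (chosen edge on
the horizontal, first-named vertex at the origin, third vertex in the upper
half-plane; distances reproduced exactly, degenerate collinear triples
accepted at zero height), and peaks from many profiles can be filtered on an
edge length (e.g. keep r_BG ≤ 100 nm) and overlaid in a common frame with a
per-peak marker (amplitude or local density).

## Conditional probability and local density

For a configuration peak with amplitude g_TC^max whose conditioning pair
(the two channels of the supplied pair profile, e.g. B–G) sits at edge
distance d:

    P(third | pair) = g_TC^max / g_PC(d)
    ρ(third | pair) = ρ_third · P(third | pair)

g_PC(d) is read from the bin containing d (no interpolation; a linear
interpolation flag exists).  ρ_third is the overall average density
N_third / A.  Under third-channel independence P → 1.

Two statistics must not be conflated here.  The *data-driven maximum* over
the flat r_BG ridge that a CSR third channel produces is an extreme-value
statistic and overshoots the ridge mean by ~3 per-bin SDs (measured
+16–18%); it does not indicate mis-normalization.  The selection-free check
reads the profile at a caller-chosen configuration bin
(`peaks.peak_at_distances`) — the natural statistic for "is C enriched at
the known complex?" — and is what the null calibration uses.  When a real
configuration exists, the peak stands far above the ridge and the
distinction is immaterial.

## Simulator

Patterns are rigid molecule arrangements (one molecule per participating
channel; pairs and triangles in practice).  Placement draws the centroid
uniformly on the canvas and an orientation uniform in [0, 2π); an instance
with any molecule outside the canvas is redrawn entirely, keeping planted
geometry intact near edges.  Each molecule emits Poisson-distributed
localizations (fixed-count mode for exact tests) scattered by an isotropic
Gaussian of sd σ; localizations that scatter off the canvas are dropped as
unobservable.  Background is an independent homogeneous Poisson process per
channel.  One seed expands into named sub-streams (placement / counts /
jitter / per-channel background), so adding background does not perturb
placement, and identical spec + seed is bit-reproducible.

Not modelled: blinking kinetics and repeated-activation correlations beyond
the iid localization count, detection inhomogeneity, drift, 3D, camera
noise.  A consequence worth knowing: with ~10 localizations per molecule, a
chance overlap of two molecules from different channels creates ~10²
correlated cross-channel localization pairs, a real (if rare) feature of
clustered localization data that shows up as minor, sub-threshold structure
at small r_BG in the benchmarks.

## Validation scenarios (tests/, scripts/acceptance.py)

* **Two-pattern mixture** — equilateral 150 nm + scalene (60, 100, 80) nm
  (side lengths are this package's choice of well-separated geometries),
  ~1000 instances on 10240 × 10240 nm², ~10 localizations/molecule, σ=5 nm,
  no background (the patterns alone give the target ~100 coords/µm² per
  channel).  Expected and observed: exactly two significant maxima, each in
  the bin of its planted triple (verified on 10 seeds before freezing).
* **CSR calibration** — 100/µm² per channel on 10 × 10 µm², ten pooled
  replicates, guard mode; ≥99% of valid bins within 3 null SE for both
  estimators.
* **Oracle equivalence** — ~100 points/channel; KD-tree vs brute-force
  profiles agree exactly on every bin.
* **Fourier cross-check** — planted (80, 100, 120) nm geometry on a
  2560 × 2560 nm² canvas, 5 nm pixels; the rasterized FFT route and the
  coordinate estimator locate the same peak bin.
* **Parameter recovery** — equilateral 100 nm, σ=5 nm, 500 instances; global
  maximum within one bin of (100, 100, 100).
* **Registration recovery** — beads distorted by a known second-order field;
  coefficients recovered to ~1e-11 relative error.
* **Conditional density** — 1500 B–G complexes at 75 nm on 10240 nm canvas,
  one localization per molecule (molecule-level densities are what the
  conditional identity concerns), 40/µm² pair background (g_PC ≈ 1.5, a
  regime chosen so the ~5% r_BG-window mismatch between the re-indexed
  triple readout and the sharp pair bin stays well inside the ±10% check),
  150/µm² CSR bystander.  Null: P = 1.00–1.05 over 20 pooled replicates.
  Attachment sweep: ρ(C|BG) rises monotonically and ≈ linearly with the
  attached fraction f ∈ {0.25, 0.5, 1}.

Passing these shows the estimators are correctly normalized, edge-corrected
and mutually consistent, and that the pipeline recovers planted geometry
under realistic density, precision and background.  It does not certify
robustness to the unmodelled effects above, nor threshold behavior on
profiles whose fluctuation is strongly non-uniform beyond what
`min_expected` controls.

## Numerical conventions

* Bins are half-open (low, high]; a distance exactly on an edge goes to the
  lower-adjacent bin's upper neighbor; zero distances drop out.
* Accumulation is double precision in deterministic (input) order; repeated
  runs are bit-identical.
* The polynomial registration solves on coordinates centered and scaled to
  an O(1) box (raw second-order monomials on 10⁴ nm coordinates are
  ill-conditioned) and re-expands the coefficients into the raw basis
  j → x^⌊j/3⌋ y^(j mod 3); only second order is exposed — higher orders
  overfit typical bead layouts.  Rank-deficient bead layouts (e.g.
  collinear) and fewer than nine pairs are rejected.
* Localization tables are CSV (`x_nm,y_nm,channel[,sigma_nm,frame]`,
  `#` comments carry the canvas); floats are written at repr precision so
  round trips are lossless and rewrites byte-identical.  Profiles serialize
  to HDF5 with bins, accumulators, mask and run metadata; peaks to JSON.

## Limitations

* Rectangular canvases only; a non-rectangular region of interest (e.g. a
  nucleus outline) must currently be bounded by its rectangle, which biases
  densities if much of the rectangle is empty.  Mask support is future work.
* The arc-mode triple estimator's Δθ-level edge bias (above) is documented,
  not corrected; use guard mode when sub-percent null accuracy matters.
* The conditional-probability readout is bin-discretized; peaks whose
  conditioning edge exceeds the pair profile's r_max are undefined.
* No 3D, no time-resolved correlation, no GPU path.
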