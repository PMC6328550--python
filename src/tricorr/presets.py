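"""Canonical synthetic scenarios used for validation and benchmarking.

These fix the study conditions once, so tests, examples and the acceptance
script all exercise identical regimes:

* ``two_pattern_mixture_spec`` — the headline benchmark: two distinct
  three-color triangle patterns, ~1000 instances in total on a
  10240 x 10240 nm² canvas with ~10 localizations per molecule per channel
  (~10^4 coordinates/channel, ~100 per µm² per channel).  The triple
  correlation of this mixture must show exactly two significant local maxima,
  one per planted geometry.  The two side-length sets (equilateral 150 nm and
  scalene 60/100/80 nm) are this package's choice of well-separated
  geometries; σ = 5 nm localization precision.
* ``single_triangle_spec`` — one planted geometry for parameter recovery.
* ``csr_spec`` — independent homogeneous channels, the null model.
* ``fork_bystander_spec`` — planted two-species (B–G) complexes at a fixed
  spacing with a third "bystander" channel C that is either pure CSR or
  attached to a fraction f of the complexes; the regime for conditional
  density estimation (g_PC(d) ≈ 5 so pair signal is strong but not extreme).
"""

from __future__ import annotations

from .io import Canvas
from .simulate import PatternSpec, SimulationSpec

__all__ = [
    "two_pattern_mixture_spec",
    "single_triangle_spec",
    "csr_spec",
    "fork_bystander_spec",
    "TWO_PATTERN_GEOMETRIES",
]

# the two planted geometries of the headline benchmark, as (r_RB, r_RG, r_BG)
TWO_PATTERN_GEOMETRIES: dict[str, tuple[float, float, float]] = {
    "equilateral-150": (150.0, 150.0, 150.0),
    "scalene-60-100-80": (60.0, 100.0, 80.0),
}


def two_pattern_mixture_spec(
    seed: int,
    canvas_nm: float = 10240.0,
    n_total: int = 1000,
    locs_per_molecule: float = 10.0,
    sigma: float = 5.0,
) -> SimulationSpec:
    """Two mixed triangle patterns, randomly placed and oriented."""
    patterns = [
        (PatternSpec.triangle(label, *dists), n_total // 2)
        for label, dists in TWO_PATTERN_GEOMETRIES.items()
    ]
    return SimulationSpec(
        canvas=Canvas(0.0, canvas_nm, 0.0, canvas_nm),
        patterns=patterns,
        sigma=sigma,
        locs_per_molecule=locs_per_molecule,
        seed=seed,
    )


def single_triangle_spec(
    seed: int,
    side_nm: float = 100.0,
    n_instances: int = 500,
    sigma: float = 5.0,
    canvas_nm: float = 5120.0,
    locs_per_molecule: float = 10.0,
) -> SimulationSpec:
    """One planted equilateral triangle, no background."""
    pat = PatternSpec.triangle(f"equilateral-{side_nm:g}", side_nm, side_nm, side_nm)
    return SimulationSpec(
        canvas=Canvas(0.0, canvas_nm, 0.0, canvas_nm),
        patterns=[(pat, n_instances)],
        sigma=sigma,
        locs_per_molecule=locs_per_molecule,
        seed=seed,
    )


def csr_spec(
    seed: int,
    density_per_um2: float = 100.0,
    canvas_nm: float = 10000.0,
    channels: tuple[str, ...] = ("R", "B", "G"),
) -> SimulationSpec:
    """Independent homogeneous (CSR) channels at a common density."""
    return SimulationSpec(
        canvas=Canvas(0.0, canvas_nm, 0.0, canvas_nm),
        background={ch: density_per_um2 for ch in channels},
        seed=seed,
    )


def fork_bystander_spec(
    seed: int,
    f_attached: float = 0.0,
    n_complexes: int = 1500,
    d_bg_nm: float = 75.0,
    apex_nm: float = 70.0,
    canvas_nm: float = 10240.0,
    locs_per_molecule: float = 1.0,
    sigma: float = 5.0,
    background_pair_per_um2: float = 40.0,
    background_c_per_um2: float = 150.0,
) -> SimulationSpec:
    """Planted B–G complexes with a third channel C attached to a fraction.

    A fraction ``f_attached`` of the ``n_complexes`` B–G pairs (spacing
    ``d_bg_nm``) carries a C molecule at distance ``apex_nm`` from both B and
    G; all three channels additionally receive CSR background.  With
    ``f_attached = 0`` the C channel is pure CSR, the null case for the
    conditional-probability estimate.

    One localization per molecule by default: the conditional identity
    P = g_TC / g_PC concerns molecule-level densities, and repeated
    localizations of one fluorophore would inflate clustered counts (and the
    variance of ridge maxima) without adding molecules.
    """
    if not 0.0 <= f_attached <= 1.0:
        raise ValueError("f_attached must lie in [0, 1]")
    n_with_c = int(round(f_attached * n_complexes))
    n_without = n_complexes - n_with_c
    patterns: list[tuple[PatternSpec, int]] = []
    if n_without:
        pair = PatternSpec(
            label="complex-BG",
            molecules=(("B", 0.0, 0.0), ("G", d_bg_nm, 0.0)),
        )
        patterns.append((pair, n_without))
    if n_with_c:
        # C sits at the isoceles apex above the B-G edge
        import numpy as np

        h = float(np.sqrt(max(apex_nm**2 - (d_bg_nm / 2.0) ** 2, 0.0)))
        tri = PatternSpec(
            label="complex-BGC",
            molecules=(
                ("B", 0.0, 0.0),
                ("G", d_bg_nm, 0.0),
                ("C", d_bg_nm / 2.0, h),
            ),
        )
        patterns.append((tri, n_with_c))
    return SimulationSpec(
        canvas=Canvas(0.0, canvas_nm, 0.0, canvas_nm),
        patterns=patterns,
        sigma=sigma,
        locs_per_molecule=locs_per_molecule,
        background={
            "B": background_pair_per_um2,
            "G": background_pair_per_um2,
            "C": background_c_per_um2,
        },
        seed=seed,
    )
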