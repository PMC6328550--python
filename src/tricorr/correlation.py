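"""Coordinate-based pair- and triple-correlation estimators.

The pair cross-correlation g(r) of two species A, B is the density of B at
distance r from an average A, divided by the density expected under
independence; complete spatial randomness (CSR) gives g = 1 everywhere.  The
triple correlation extends this to third order: every localization of an
origin species R is visited, the joint density of species B at displacement
(r1, θ) and species G at (r2, θ + Δθ) is histogrammed over all origins and
angles, and normalized by canvas area and the three average densities so that
three independent CSR channels give g = 1.  The (r1, r2, Δθ) histogram is
finally re-indexed to the three pairwise distances {r_RB, r_RG, r_BG} of the
triangle (law of cosines at bin centers), which is the natural,
chirality-free representation of a three-species geometric configuration.

Estimators (bin centers r1c, r2c; radial width dr; angular width ΔΘ over
[0, π]; canvas area A; counts N_R, N_B, N_G):

    pair:    g(r) = A / (N_A N_B) * sum_i n_B(annulus r) / (2π r_c dr e_i)
    triple:  g(r1, r2, Δθ) = A² / (N_R N_B N_G)
                 * W(r1, r2, Δθ) / (2π r1c dr * r2c dr * 2ΔΘ)

where W accumulates, over all triples within the cutoff, the edge-correction
weight 1 / (e_i(r1c) e_i(r2c)), and e_i(r) is the exact fraction of the circle
of radius r around origin i lying inside the canvas (closed-form arc
geometry).  The factor 2ΔΘ folds the two signs of Δθ.  All geometric factors
are evaluated at bin centers so the brute-force oracle is bit-comparable.

Neighbor search uses a KD-tree with cutoff r_max (never the all-pairs
product); :func:`tc_bruteforce` is the deliberately naive O(N³) oracle, and
:func:`tc_fourier_reference` the pixel-rendered Fourier (bispectrum) oracle.

Every profile also carries the analytic CSR expectation of its accumulator
and its CSR-null variance, which give per-bin Monte-Carlo standard errors for
calibration tests (see :func:`fraction_within_csr_noise`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.fft import next_fast_len
from scipy.spatial import cKDTree

from .io import Canvas, LocalizationSet

logger = logging.getLogger(__name__)

__all__ = [
    "RadialBins",
    "PairCorrelationProfile",
    "TripleCorrelationProfile",
    "edge_arc_fraction",
    "edge_arc_fractions",
    "compute_pair_correlation",
    "compute_triple_correlation",
    "tc_bruteforce",
    "tc_fourier_reference",
    "pool_pair_profiles",
    "pool_triple_profiles",
    "fraction_within_csr_noise",
]

EDGE_FRACTION_CAP = 0.05  # arc fractions below this are clamped (weight cap)
_CHUNK_COMBOS = 4_000_000  # triples accumulated per vectorized chunk
_BRUTE_CAP = 100_000_000  # refuse brute force beyond this many raw triples


class EmptyProfileError(ValueError):
    """A correlation was requested on an empty localization set."""


class AllBinsMaskedError(ValueError):
    """No valid bin remains in the requested profile."""


# ---------------------------------------------------------------------------
# bins


@dataclass(frozen=True)
class RadialBins:
    """Half-open radial bins (0, r_max] of width dr, plus angular bins.

    ``n_theta`` angular bins cover the unsigned angle range [0, π]; the
    distance r_BG axis extends to 2 r_max (the largest triangle side reachable
    from two legs of length r_max).  Distances exactly on a bin edge belong to
    the lower-adjacent bin's upper neighbor, i.e. bins are (low, high].
    """

    dr: float = 10.0
    r_max: float = 300.0
    n_theta: int = 72

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.r_max <= 0:
            raise ValueError("dr and r_max must be positive")
        n = self.r_max / self.dr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("r_max must be an integer multiple of dr")
        if self.n_theta < 1:
            raise ValueError("n_theta must be >= 1")

    @property
    def n_r(self) -> int:
        return int(round(self.r_max / self.dr))

    @property
    def n_r3(self) -> int:
        return 2 * self.n_r

    @property
    def dtheta(self) -> float:
        return np.pi / self.n_theta

    @property
    def r_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_r + 1)

    @property
    def r_centers(self) -> np.ndarray:
        e = self.r_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def r3_edges(self) -> np.ndarray:
        return np.linspace(0.0, 2.0 * self.r_max, self.n_r3 + 1)

    @property
    def r3_centers(self) -> np.ndarray:
        e = self.r3_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return (np.arange(self.n_theta) + 0.5) * self.dtheta

    def r_bin(self, r: np.ndarray) -> np.ndarray:
        """Index of the (0, r_max] bin holding each distance; -1 if below."""
        return np.searchsorted(self.r_edges, np.asarray(r, dtype=float), side="left") - 1

    def r3_bin(self, r: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.r3_edges, np.asarray(r, dtype=float), side="left") - 1

    def theta_bin(self, dth: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(
            np.linspace(0.0, np.pi, self.n_theta + 1), np.asarray(dth, dtype=float), side="left"
        ) - 1
        return np.clip(idx, 0, self.n_theta - 1)


# ---------------------------------------------------------------------------
# edge correction


def edge_arc_fractions(
    origins: np.ndarray, radii: np.ndarray, canvas: Canvas
) -> np.ndarray:
    """Fraction of each circle (origin, radius) lying inside the canvas.

    Exact closed form: a circle point is outside the closed rectangle iff it
    violates at least one of the four half-plane constraints; each violated
    constraint excludes an arc of half-width arccos(d/r) centered on the
    outward wall normal, and because every half-width is <= π/2 only arcs of
    adjacent walls can overlap.

    Returns an (N, M) array for N origins and M radii, values in [0, 1].
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if not np.all(canvas.contains(origins)):
        raise ValueError("all origins must lie inside the canvas")

    # wall distances, ordered so consecutive entries are adjacent walls
    d = np.stack(
        [
            origins[:, 0] - canvas.x_min,  # left
            origins[:, 1] - canvas.y_min,  # bottom
            canvas.x_max - origins[:, 0],  # right
            canvas.y_max - origins[:, 1],  # top
        ],
        axis=1,
    )  # (N, 4)
    ratio = d[:, :, None] / radii[None, None, :]  # (N, 4, M)
    a = np.arccos(np.clip(ratio, -1.0, 1.0))
    a[ratio >= 1.0] = 0.0
    excluded = 2.0 * a.sum(axis=1)
    # overlaps of adjacent wall arcs: (left,bottom), (bottom,right),
    # (right,top), (top,left)
    for i in range(4):
        j = (i + 1) % 4
        excluded -= np.maximum(0.0, a[:, i] + a[:, j] - 0.5 * np.pi)
    return np.clip(1.0 - excluded / (2.0 * np.pi), 0.0, 1.0)


def edge_arc_fraction(origin: Sequence[float], r: float, canvas: Canvas) -> float:
    """Scalar convenience wrapper around :func:`edge_arc_fractions`."""
    return float(edge_arc_fractions(np.asarray(origin, float)[None, :], [r], canvas)[0, 0])


# ---------------------------------------------------------------------------
# profiles


@dataclass
class PairCorrelationProfile:
    """Edge-corrected cross- (or auto-) pair correlation over radial bins."""

    channels: tuple[str, str]
    bins: RadialBins
    g: np.ndarray  # (n_r,), NaN on masked bins
    mask: np.ndarray  # (n_r,) bool
    sum_w: np.ndarray  # raw edge-weighted pair counts
    csr_expected: np.ndarray  # E[sum_w] under CSR
    csr_var: np.ndarray  # Var[sum_w] under CSR
    n_a: int
    n_b: int
    n_origins_used: int
    area: float
    edge_mode: str = "arc"
    auto: bool = False
    min_expected: float = 0.0
    profile_id: str = ""

    def g_at(self, r: float, interpolate: bool = False) -> float:
        """g at distance r: containing bin by default, linear if requested."""
        centers = self.bins.r_centers
        idx = int(self.bins.r_bin(np.array([r]))[0])
        if idx < 0 or idx >= self.bins.n_r:
            raise ValueError(f"r={r} nm outside the binned range (0, {self.bins.r_max}]")
        if not self.mask[idx]:
            raise ValueError(f"g(r) undefined: bin at {centers[idx]} nm is masked")
        if not interpolate:
            return float(self.g[idx])
        lo = idx if r >= centers[idx] else idx - 1
        hi = lo + 1
        if lo < 0 or hi >= self.bins.n_r or not (self.mask[lo] and self.mask[hi]):
            return float(self.g[idx])
        t = (r - centers[lo]) / (centers[hi] - centers[lo])
        return float((1 - t) * self.g[lo] + t * self.g[hi])

    def save(self, path: Union[str, Path]) -> None:
        _save_profile_h5(self, path, kind="pair")

    @staticmethod
    def load(path: Union[str, Path]) -> "PairCorrelationProfile":
        return _load_profile_h5(path, kind="pair")


@dataclass
class TripleCorrelationProfile:
    """Triple correlation over the triangle-distance grid (r_RB, r_RG, r_BG).

    ``g`` is NaN outside ``mask``; the mask excludes bins whose centers
    violate the triangle inequality, bins no angular bin maps into, and bins
    whose CSR expectation falls below ``min_expected`` accumulated counts
    (low-expectation bins carry uninformative, spurious-peak-prone noise).
    """

    roles: tuple[str, str, str]  # origin R, satellites B and G
    bins: RadialBins
    g: np.ndarray  # (n_r, n_r, n_r3)
    mask: np.ndarray
    sum_w: np.ndarray
    csr_expected: np.ndarray
    csr_var: Optional[np.ndarray]
    n_contrib: np.ndarray  # angular bins mapping into each r3 bin
    n_r_pts: int
    n_b_pts: int
    n_g_pts: int
    n_origins_used: int
    area: float
    edge_mode: str = "arc"
    min_expected: float = 10.0
    profile_id: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def argmax(self) -> tuple[int, int, int]:
        """Grid index of the global maximum over valid bins."""
        if not self.mask.any():
            raise AllBinsMaskedError("profile has no valid bins")
        g = np.where(self.mask, self.g, -np.inf)
        return tuple(int(i) for i in np.unravel_index(np.argmax(g), g.shape))

    def distances_at(self, idx: tuple[int, int, int]) -> tuple[float, float, float]:
        """Bin-center triangle distances (r_RB, r_RG, r_BG) at a grid index."""
        c, c3 = self.bins.r_centers, self.bins.r3_centers
        return float(c[idx[0]]), float(c[idx[1]]), float(c3[idx[2]])

    def save(self, path: Union[str, Path]) -> None:
        _save_profile_h5(self, path, kind="triple")

    @staticmethod
    def load(path: Union[str, Path]) -> "TripleCorrelationProfile":
        return _load_profile_h5(path, kind="triple")


# ---------------------------------------------------------------------------
# shared internals


def _feasible_centers(bins: RadialBins) -> np.ndarray:
    """Triangle-inequality mask at bin centers, shape (n_r, n_r, n_r3)."""
    r1 = bins.r_centers[:, None, None]
    r2 = bins.r_centers[None, :, None]
    r3 = bins.r3_centers[None, None, :]
    return (np.abs(r1 - r2) <= r3) & (r3 <= r1 + r2)


def _check_r_max(bins: RadialBins, canvas: Canvas) -> None:
    if bins.r_max > min(canvas.width, canvas.height) / 2.0:
        logger.warning(
            "r_max=%.0f nm exceeds half the shorter canvas side (%.0f nm); "
            "edge-correction weights become extreme",
            bins.r_max,
            min(canvas.width, canvas.height) / 2.0,
        )


def _inv_edge_weights(origins: np.ndarray, bins: RadialBins, canvas: Canvas) -> np.ndarray:
    """1 / e_i(r_c) per origin and radial bin, with the small-fraction cap."""
    e = edge_arc_fractions(origins, bins.r_centers, canvas)
    n_capped = int((e < EDGE_FRACTION_CAP).sum())
    if n_capped:
        logger.warning(
            "%d (origin, radius) edge fractions below %.2f were capped",
            n_capped,
            EDGE_FRACTION_CAP,
        )
    return 1.0 / np.clip(e, EDGE_FRACTION_CAP, 1.0)


def _guard_origin_mask(origins: np.ndarray, r_max: float, canvas: Canvas) -> np.ndarray:
    return (
        (origins[:, 0] - canvas.x_min >= r_max)
        & (canvas.x_max - origins[:, 0] >= r_max)
        & (origins[:, 1] - canvas.y_min >= r_max)
        & (canvas.y_max - origins[:, 1] >= r_max)
    )


def _segmented_cross(counts_b: np.ndarray, counts_g: np.ndarray):
    """Per-origin cartesian product of two grouped arrays.

    Given per-origin group sizes in two parallel grouped arrays, return index
    arrays (into the grouped arrays) enumerating, origin by origin, every
    (B, G) combination — B-major, preserving ascending order on both sides so
    accumulation order matches a naive triple loop.
    """
    t = counts_b * counts_g
    total = int(t.sum())
    start = np.cumsum(t) - t
    local = np.arange(total, dtype=np.int64) - np.repeat(start, t)
    gc = np.repeat(counts_g, t)
    jb = local // gc
    jg = local - jb * gc
    idx_b = np.repeat(np.cumsum(counts_b) - counts_b, t) + jb
    idx_g = np.repeat(np.cumsum(counts_g) - counts_g, t) + jg
    return idx_b, idx_g


def _grouped_satellites_kdtree(
    origin_xy: np.ndarray, sat_xy: np.ndarray, r_max: float
):
    """(origin index, distance, angle) of satellites within r_max, grouped.

    Satellite indices are sorted ascending within each origin so the
    accumulation order equals the brute-force loop's.
    """
    tree_o = cKDTree(origin_xy)
    tree_s = cKDTree(sat_xy)
    lists = tree_o.query_ball_tree(tree_s, r_max)
    counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
    if counts.sum() == 0:
        empty = np.zeros(0)
        return counts, empty, empty
    sat_idx = np.concatenate([np.sort(l) for l in lists if l]).astype(np.int64)
    origin_idx = np.repeat(np.arange(len(origin_xy)), counts)
    return counts, origin_idx, sat_idx


def _grouped_satellites_brute(origin_xy: np.ndarray, sat_xy: np.ndarray, r_max: float):
    """All-pairs distance-matrix variant of the neighbor grouping."""
    diff = sat_xy[None, :, :] - origin_xy[:, None, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    within = dist <= r_max
    counts = within.sum(axis=1).astype(np.int64)
    origin_idx, sat_idx = np.nonzero(within)  # row-major: ascending per origin
    return counts, origin_idx.astype(np.int64), sat_idx.astype(np.int64)


def _dist_angle(origin_xy, sat_xy, origin_idx, sat_idx):
    d = sat_xy[sat_idx] - origin_xy[origin_idx]
    return np.hypot(d[:, 0], d[:, 1]), np.arctan2(d[:, 1], d[:, 0])


def _regroup(counts, origin_idx, keep):
    """Drop entries failing ``keep`` and recompute per-origin counts."""
    new_counts = np.bincount(origin_idx[keep], minlength=len(counts)).astype(np.int64)
    return new_counts


# ---------------------------------------------------------------------------
# pair correlation


def compute_pair_correlation(
    set_a: LocalizationSet,
    set_b: LocalizationSet,
    bins: RadialBins = RadialBins(),
    edge: str = "arc",
    min_expected: float = 0.0,
    profile_id: str = "",
) -> PairCorrelationProfile:
    """Edge-corrected pair correlation g(r) between species A and B.

    Pass the same object twice for the auto-correlation (self-pairs are then
    excluded).  ``edge`` selects the correction: ``"arc"`` weights every pair
    by the inverse in-canvas arc fraction at the origin; ``"guard"`` discards
    origins closer than r_max to the boundary and applies no weights.
    """
    if set_a.n < 1 or set_b.n < 1:
        raise EmptyProfileError("pair correlation requires non-empty channels")
    if set_a.canvas != set_b.canvas:
        raise ValueError("both channels must share one canvas")
    canvas = set_a.canvas
    _check_r_max(bins, canvas)
    auto = set_a is set_b

    origins = set_a.xy
    if edge == "arc":
        used = np.arange(set_a.n)
    elif edge == "guard":
        keep = _guard_origin_mask(origins, bins.r_max, canvas)
        used = np.flatnonzero(keep)
        if used.size == 0:
            raise EmptyProfileError("guard mode removed every origin; reduce r_max")
        origins = origins[keep]
    else:
        raise ValueError(f"unknown edge mode {edge!r}")

    n_used = len(origins)
    inv_e = (
        _inv_edge_weights(origins, bins, canvas)
        if edge == "arc"
        else np.ones((n_used, bins.n_r))
    )

    counts, origin_idx, sat_idx = _grouped_satellites_kdtree(origins, set_b.xy, bins.r_max)
    n_r = bins.n_r
    sum_w = np.zeros(n_r)
    if counts.sum():
        dist, _ = _dist_angle(origins, set_b.xy, origin_idx, sat_idx)
        rbin = bins.r_bin(dist)
        keep = rbin >= 0
        if auto:
            keep &= used[origin_idx] != sat_idx
        if keep.any():
            w = inv_e[origin_idx[keep], rbin[keep]]
            sum_w = np.bincount(rbin[keep], weights=w, minlength=n_r)

    area = canvas.area()
    rho_b = set_b.n / area
    geo = 2.0 * np.pi * bins.r_centers * bins.dr
    expected = n_used * rho_b * geo
    if edge == "arc":
        var = rho_b * geo * inv_e.sum(axis=0)
    else:
        var = expected.copy()

    mask = expected >= max(min_expected, np.finfo(float).tiny)
    g = np.full(n_r, np.nan)
    g[mask] = sum_w[mask] / expected[mask]
    return PairCorrelationProfile(
        channels=(set_a.channel, set_b.channel),
        bins=bins,
        g=g,
        mask=mask,
        sum_w=sum_w,
        csr_expected=expected,
        csr_var=var,
        n_a=set_a.n,
        n_b=set_b.n,
        n_origins_used=n_used,
        area=area,
        edge_mode=edge,
        auto=auto,
        min_expected=min_expected,
        profile_id=profile_id,
    )


# ---------------------------------------------------------------------------
# triple correlation


def _triple_from_grouped(
    set_r: LocalizationSet,
    set_b: LocalizationSet,
    set_g: LocalizationSet,
    bins: RadialBins,
    edge: str,
    min_expected: float,
    profile_id: str,
    grouped_fn,
) -> TripleCorrelationProfile:
    for s, role in ((set_r, "R"), (set_b, "B"), (set_g, "G")):
        if s.n < 1:
            raise EmptyProfileError(f"triple correlation requires a non-empty {role} channel")
    if not (set_r.canvas == set_b.canvas == set_g.canvas):
        raise ValueError("all three channels must share one canvas")
    canvas = set_r.canvas
    _check_r_max(bins, canvas)

    origins = set_r.xy
    if edge == "guard":
        keep = _guard_origin_mask(origins, bins.r_max, canvas)
        origins = origins[keep]
        if len(origins) == 0:
            raise EmptyProfileError("guard mode removed every origin; reduce r_max")
    elif edge != "arc":
        raise ValueError(f"unknown edge mode {edge!r}")
    n_used = len(origins)

    inv_e = (
        _inv_edge_weights(origins, bins, canvas)
        if edge == "arc"
        else np.ones((n_used, bins.n_r))
    )

    cb, ob, sb = grouped_fn(origins, set_b.xy, bins.r_max)
    cg, og, sg = grouped_fn(origins, set_g.xy, bins.r_max)

    n_r, n_t = bins.n_r, bins.n_theta
    w_theta = np.zeros(n_r * n_r * n_t)

    if cb.sum() and cg.sum():
        d_b, th_b = _dist_angle(origins, set_b.xy, ob, sb)
        d_g, th_g = _dist_angle(origins, set_g.xy, og, sg)
        bin_b = bins.r_bin(d_b)
        bin_g = bins.r_bin(d_g)
        keep_b = bin_b >= 0  # zero-distance cross-channel coincidences drop out
        keep_g = bin_g >= 0
        cb = _regroup(cb, ob, keep_b)
        cg = _regroup(cg, og, keep_g)
        ob, bin_b, th_b = ob[keep_b], bin_b[keep_b], th_b[keep_b]
        og, bin_g, th_g = og[keep_g], bin_g[keep_g], th_g[keep_g]

        # chunk origins so per-chunk combination counts stay bounded
        t = cb * cg
        cum = np.cumsum(t)
        chunk_ids = (cum // _CHUNK_COMBOS).astype(np.int64)
        boundaries = np.flatnonzero(np.diff(chunk_ids)) + 1
        origin_splits = np.concatenate([[0], boundaries, [len(t)]])
        off_b = np.concatenate([[0], np.cumsum(cb)])
        off_g = np.concatenate([[0], np.cumsum(cg)])
        for lo, hi in zip(origin_splits[:-1], origin_splits[1:]):
            if lo == hi or t[lo:hi].sum() == 0:
                continue
            slb = slice(off_b[lo], off_b[hi])
            slg = slice(off_g[lo], off_g[hi])
            ib, ig = _segmented_cross(cb[lo:hi], cg[lo:hi])
            b1 = bin_b[slb][ib]
            b2 = bin_g[slg][ig]
            dth = np.abs(th_b[slb][ib] - th_g[slg][ig])
            dth = np.minimum(dth, 2.0 * np.pi - dth)
            bt = bins.theta_bin(dth)
            w = inv_e[ob[slb][ib], b1] * inv_e[og[slg][ig], b2]
            flat = (b1 * n_r + b2) * n_t + bt
            w_theta += np.bincount(flat, weights=w, minlength=n_r * n_r * n_t)

    w_theta = w_theta.reshape(n_r, n_r, n_t)

    area = canvas.area()
    rho_b = set_b.n / area
    rho_g = set_g.n / area
    geo1 = 2.0 * np.pi * bins.r_centers * bins.dr  # (n_r,)
    geo2 = bins.r_centers * bins.dr * 2.0 * bins.dtheta  # (n_r,)
    e_theta = n_used * rho_b * rho_g * np.outer(geo1, geo2)  # (n_r, n_r)
    s2 = inv_e.T @ inv_e  # sum_i 1/(e_i(r1) e_i(r2))
    v_theta = rho_b * rho_g * np.outer(geo1, geo2) * s2

    # re-index each Δθ slice to the r_BG bin given by the law of cosines at
    # bin centers; CSR-expectation weighting reduces to summing accumulators
    r1c = bins.r_centers[:, None, None]
    r2c = bins.r_centers[None, :, None]
    thc = bins.theta_centers[None, None, :]
    r3 = np.sqrt(
        np.maximum(r1c**2 + r2c**2 - 2.0 * r1c * r2c * np.cos(thc), 0.0)
    )
    idx3 = bins.r3_bin(r3)
    idx3 = np.clip(idx3, 0, bins.n_r3 - 1)  # r3=0 only for degenerate centers

    n_r3 = bins.n_r3
    grid12 = (np.arange(n_r)[:, None, None] * n_r + np.arange(n_r)[None, :, None])
    flat3 = (grid12 * n_r3 + idx3).ravel()
    size3 = n_r * n_r * n_r3
    sum_w3 = np.bincount(flat3, weights=w_theta.ravel(), minlength=size3)
    e3 = np.bincount(
        flat3, weights=np.broadcast_to(e_theta[:, :, None], w_theta.shape).ravel(),
        minlength=size3,
    )
    v3 = np.bincount(
        flat3, weights=np.broadcast_to(v_theta[:, :, None], w_theta.shape).ravel(),
        minlength=size3,
    )
    n_contrib = np.bincount(flat3, minlength=size3)

    shape = (n_r, n_r, n_r3)
    return _finalize_triple(
        roles=(set_r.channel, set_b.channel, set_g.channel),
        bins=bins,
        sum_w=sum_w3.reshape(shape),
        expected=e3.reshape(shape),
        var=v3.reshape(shape),
        n_contrib=n_contrib.reshape(shape),
        n_pts=(set_r.n, set_b.n, set_g.n),
        n_origins_used=n_used,
        area=area,
        edge_mode=edge,
        min_expected=min_expected,
        profile_id=profile_id,
    )


def _finalize_triple(
    roles,
    bins,
    sum_w,
    expected,
    var,
    n_contrib,
    n_pts,
    n_origins_used,
    area,
    edge_mode,
    min_expected,
    profile_id,
) -> TripleCorrelationProfile:
    feasible = _feasible_centers(bins)
    mask = (
        feasible
        & (n_contrib > 0)
        & (expected >= max(min_expected, np.finfo(float).tiny))
    )
    if not mask.any():
        raise AllBinsMaskedError(
            "every bin of the triple-correlation grid is masked; "
            "check densities, r_max and min_expected"
        )
    g = np.full(mask.shape, np.nan)
    g[mask] = sum_w[mask] / expected[mask]
    return TripleCorrelationProfile(
        roles=roles,
        bins=bins,
        g=g,
        mask=mask,
        sum_w=sum_w,
        csr_expected=expected,
        csr_var=var,
        n_contrib=n_contrib,
        n_r_pts=n_pts[0],
        n_b_pts=n_pts[1],
        n_g_pts=n_pts[2],
        n_origins_used=n_origins_used,
        area=area,
        edge_mode=edge_mode,
        min_expected=min_expected,
        profile_id=profile_id,
    )


def compute_triple_correlation(
    set_r: LocalizationSet,
    set_b: LocalizationSet,
    set_g: LocalizationSet,
    bins: RadialBins = RadialBins(),
    edge: str = "arc",
    min_expected: float = 10.0,
    profile_id: str = "",
) -> TripleCorrelationProfile:
    """Triple correlation over triangle distances, KD-tree accelerated.

    ``set_r`` is the origin species; ``set_b`` and ``set_g`` are the two
    satellites whose displacement vectors from each origin define the
    (r_RB, r_RG, Δθ) accumulation.  See the module docstring for the
    estimator; the result is indexed by (r_RB, r_RG, r_BG).
    """
    return _triple_from_grouped(
        set_r, set_b, set_g, bins, edge, min_expected, profile_id,
        _grouped_satellites_kdtree,
    )


def tc_bruteforce(
    set_r: LocalizationSet,
    set_b: LocalizationSet,
    set_g: LocalizationSet,
    bins: RadialBins = RadialBins(),
    edge: str = "arc",
    min_expected: float = 10.0,
    profile_id: str = "",
) -> TripleCorrelationProfile:
    """Validation oracle: identical estimator via explicit all-pairs distances.

    No spatial index and no cutoff shortcut — every origin-satellite distance
    is computed from the full distance matrices.  Refuses inputs beyond
    ``10^8`` raw triples.
    """
    n_triples = set_r.n * set_b.n * set_g.n
    if n_triples > _BRUTE_CAP:
        raise ValueError(
            f"brute force refused: {n_triples:.2e} raw triples exceeds the "
            f"{_BRUTE_CAP:.0e} cap"
        )
    return _triple_from_grouped(
        set_r, set_b, set_g, bins, edge, min_expected, profile_id,
        _grouped_satellites_brute,
    )


# ---------------------------------------------------------------------------
# Fourier-transform reference (pixel-rendered bispectrum route; test oracle)


def tc_fourier_reference(
    set_r: LocalizationSet,
    set_b: LocalizationSet,
    set_g: LocalizationSet,
    bins: RadialBins = RadialBins(),
    pixel_nm: float = 5.0,
    binary: bool = True,
    max_grid: int = 1200,
    profile_id: str = "",
) -> TripleCorrelationProfile:
    """Triple correlation via pixel rendering and FFT cross-correlation.

    The classic route: localizations are rendered onto a pixel grid (binary
    occupancy by default), the third-order correlation T(a, b) =
    Σ_R I_R(R) I_B(R+a) I_G(R+b) is evaluated with FFTs for all displacements
    up to r_max, normalized by the analytic overlap volume and the mean
    densities, and radially re-binned onto the same (r_RB, r_RG, r_BG) grid
    as the coordinate estimator.  Test-only oracle: quadratic in grid size
    and limited by pixelation accuracy.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    canvas = set_r.canvas
    if not (canvas == set_b.canvas == set_g.canvas):
        raise ValueError("all three channels must share one canvas")
    nx = int(round(canvas.width / pixel_nm))
    ny = int(round(canvas.height / pixel_nm))
    if max(nx, ny) > max_grid:
        raise ValueError(
            f"pixel grid {nx}x{ny} exceeds max_grid={max_grid}; use a smaller "
            "canvas or larger pixels for the Fourier reference"
        )

    def render(s: LocalizationSet) -> np.ndarray:
        img = np.zeros((ny, nx))
        ix = np.clip(((s.xy[:, 0] - canvas.x_min) / pixel_nm).astype(int), 0, nx - 1)
        iy = np.clip(((s.xy[:, 1] - canvas.y_min) / pixel_nm).astype(int), 0, ny - 1)
        np.add.at(img, (iy, ix), 1.0)
        return np.minimum(img, 1.0) if binary else img

    img_r, img_b, img_g = render(set_r), render(set_b), render(set_g)
    n1, n2, n3 = img_r.sum(), img_b.sum(), img_g.sum()
    if min(n1, n2, n3) == 0:
        raise EmptyProfileError("a channel rendered to an empty image")

    smax = int(np.ceil(bins.r_max / pixel_nm))
    pad = next_fast_len(max(nx, ny) + smax + 1)
    f_g = np.fft.rfft2(img_g, s=(pad, pad))

    # displacement grids for the b window
    win = np.arange(-smax, smax + 1)
    wrap = win % pad
    bx = win[None, :]
    by = win[:, None]
    r2_pix = np.hypot(bx, by)
    r2bin = bins.r_bin((r2_pix * pixel_nm).ravel()).reshape(r2_pix.shape)

    # all a displacements with r1 in range
    axs, ays = np.meshgrid(win, win)
    r1_nm = np.hypot(axs, ays).ravel() * pixel_nm
    r1bin_all = bins.r_bin(r1_nm)
    keep_a = (r1bin_all >= 0) & (r1_nm <= bins.r_max)
    a_list = np.column_stack([axs.ravel()[keep_a], ays.ravel()[keep_a]])
    r1bin_list = r1bin_all[keep_a]

    n_r, n_r3 = bins.n_r, bins.n_r3
    size3 = n_r * n_r * n_r3
    t_sum = np.zeros(size3)
    v_sum = np.zeros(size3)
    pair_count = np.zeros(size3, dtype=np.int64)

    def overlap(shift: np.ndarray, n: int) -> np.ndarray:
        hi = np.maximum(np.maximum(shift[0], shift[1]), 0)
        lo = np.minimum(np.minimum(shift[0], shift[1]), 0)
        return np.maximum(n - (hi - lo), 0)

    batch = 16
    for start in range(0, len(a_list), batch):
        sel = a_list[start : start + batch]
        js = np.zeros((len(sel), ny, nx))
        for k, (ax, ay) in enumerate(sel):
            x0, x1 = max(0, -ax), nx - max(0, ax)
            y0, y1 = max(0, -ay), ny - max(0, ay)
            if x1 <= x0 or y1 <= y0:
                continue
            js[k, y0:y1, x0:x1] = (
                img_r[y0:y1, x0:x1] * img_b[y0 + ay : y1 + ay, x0 + ax : x1 + ax]
            )
        fj = np.fft.rfft2(js, s=(pad, pad), axes=(-2, -1))
        corr = np.fft.irfft2(np.conj(fj) * f_g[None], s=(pad, pad), axes=(-2, -1))
        window = corr[:, wrap[:, None], wrap[None, :]]  # (batch, 2s+1, 2s+1)

        for k, (ax, ay) in enumerate(sel):
            r1b = r1bin_list[start + k]
            r3_pix = np.hypot(bx - ax, by - ay)
            r3b = bins.r3_bin((r3_pix * pixel_nm).ravel()).reshape(r3_pix.shape)
            vx = overlap(np.array([ax * np.ones_like(bx), bx]), nx)
            vy = overlap(np.array([ay * np.ones_like(by), by]), ny)
            vol = (vx * vy).astype(float)
            ok = (r2bin >= 0) & (r2bin < n_r) & (r3b >= 0) & (r3b < n_r3) & (vol > 0)
            flat = (r1b * n_r + r2bin[ok]) * n_r3 + r3b[ok]
            t_sum += np.bincount(flat, weights=window[k][ok], minlength=size3)
            v_sum += np.bincount(flat, weights=vol[ok], minlength=size3)
            pair_count += np.bincount(flat, minlength=size3)

    area = canvas.area()
    rho = (n1 / area) * (n2 / area) * (n3 / area)
    # E[T(a,b)] under CSR is V(a,b) * (rho_1 px^2)(rho_2 px^2)(rho_3 px^2)
    # with V the number of grid positions where all three factors overlap
    expected = v_sum * (rho * pixel_nm**6)

    shape = (n_r, n_r, n_r3)
    return _finalize_triple(
        roles=(set_r.channel, set_b.channel, set_g.channel),
        bins=bins,
        sum_w=t_sum.reshape(shape),
        expected=expected.reshape(shape),
        var=None,
        n_contrib=pair_count.reshape(shape),
        n_pts=(int(n1), int(n2), int(n3)),
        n_origins_used=int(n1),
        area=area,
        edge_mode="fourier",
        min_expected=0.0,
        profile_id=profile_id,
    )


# ---------------------------------------------------------------------------
# pooling and calibration checks


def pool_pair_profiles(profiles: Sequence[PairCorrelationProfile]) -> PairCorrelationProfile:
    """Combine replicate pair profiles by summing their accumulators.

    The pooled estimate is the CSR-expectation-weighted average of the
    replicates, so a CSR input still pools to g = 1.
    """
    if not profiles:
        raise ValueError("nothing to pool")
    p0 = profiles[0]
    for p in profiles[1:]:
        if p.bins != p0.bins or p.channels != p0.channels or p.edge_mode != p0.edge_mode:
            raise ValueError("profiles to pool must share bins, channels and edge mode")
    sum_w = np.sum([p.sum_w for p in profiles], axis=0)
    expected = np.sum([p.csr_expected for p in profiles], axis=0)
    var = np.sum([p.csr_var for p in profiles], axis=0)
    mask = expected >= max(p0.min_expected, np.finfo(float).tiny)
    g = np.full_like(sum_w, np.nan)
    g[mask] = sum_w[mask] / expected[mask]
    return replace(
        p0,
        g=g,
        mask=mask,
        sum_w=sum_w,
        csr_expected=expected,
        csr_var=var,
        n_a=sum(p.n_a for p in profiles),
        n_b=sum(p.n_b for p in profiles),
        n_origins_used=sum(p.n_origins_used for p in profiles),
        profile_id="+".join(filter(None, (p.profile_id for p in profiles))),
    )


def pool_triple_profiles(
    profiles: Sequence[TripleCorrelationProfile],
) -> TripleCorrelationProfile:
    """Combine replicate triple profiles by summing their accumulators."""
    if not profiles:
        raise ValueError("nothing to pool")
    p0 = profiles[0]
    for p in profiles[1:]:
        if p.bins != p0.bins or p.roles != p0.roles or p.edge_mode != p0.edge_mode:
            raise ValueError("profiles to pool must share bins, roles and edge mode")
        if p.csr_var is None or p0.csr_var is None:
            raise ValueError("profiles without CSR variance cannot be pooled")
    return _finalize_triple(
        roles=p0.roles,
        bins=p0.bins,
        sum_w=np.sum([p.sum_w for p in profiles], axis=0),
        expected=np.sum([p.csr_expected for p in profiles], axis=0),
        var=np.sum([p.csr_var for p in profiles], axis=0),
        n_contrib=np.sum([p.n_contrib for p in profiles], axis=0),
        n_pts=(
            sum(p.n_r_pts for p in profiles),
            sum(p.n_b_pts for p in profiles),
            sum(p.n_g_pts for p in profiles),
        ),
        n_origins_used=sum(p.n_origins_used for p in profiles),
        area=p0.area,
        edge_mode=p0.edge_mode,
        min_expected=p0.min_expected,
        profile_id="+".join(filter(None, (p.profile_id for p in profiles))),
    )


def fraction_within_csr_noise(
    profile: Union[PairCorrelationProfile, TripleCorrelationProfile],
    n_se: float = 3.0,
) -> float:
    """Fraction of valid bins whose deviation from CSR (g=1) is within n_se
    Monte-Carlo standard errors.

    The per-bin standard error is the analytic CSR-null sampling error of the
    accumulator, sqrt(E[sum of squared weights]); the statistic tested is
    z = (sum_w - E) / SE.
    """
    if profile.csr_var is None:
        raise ValueError("profile carries no CSR variance")
    m = profile.mask
    se = np.sqrt(profile.csr_var[m])
    z = (profile.sum_w[m] - profile.csr_expected[m]) / se
    return float(np.mean(np.abs(z) <= n_se))


# ---------------------------------------------------------------------------
# HDF5 serialization


def _save_profile_h5(profile, path, kind: str) -> None:
    import h5py

    from . import __version__

    with h5py.File(path, "w") as f:
        f.attrs["kind"] = kind
        f.attrs["version"] = __version__
        f.attrs["profile_id"] = profile.profile_id
        f.attrs["edge_mode"] = profile.edge_mode
        f.attrs["min_expected"] = profile.min_expected
        f.attrs["area_nm2"] = profile.area
        b = profile.bins
        f.attrs["dr"] = b.dr
        f.attrs["r_max"] = b.r_max
        f.attrs["n_theta"] = b.n_theta
        f.create_dataset("g", data=profile.g)
        f.create_dataset("mask", data=profile.mask)
        f.create_dataset("sum_w", data=profile.sum_w)
        f.create_dataset("csr_expected", data=profile.csr_expected)
        if profile.csr_var is not None:
            f.create_dataset("csr_var", data=profile.csr_var)
        f.create_dataset("bin_edges_r", data=b.r_edges)
        if kind == "pair":
            f.attrs["channels"] = list(profile.channels)
            f.attrs["auto"] = profile.auto
            f.attrs["n_a"] = profile.n_a
            f.attrs["n_b"] = profile.n_b
            f.attrs["n_origins_used"] = profile.n_origins_used
        else:
            f.attrs["roles"] = list(profile.roles)
            f.attrs["n_r_pts"] = profile.n_r_pts
            f.attrs["n_b_pts"] = profile.n_b_pts
            f.attrs["n_g_pts"] = profile.n_g_pts
            f.attrs["n_origins_used"] = profile.n_origins_used
            f.create_dataset("n_contrib", data=profile.n_contrib)
            f.create_dataset("bin_edges_r3", data=b.r3_edges)


def _load_profile_h5(path, kind: str):
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs["kind"] != kind:
            raise ValueError(f"{path} holds a {f.attrs['kind']} profile, expected {kind}")
        bins = RadialBins(
            dr=float(f.attrs["dr"]),
            r_max=float(f.attrs["r_max"]),
            n_theta=int(f.attrs["n_theta"]),
        )
        common = dict(
            bins=bins,
            g=f["g"][...],
            mask=f["mask"][...].astype(bool),
            sum_w=f["sum_w"][...],
            csr_expected=f["csr_expected"][...],
            area=float(f.attrs["area_nm2"]),
            edge_mode=str(f.attrs["edge_mode"]),
            min_expected=float(f.attrs["min_expected"]),
            profile_id=str(f.attrs["profile_id"]),
        )
        csr_var = f["csr_var"][...] if "csr_var" in f else None
        if kind == "pair":
            return PairCorrelationProfile(
                channels=tuple(f.attrs["channels"]),
                csr_var=csr_var,
                auto=bool(f.attrs["auto"]),
                n_a=int(f.attrs["n_a"]),
                n_b=int(f.attrs["n_b"]),
                n_origins_used=int(f.attrs["n_origins_used"]),
                **common,
            )
        return TripleCorrelationProfile(
            roles=tuple(f.attrs["roles"]),
            csr_var=csr_var,
            n_contrib=f["n_contrib"][...],
            n_r_pts=int(f.attrs["n_r_pts"]),
            n_b_pts=int(f.attrs["n_b_pts"]),
            n_g_pts=int(f.attrs["n_g_pts"]),
            n_origins_used=int(f.attrs["n_origins_used"]),
            **common,
        )
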