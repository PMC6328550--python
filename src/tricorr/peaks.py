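"""Significant configurations: local maxima of a triple-correlation profile.

A three-species geometric configuration shows up as a local maximum of
g(r_RB, r_RG, r_BG).  A bin is reported as a configuration peak when it is
strictly greater than every valid bin in its full 3D 26-neighborhood and its
amplitude exceeds mean + z·SD of the profile's fluctuation (mean and SD taken
over all valid bins; z = 2.5 by default).  Each peak's distance triple is
reconstructed as a triangle — one chosen edge on the horizontal axis, third
vertex in the upper half-plane — and many peaks (e.g. one per nucleus) can be
filtered on an edge length and overlaid in a common frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .correlation import AllBinsMaskedError, TripleCorrelationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationPeak",
    "find_peaks",
    "triangle_from_distances",
    "overlay_configurations",
    "peaks_to_json",
    "peaks_from_json",
    "GeometryError",
]

_EDGES = ("RB", "RG", "BG")


class GeometryError(ValueError):
    """Distances violate the triangle inequality beyond tolerance."""


@dataclass
class ConfigurationPeak:
    """One significant local maximum of a triple-correlation profile.

    ``r_rb, r_rg, r_bg`` are the bin-center distances (nm) of the peak;
    ``vertices`` maps the three roles to aligned 2D positions whose pairwise
    distances reproduce the distance triple exactly.
    """

    r_rb: float
    r_rg: float
    r_bg: float
    amplitude: float
    z_score: float
    index: tuple[int, int, int]
    vertices: dict[str, tuple[float, float]]
    roles: tuple[str, str, str] = ("R", "B", "G")
    profile_id: str = ""

    def edge_length(self, edge: str) -> float:
        """Length of one edge by name ("RB", "RG" or "BG")."""
        return {"RB": self.r_rb, "RG": self.r_rg, "BG": self.r_bg}[edge.upper()]


def triangle_from_distances(
    r_rb: float,
    r_rg: float,
    r_bg: float,
    align_edge: str = "RG",
    tol: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Vertices R, B, G of the triangle with the given pairwise distances.

    The ``align_edge`` (e.g. "RG") is placed on the horizontal axis with its
    first-named vertex at the origin; the third vertex lands in the upper
    half-plane.  Degenerate (collinear) triples within ``tol`` (relative) of
    the triangle-inequality boundary are accepted with zero height.
    """
    lengths = {"RB": float(r_rb), "RG": float(r_rg), "BG": float(r_bg)}
    if min(lengths.values()) <= 0:
        raise GeometryError(f"edge lengths must be positive, got {lengths}")
    edge = align_edge.upper()
    if edge not in _EDGES:
        raise ValueError(f"align_edge must be one of {_EDGES}")
    p, q = edge[0], edge[1]
    (third,) = set("RBG") - {p, q}

    def dist(u: str, v: str) -> float:
        return lengths["".join(sorted((u, v), key="RBG".index))]

    base = dist(p, q)
    d_p3 = dist(p, third)
    d_q3 = dist(q, third)
    scale = max(lengths.values())
    x = (base**2 + d_p3**2 - d_q3**2) / (2.0 * base)
    h2 = d_p3**2 - x**2
    if h2 < -tol * scale**2:
        raise GeometryError(
            f"distances (r_RB={r_rb}, r_RG={r_rg}, r_BG={r_bg}) violate the "
            "triangle inequality"
        )
    y = float(np.sqrt(max(h2, 0.0)))
    return {
        p: np.array([0.0, 0.0]),
        q: np.array([base, 0.0]),
        third: np.array([x, y]),
    }


def _neighbor_max(filled: np.ndarray) -> np.ndarray:
    """Max over the 26-neighborhood, excluding the center voxel."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    return ndimage.maximum_filter(
        filled, footprint=footprint, mode="constant", cval=-np.inf
    )


def find_peaks(
    profile: TripleCorrelationProfile,
    z_threshold: float = 2.5,
    align_edge: str = "RG",
) -> list[ConfigurationPeak]:
    """Significant local maxima of a triple-correlation profile.

    A peak must (a) exceed every valid bin in its 26-neighborhood (masked
    neighbors are ignored; plateau ties collapse to the lexicographically
    smallest bin) and (b) satisfy g >= mean + z_threshold * SD, with mean and
    SD over all valid bins.  Returns peaks sorted by amplitude descending,
    ties broken by (r_RB, r_RG, r_BG).
    """
    if not profile.mask.any():
        raise AllBinsMaskedError("profile has no valid bins")
    vals = profile.g[profile.mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        logger.info("constant profile (SD = 0): no peaks")
        return []
    threshold = mean + z_threshold * sd

    filled = np.where(profile.mask, profile.g, -np.inf)
    nb_max = _neighbor_max(filled)
    candidates = profile.mask & (filled >= nb_max) & (filled >= threshold)

    peaks: list[ConfigurationPeak] = []
    for idx in np.argwhere(candidates):
        idx = tuple(int(i) for i in idx)
        value = filled[idx]
        if value > nb_max[idx]:
            keep = True
        else:
            # plateau tie: keep only the lexicographically smallest member
            keep = True
            lo = tuple(max(0, i - 1) for i in idx)
            hi = tuple(min(s, i + 2) for i, s in zip(idx, filled.shape))
            for off in np.ndindex(tuple(h - l for l, h in zip(lo, hi))):
                nb = tuple(l + o for l, o in zip(lo, off))
                if nb == idx:
                    continue
                if filled[nb] == value and nb < idx:
                    keep = False
                    break
        if not keep:
            continue
        r_rb, r_rg, r_bg = profile.distances_at(idx)
        vertices = triangle_from_distances(r_rb, r_rg, r_bg, align_edge=align_edge)
        peaks.append(
            ConfigurationPeak(
                r_rb=r_rb,
                r_rg=r_rg,
                r_bg=r_bg,
                amplitude=float(value),
                z_score=float((value - mean) / sd),
                index=idx,
                vertices={k: (float(v[0]), float(v[1])) for k, v in vertices.items()},
                roles=profile.roles,
                profile_id=profile.profile_id,
            )
        )
    peaks.sort(key=lambda p: (-p.amplitude, p.r_rb, p.r_rg, p.r_bg))
    return peaks


def peak_at_distances(
    profile: TripleCorrelationProfile,
    r_rb: float,
    r_rg: float,
    r_bg: float,
    align_edge: str = "RG",
) -> ConfigurationPeak:
    """Read the profile at a hypothesized configuration, as a peak object.

    Unlike :func:`find_peaks`, the bin is chosen by the caller (e.g. a known
    complex geometry), so the returned amplitude is free of the selection
    bias a data-driven maximum carries.  The bin containing the distance
    triple must be valid.
    """
    idx = (
        int(profile.bins.r_bin(np.array([r_rb]))[0]),
        int(profile.bins.r_bin(np.array([r_rg]))[0]),
        int(profile.bins.r3_bin(np.array([r_bg]))[0]),
    )
    shape = profile.g.shape
    if not all(0 <= i < s for i, s in zip(idx, shape)):
        raise ValueError(f"distances ({r_rb}, {r_rg}, {r_bg}) fall outside the grid")
    if not profile.mask[idx]:
        raise ValueError(f"bin {idx} holding ({r_rb}, {r_rg}, {r_bg}) is masked")
    vals = profile.g[profile.mask]
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    c_rb, c_rg, c_bg = profile.distances_at(idx)
    vertices = triangle_from_distances(c_rb, c_rg, c_bg, align_edge=align_edge)
    return ConfigurationPeak(
        r_rb=c_rb,
        r_rg=c_rg,
        r_bg=c_bg,
        amplitude=float(profile.g[idx]),
        z_score=float((profile.g[idx] - mean) / sd) if sd > 0 else 0.0,
        index=idx,
        vertices={k: (float(v[0]), float(v[1])) for k, v in vertices.items()},
        roles=profile.roles,
        profile_id=profile.profile_id,
    )


def overlay_configurations(
    peaks: Sequence[ConfigurationPeak],
    edge_filter: Optional[tuple[str, float]] = None,
    align_edge: str = "RG",
    marker: Union[str, Mapping[int, float]] = "amplitude",
) -> pd.DataFrame:
    """Overlay many configuration peaks in one aligned frame.

    Peaks failing ``edge_filter`` — e.g. ``("BG", 100.0)`` keeps peaks with
    the BG edge at most 100 nm — are dropped (count logged).  Survivors are
    re-aligned on ``align_edge`` and emitted one row per vertex with a marker
    value (peak amplitude by default, or a per-peak mapping such as a local
    density).

    Returns a DataFrame with columns
    ``peak_id, profile_id, role, x_nm, y_nm, marker``.
    """
    if not peaks:
        raise ValueError("no peaks to overlay")
    kept: list[tuple[int, ConfigurationPeak]] = []
    for i, p in enumerate(peaks):
        if edge_filter is not None:
            edge, max_nm = edge_filter
            if p.edge_length(edge) > max_nm:
                continue
        kept.append((i, p))
    n_dropped = len(peaks) - len(kept)
    if n_dropped:
        logger.info("edge filter %s dropped %d of %d peaks", edge_filter, n_dropped, len(peaks))

    rows = []
    for i, p in kept:
        verts = triangle_from_distances(p.r_rb, p.r_rg, p.r_bg, align_edge=align_edge)
        if isinstance(marker, str):
            mval = getattr(p, marker)
        else:
            mval = marker[i]
        for role in "RBG":
            rows.append(
                {
                    "peak_id": i,
                    "profile_id": p.profile_id,
                    "role": role,
                    "x_nm": float(verts[role][0]),
                    "y_nm": float(verts[role][1]),
                    "marker": float(mval),
                }
            )
    return pd.DataFrame(rows, columns=["peak_id", "profile_id", "role", "x_nm", "y_nm", "marker"])


# ---------------------------------------------------------------------------
# JSON serialization


def peaks_to_json(peaks: Sequence[ConfigurationPeak]) -> str:
    return json.dumps(
        [
            {
                "r_rb_nm": p.r_rb,
                "r_rg_nm": p.r_rg,
                "r_bg_nm": p.r_bg,
                "amplitude": p.amplitude,
                "z_score": p.z_score,
                "index": list(p.index),
                "vertices": {k: list(v) for k, v in p.vertices.items()},
                "roles": list(p.roles),
                "profile_id": p.profile_id,
            }
            for p in peaks
        ],
        indent=2,
    )


def peaks_from_json(text: str) -> list[ConfigurationPeak]:
    return [
        ConfigurationPeak(
            r_rb=d["r_rb_nm"],
            r_rg=d["r_rg_nm"],
            r_bg=d["r_bg_nm"],
            amplitude=d["amplitude"],
            z_score=d["z_score"],
            index=tuple(d["index"]),
            vertices={k: tuple(v) for k, v in d["vertices"].items()},
            roles=tuple(d.get("roles", ("R", "B", "G"))),
            profile_id=d.get("profile_id", ""),
        )
        for d in json.loads(text)
    ]
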