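"""Synthetic multi-channel SMLM data with planted molecular configurations.

The generative model: a molecular *pattern* is a small rigid arrangement of
"molecules", one (or none) per color channel — e.g. a three-species triangle,
or a two-species pair.  Each pattern instance is translated to a uniformly
random centroid position on the canvas and rotated by a uniform angle in
[0, 2π); instances whose molecules would fall outside the canvas are redrawn
(rejection sampling), so planted geometry is never clipped at edges.  Every
molecule then emits a number of localizations (Poisson by default, fixed on
request), each scattered by an isotropic 2D Gaussian of standard deviation σ —
the localization precision.  Optionally, each channel receives an independent
homogeneous Poisson background (complete spatial randomness, CSR).

Randomness is split into named sub-streams (placement / localization counts /
jitter / per-channel background) derived from one seed, so e.g. adding
background does not perturb where patterns land.  Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Canvas, LocalizationSet

__all__ = ["PatternSpec", "SimulationSpec", "simulate", "csr", "SimulationSizeError"]

# sub-stream tags for SeedSequence spawn keys
_STREAM_PLACEMENT = 0
_STREAM_COUNTS = 1
_STREAM_JITTER = 2
_STREAM_BACKGROUND = 3

_MAX_EXPECTED_POINTS = 5_000_000  # safety cap on total expected localizations


class SimulationSizeError(ValueError):
    """The spec asks for more points than the configured safety cap."""


@dataclass(frozen=True)
class PatternSpec:
    """One rigid molecular pattern: a mapping channel label -> offset (nm).

    Offsets are relative to an arbitrary reference; placement recenters them
    on the pattern centroid.  Three-molecule patterns must satisfy the
    triangle inequality unless ``allow_degenerate`` is set (collinear
    patterns are then accepted).
    """

    label: str
    molecules: tuple[tuple[str, float, float], ...]
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.molecules) < 1:
            raise ValueError(f"pattern {self.label!r} has no molecules")
        labels = [ch for ch, _, _ in self.molecules]
        if len(set(labels)) != len(labels):
            raise ValueError(f"pattern {self.label!r}: duplicate channel labels")
        offs = self.offsets()
        if len(offs) == 3 and not self.allow_degenerate:
            d = [
                float(np.hypot(*(offs[i] - offs[j])))
                for i, j in ((0, 1), (0, 2), (1, 2))
            ]
            if min(d) <= 0:
                raise ValueError(f"pattern {self.label!r}: coincident molecules")
            d.sort()
            if d[0] + d[1] <= d[2] * (1 + 1e-12):
                raise ValueError(
                    f"pattern {self.label!r}: degenerate (collinear) geometry; "
                    "pass allow_degenerate=True to accept"
                )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(ch for ch, _, _ in self.molecules)

    def offsets(self) -> np.ndarray:
        return np.array([[x, y] for _, x, y in self.molecules], dtype=float)

    @staticmethod
    def triangle(
        label: str,
        r_rb: float,
        r_rg: float,
        r_bg: float,
        channels: Sequence[str] = ("R", "B", "G"),
        allow_degenerate: bool = False,
    ) -> "PatternSpec":
        """Build a three-species pattern from its three pairwise distances.

        ``r_rb``, ``r_rg``, ``r_bg`` are the distances between the molecules
        on channels[0]&[1], [0]&[2] and [1]&[2] respectively.
        """
        r, b, g = channels
        # place R at origin, G on the x axis, B above it
        x_b = (r_rg**2 + r_rb**2 - r_bg**2) / (2 * r_rg)
        h2 = r_rb**2 - x_b**2
        if h2 < -1e-9 * max(r_rb, r_rg, r_bg) ** 2:
            raise ValueError(f"({r_rb}, {r_rg}, {r_bg}) violates the triangle inequality")
        y_b = float(np.sqrt(max(h2, 0.0)))
        return PatternSpec(
            label=label,
            molecules=((r, 0.0, 0.0), (b, x_b, y_b), (g, r_rg, 0.0)),
            allow_degenerate=allow_degenerate,
        )


@dataclass
class SimulationSpec:
    """Full description of one synthetic acquisition.

    Attributes
    ----------
    canvas : observation window (nm).
    patterns : list of (PatternSpec, instance count).
    sigma : localization precision σ in nm (isotropic Gaussian sd).
    locs_per_molecule : mean number of localizations each molecule emits.
    fixed_locs : if True, every molecule emits exactly
        ``int(locs_per_molecule)`` localizations instead of Poisson counts.
    background : per-channel CSR background density in points/µm².
    seed : integer RNG seed; same spec + seed is bit-reproducible.
    """

    canvas: Canvas
    patterns: list[tuple[PatternSpec, int]] = field(default_factory=list)
    sigma: float = 0.0
    locs_per_molecule: float = 1.0
    fixed_locs: bool = False
    background: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma = float(self.sigma)
        self.locs_per_molecule = float(self.locs_per_molecule)
        self.background = {k: float(v) for k, v in self.background.items()}
        self.seed = int(self.seed)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(cnt < 0 for _, cnt in self.patterns):
            raise ValueError("pattern counts must be >= 0")
        if any(rho < 0 for rho in self.background.values()):
            raise ValueError("background densities must be >= 0")

    @property
    def channels(self) -> tuple[str, ...]:
        labels: set[str] = set(self.background)
        for pat, _ in self.patterns:
            labels.update(pat.channels)
        return tuple(sorted(labels))

    def expected_points(self) -> float:
        n_pat = sum(len(pat.molecules) * cnt for pat, cnt in self.patterns)
        area_um2 = self.canvas.area() / 1e6
        n_bg = sum(self.background.values()) * area_um2
        return n_pat * self.locs_per_molecule + n_bg

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "canvas": {
                "x_min": self.canvas.x_min,
                "x_max": self.canvas.x_max,
                "y_min": self.canvas.y_min,
                "y_max": self.canvas.y_max,
            },
            "patterns": [
                {
                    "label": pat.label,
                    "molecules": [
                        {"channel": ch, "x_nm": x, "y_nm": y} for ch, x, y in pat.molecules
                    ],
                    "allow_degenerate": pat.allow_degenerate,
                    "count": cnt,
                }
                for pat, cnt in self.patterns
            ],
            "sigma_nm": self.sigma,
            "locs_per_molecule": self.locs_per_molecule,
            "fixed_locs": self.fixed_locs,
            "background_per_um2": dict(self.background),
            "seed": self.seed,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "SimulationSpec":
        doc = yaml.safe_load(text)
        cv = doc["canvas"]
        patterns = [
            (
                PatternSpec(
                    label=p["label"],
                    molecules=tuple(
                        (m["channel"], float(m["x_nm"]), float(m["y_nm"]))
                        for m in p["molecules"]
                    ),
                    allow_degenerate=bool(p.get("allow_degenerate", False)),
                ),
                int(p["count"]),
            )
            for p in doc.get("patterns", [])
        ]
        return SimulationSpec(
            canvas=Canvas(cv["x_min"], cv["x_max"], cv["y_min"], cv["y_max"]),
            patterns=patterns,
            sigma=float(doc.get("sigma_nm", 0.0)),
            locs_per_molecule=float(doc.get("locs_per_molecule", 1.0)),
            fixed_locs=bool(doc.get("fixed_locs", False)),
            background={str(k): float(v) for k, v in doc.get("background_per_um2", {}).items()},
            seed=int(doc.get("seed", 0)),
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _place_patterns(spec: SimulationSpec) -> pd.DataFrame:
    """Random rigid placement of every pattern instance; returns the manifest."""
    rng = _rng(spec.seed, _STREAM_PLACEMENT)
    cv = spec.canvas
    rows = []
    pattern_id = 0
    for pat, count in spec.patterns:
        offs = pat.offsets()
        offs = offs - offs.mean(axis=0)  # centroid at the placement point
        channels = pat.channels
        placed = 0
        while placed < count:
            m = count - placed
            cx = rng.uniform(cv.x_min, cv.x_max, size=m)
            cy = rng.uniform(cv.y_min, cv.y_max, size=m)
            ang = rng.uniform(0.0, 2.0 * np.pi, size=m)
            ca, sa = np.cos(ang), np.sin(ang)
            # rotated offsets: (m, n_mol, 2)
            rx = offs[None, :, 0] * ca[:, None] - offs[None, :, 1] * sa[:, None]
            ry = offs[None, :, 0] * sa[:, None] + offs[None, :, 1] * ca[:, None]
            mx = cx[:, None] + rx
            my = cy[:, None] + ry
            ok = (
                (mx >= cv.x_min) & (mx <= cv.x_max) & (my >= cv.y_min) & (my <= cv.y_max)
            ).all(axis=1)
            for i in np.flatnonzero(ok):
                for j, ch in enumerate(channels):
                    rows.append(
                        (pattern_id, pat.label, ch, float(mx[i, j]), float(my[i, j]))
                    )
                pattern_id += 1
                placed += 1
    return pd.DataFrame(
        rows, columns=["pattern_id", "pattern_label", "channel", "true_x_nm", "true_y_nm"]
    )


def simulate(spec: SimulationSpec) -> tuple[dict[str, LocalizationSet], pd.DataFrame]:
    """Generate localization sets per channel plus the ground-truth manifest.

    Returns
    -------
    sets : dict channel label -> :class:`LocalizationSet` containing
        pattern-derived localizations followed by background points.
    manifest : DataFrame with columns
        ``pattern_id, pattern_label, channel, true_x_nm, true_y_nm`` — the
        true molecule positions of every placed pattern instance.
    """
    if spec.expected_points() > _MAX_EXPECTED_POINTS:
        raise SimulationSizeError(
            f"spec requests ~{spec.expected_points():.0f} expected localizations "
            f"(cap {_MAX_EXPECTED_POINTS}); shrink the canvas, counts or densities"
        )
    manifest = _place_patterns(spec)

    counts_rng = _rng(spec.seed, _STREAM_COUNTS)
    jitter_rng = _rng(spec.seed, _STREAM_JITTER)
    cv = spec.canvas
    area_um2 = cv.area() / 1e6

    n_mol = len(manifest)
    if n_mol:
        if spec.fixed_locs:
            n_locs = np.full(n_mol, int(round(spec.locs_per_molecule)), dtype=np.int64)
        else:
            n_locs = counts_rng.poisson(spec.locs_per_molecule, size=n_mol)
        mol_xy = manifest[["true_x_nm", "true_y_nm"]].to_numpy()
        centers = np.repeat(mol_xy, n_locs, axis=0)
        if spec.sigma > 0:
            locs = centers + jitter_rng.normal(0.0, spec.sigma, size=centers.shape)
        else:
            locs = centers.copy()
        loc_channel = np.repeat(manifest["channel"].to_numpy(), n_locs)
        # jitter can scatter a localization of a near-edge molecule off the
        # canvas; such points are unobservable and dropped
        inside = cv.contains(locs)
        locs = locs[inside]
        loc_channel = loc_channel[inside]
    else:
        locs = np.zeros((0, 2))
        loc_channel = np.zeros(0, dtype=object)

    sets: dict[str, LocalizationSet] = {}
    for ci, ch in enumerate(spec.channels):
        parts = [locs[loc_channel == ch]]
        rho = spec.background.get(ch, 0.0)
        if rho > 0:
            bg_rng = _rng(spec.seed, _STREAM_BACKGROUND, ci)
            n_bg = bg_rng.poisson(rho * area_um2)
            bx = bg_rng.uniform(cv.x_min, cv.x_max, size=n_bg)
            by = bg_rng.uniform(cv.y_min, cv.y_max, size=n_bg)
            parts.append(np.column_stack([bx, by]))
        xy = np.vstack(parts) if parts else np.zeros((0, 2))
        sigma = np.full(len(xy), spec.sigma) if spec.sigma > 0 else None
        sets[ch] = LocalizationSet(channel=ch, xy=xy, canvas=cv, sigma=sigma)
    return sets, manifest


def csr(spec: SimulationSpec) -> dict[str, LocalizationSet]:
    """Homogeneous Poisson (CSR) channels — the null model for normalization.

    The spec must contain no patterns and at least one channel with positive
    background density; channels are generated independently.
    """
    if spec.patterns:
        raise ValueError("csr() requires a spec without patterns")
    if not any(rho > 0 for rho in spec.background.values()):
        raise ValueError("csr() requires a positive background density")
    sets, _ = simulate(spec)
    return sets
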