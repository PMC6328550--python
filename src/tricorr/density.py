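"""Conditional probability and local density of a third species at a complex.

Given a significant three-species configuration (a triple-correlation peak
with amplitude g_TC^max) whose conditioning pair — say species B and G at
distance d — has pair correlation g_PC(d), the posterior probability of
finding the third species R associated with a given B–G complex is

    P(R | BG) = g_TC^max / g_PC(d),

and the local density of R at each such complex is the overall average
density of R scaled by that probability,

    rho(R | BG) = rho_R * P(R | BG).

Under third-channel independence (CSR R), the triple correlation carries no
information beyond the pair term and P -> 1, rho(R|BG) -> rho_R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import PairCorrelationProfile
from .peaks import ConfigurationPeak

__all__ = [
    "ConditionalDensityResult",
    "conditional_density",
    "per_profile_density_summary",
]


class UndefinedConditionalError(ValueError):
    """g_PC at the conditioning distance is zero or masked."""


@dataclass
class ConditionalDensityResult:
    """Conditional probability / local density at one configuration peak."""

    peak: ConfigurationPeak
    conditioning_edge: str  # "RB", "RG" or "BG"
    d_nm: float  # conditioning-pair distance read from the peak
    g_pc_at_d: float
    p_conditional: float  # P(third | pair)
    rho_third_per_um2: float  # overall average density of the third species
    rho_conditional_per_um2: float  # local density at the complex

    def to_dict(self) -> dict:
        return {
            "profile_id": self.peak.profile_id,
            "conditioning_edge": self.conditioning_edge,
            "d_nm": self.d_nm,
            "g_tc_max": self.peak.amplitude,
            "g_pc_at_d": self.g_pc_at_d,
            "p_conditional": self.p_conditional,
            "rho_third_per_um2": self.rho_third_per_um2,
            "rho_conditional_per_um2": self.rho_conditional_per_um2,
        }


def _edge_for_pair(peak: ConfigurationPeak, pair: tuple[str, str]) -> str:
    """Which triangle edge corresponds to a channel pair, via the peak roles."""
    role_of = {label: role for role, label in zip("RBG", peak.roles)}
    try:
        roles = {role_of[pair[0]], role_of[pair[1]]}
    except KeyError as exc:
        raise ValueError(
            f"pair channel {exc} is not among the peak's roles {peak.roles}"
        ) from None
    for edge in ("RB", "RG", "BG"):
        if set(edge) == roles:
            return edge
    raise ValueError(f"pair {pair} does not form an edge")


def conditional_density(
    peak: ConfigurationPeak,
    pc_profile: PairCorrelationProfile,
    rho_third_per_um2: float,
    interpolate: bool = False,
) -> ConditionalDensityResult:
    """P(third | pair) and the local third-species density at one peak.

    Parameters
    ----------
    peak : configuration peak supplying g_TC^max and the conditioning-edge
        distance d (the peak's edge between the two channels of
        ``pc_profile``).
    pc_profile : cross-pair correlation of the two conditioning channels.
    rho_third_per_um2 : overall average density of the third species
        (N / canvas area), in points/µm².
    interpolate : evaluate g_PC(d) by linear interpolation between bin
        centers instead of the containing bin.
    """
    if rho_third_per_um2 < 0:
        raise ValueError("rho_third_per_um2 must be >= 0")
    edge = _edge_for_pair(peak, pc_profile.channels)
    d = peak.edge_length(edge)
    try:
        g_pc = pc_profile.g_at(d, interpolate=interpolate)
    except ValueError as exc:
        raise UndefinedConditionalError(str(exc)) from None
    if not np.isfinite(g_pc) or g_pc <= 0:
        raise UndefinedConditionalError(
            f"g_PC({d:.1f} nm) = {g_pc}; conditional probability undefined"
        )
    p = peak.amplitude / g_pc
    return ConditionalDensityResult(
        peak=peak,
        conditioning_edge=edge,
        d_nm=d,
        g_pc_at_d=g_pc,
        p_conditional=p,
        rho_third_per_um2=rho_third_per_um2,
        rho_conditional_per_um2=rho_third_per_um2 * p,
    )


def per_profile_density_summary(
    groups: Mapping[str, Sequence[ConditionalDensityResult]],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-profile mean local densities, plus a two-group comparison.

    Results within each group are averaged per profile id (one value per
    profile — e.g. per nucleus).  When exactly two groups are given, the
    unpaired two-sample t-test p-value between their per-profile means is
    returned as well (otherwise None).
    """
    if not groups:
        raise ValueError("no groups given")
    rows = []
    for name, results in groups.items():
        if not results:
            raise ValueError(f"group {name!r} is empty")
        per_profile: dict[str, list[float]] = {}
        for r in results:
            per_profile.setdefault(r.peak.profile_id, []).append(
                r.rho_conditional_per_um2
            )
        for pid, vals in per_profile.items():
            rows.append(
                {
                    "group": name,
                    "profile_id": pid,
                    "mean_rho_conditional_per_um2": float(np.mean(vals)),
                    "n_peaks": len(vals),
                }
            )
    table = pd.DataFrame(rows)
    p_value: Optional[float] = None
    names = list(groups)
    if len(names) == 2:
        a = table.loc[table["group"] == names[0], "mean_rho_conditional_per_um2"]
        b = table.loc[table["group"] == names[1], "mean_rho_conditional_per_um2"]
        if len(a) > 1 and len(b) > 1:
            p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return table, p_value
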