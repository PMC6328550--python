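"""Peak detection, triangle reconstruction and configuration overlay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricorr.correlation import RadialBins, TripleCorrelationProfile
from tricorr.peaks import (
    ConfigurationPeak,
    GeometryError,
    find_peaks,
    overlay_configurations,
    peak_at_distances,
    peaks_from_json,
    peaks_to_json,
    triangle_from_distances,
)


def synthetic_profile(g, mask=None, bins=None):
    """Wrap a hand-built grid into a profile object (synthetic stand-in)."""
    bins = bins or RadialBins(dr=10.0, r_max=100.0, n_theta=18)
    if mask is None:
        mask = np.isfinite(g)
    g = np.where(mask, g, np.nan)
    return TripleCorrelationProfile(
        roles=("R", "B", "G"),
        bins=bins,
        g=g,
        mask=mask,
        sum_w=np.nan_to_num(g),
        csr_expected=np.ones_like(g),
        csr_var=np.ones_like(g),
        n_contrib=mask.astype(int),
        n_r_pts=1,
        n_b_pts=1,
        n_g_pts=1,
        n_origins_used=1,
        area=1.0,
        profile_id="synthetic",
    )


def feasible_mask(bins):
    r1 = bins.r_centers[:, None, None]
    r2 = bins.r_centers[None, :, None]
    r3 = bins.r3_centers[None, None, :]
    return (np.abs(r1 - r2) <= r3) & (r3 <= r1 + r2)


class TestFindPeaks:
    def test_constant_profile_has_no_peaks(self):
        bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
        g = np.ones((10, 10, 20))
        prof = synthetic_profile(g, mask=feasible_mask(bins), bins=bins)
        assert find_peaks(prof) == []

    def test_single_spike_recovered_exactly(self, rng):
        bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
        mask = feasible_mask(bins)
        # bounded (uniform) fluctuation: no background bin can reach the
        # mean + 2.5 SD threshold, only the planted spike
        g = np.where(mask, 1.0 + rng.uniform(0.0, 0.01, mask.shape), np.nan)
        vals = g[mask]
        spike = (5, 6, 9)
        assert mask[spike]
        g[spike] = vals.mean() + 10 * vals.std()
        prof = synthetic_profile(g, mask=mask, bins=bins)
        peaks = find_peaks(prof)
        assert len(peaks) == 1
        assert peaks[0].index == spike
        assert peaks[0].z_score >= 2.5
        assert peaks[0].amplitude == pytest.approx(g[spike])

    def test_every_peak_satisfies_both_conditions(self, rng):
        bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
        mask = feasible_mask(bins)
        g = np.where(mask, rng.exponential(1.0, mask.shape), np.nan)
        prof = synthetic_profile(g, mask=mask, bins=bins)
        vals = g[mask]
        thr = vals.mean() + 2.5 * vals.std()
        for p in find_peaks(prof):
            assert p.amplitude >= thr
            i, j, k = p.index
            nb = g[max(0, i - 1): i + 2, max(0, j - 1): j + 2, max(0, k - 1): k + 2]
            assert p.amplitude == np.nanmax(nb)

    def test_raising_threshold_never_adds_peaks(self, rng):
        bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
        mask = feasible_mask(bins)
        g = np.where(mask, rng.exponential(1.0, mask.shape), np.nan)
        prof = synthetic_profile(g, mask=mask, bins=bins)
        counts = [len(find_peaks(prof, z_threshold=z)) for z in (0.5, 1.5, 2.5, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_reported_once_at_smallest_index(self):
        bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
        mask = feasible_mask(bins)
        g = np.where(mask, 1.0, np.nan)
        # two adjacent equal-valued bins well above the rest
        g[4, 4, 4] = g[4, 4, 5] = 50.0
        # break SD=0 elsewhere
        g[0, 0, 0] = 1.5
        prof = synthetic_profile(g, mask=mask, bins=bins)
        peaks = find_peaks(prof)
        assert [p.index for p in peaks] == [(4, 4, 4)]


class TestTriangleFromDistances:
    def test_equilateral_closed_form(self):
        v = triangle_from_distances(100.0, 100.0, 100.0, align_edge="RG")
        np.testing.assert_allclose(v["R"], [0.0, 0.0])
        np.testing.assert_allclose(v["G"], [100.0, 0.0])
        np.testing.assert_allclose(v["B"], [50.0, 86.60254037844386], atol=1e-9)

    def test_degenerate_collinear_accepted(self):
        v = triangle_from_distances(100.0, 50.0, 50.0, align_edge="RG")
        assert v["B"][1] == 0.0  # zero height
        assert np.hypot(*(v["B"] - v["R"])) == pytest.approx(100.0)

    def test_right_triangle_from_circle_intersection(self):
        v = triangle_from_distances(3.0, 4.0, 5.0, align_edge="BG")
        # verify by recomputing all three distances
        assert np.hypot(*(v["R"] - v["B"])) == pytest.approx(3.0)
        assert np.hypot(*(v["R"] - v["G"])) == pytest.approx(4.0)
        assert np.hypot(*(v["B"] - v["G"])) == pytest.approx(5.0)
        assert v["R"][1] >= 0  # upper half-plane

    def test_violation_rejected(self):
        with pytest.raises(GeometryError):
            triangle_from_distances(10.0, 10.0, 100.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        r1=st.floats(1.0, 500.0),
        r2=st.floats(1.0, 500.0),
        t=st.floats(0.02, 0.98),
    )
    def test_roundtrip_distances_preserved(self, r1, r2, t):
        # r3 sampled strictly inside the triangle-inequality interval
        lo, hi = abs(r1 - r2), r1 + r2
        r3 = lo + t * (hi - lo)
        if r3 <= 0:
            return
        for edge in ("RB", "RG", "BG"):
            v = triangle_from_distances(r1, r2, r3, align_edge=edge)
            assert np.hypot(*(v["R"] - v["B"])) == pytest.approx(r1, abs=1e-9, rel=1e-9)
            assert np.hypot(*(v["R"] - v["G"])) == pytest.approx(r2, abs=1e-9, rel=1e-9)
            assert np.hypot(*(v["B"] - v["G"])) == pytest.approx(r3, abs=1e-9, rel=1e-9)
            first = v[edge[0]]
            np.testing.assert_allclose(first, [0.0, 0.0], atol=1e-12)


def make_peak(r_rb, r_rg, r_bg, amplitude=5.0, pid="p"):
    v = triangle_from_distances(r_rb, r_rg, r_bg)
    return ConfigurationPeak(
        r_rb=r_rb, r_rg=r_rg, r_bg=r_bg, amplitude=amplitude, z_score=3.0,
        index=(0, 0, 0), vertices={k: tuple(p) for k, p in v.items()},
        profile_id=pid,
    )


class TestOverlay:
    def test_edge_filter_semantics(self):
        peaks = [make_peak(100, 100, 80.0, pid="a"), make_peak(100, 100, 120.0, pid="b")]
        table = overlay_configurations(peaks, edge_filter=("BG", 100.0))
        assert table.profile_id.unique().tolist() == ["a"]
        assert len(table) == 3  # one row per vertex

    def test_single_peak_overlay_equals_triangle(self):
        pk = make_peak(60.0, 100.0, 80.0)
        table = overlay_configurations([pk], align_edge="BG")
        v = triangle_from_distances(60.0, 100.0, 80.0, align_edge="BG")
        for role in "RBG":
            row = table[table.role == role].iloc[0]
            np.testing.assert_allclose([row.x_nm, row.y_nm], v[role], atol=1e-12)

    def test_marker_defaults_to_amplitude(self):
        pk = make_peak(50, 50, 50, amplitude=7.5)
        table = overlay_configurations([pk])
        assert (table.marker == 7.5).all()

    def test_scattered_peaks_from_one_geometry_cluster_within_bin_width(self, rng):
        # synthetic per-profile peaks jittered by less than one 10 nm bin
        peaks = [
            make_peak(100 + rng.uniform(-5, 5), 100 + rng.uniform(-5, 5), 80 + rng.uniform(-5, 5))
            for _ in range(100)
        ]
        table = overlay_configurations(peaks, align_edge="BG")
        b_rows = table[table.role == "R"]
        assert b_rows.x_nm.std() <= 10.0 and b_rows.y_nm.std() <= 10.0

    def test_json_round_trip(self):
        peaks = [make_peak(100, 100, 80.0), make_peak(60, 100, 80.0)]
        again = peaks_from_json(peaks_to_json(peaks))
        assert [p.r_bg for p in again] == [80.0, 80.0]
        assert again[0].vertices.keys() == peaks[0].vertices.keys()


def test_peak_at_distances_reads_requested_bin(rng):
    bins = RadialBins(dr=10.0, r_max=100.0, n_theta=18)
    mask = feasible_mask(bins)
    g = np.where(mask, 1.0 + 0.1 * rng.standard_normal(mask.shape), np.nan)
    prof = synthetic_profile(g, mask=mask, bins=bins)
    pk = peak_at_distances(prof, 72.0, 68.0, 75.0)
    assert pk.index == (7, 6, 7)
    assert pk.amplitude == pytest.approx(g[7, 6, 7])
    assert (pk.r_rb, pk.r_rg, pk.r_bg) == (75.0, 65.0, 75.0)  # bin centers
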