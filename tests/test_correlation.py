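"""Correlation estimators: edge geometry, CSR calibration, oracles, symmetry."""

import numpy as np
import pytest

from tricorr import presets
from tricorr.correlation import (
    EmptyProfileError,
    RadialBins,
    compute_pair_correlation,
    compute_triple_correlation,
    edge_arc_fraction,
    edge_arc_fractions,
    fraction_within_csr_noise,
    pool_triple_profiles,
    tc_bruteforce,
    tc_fourier_reference,
)
from tricorr.io import Canvas, LocalizationSet
from tricorr.simulate import csr, simulate

from conftest import make_set


# ---------------------------------------------------------------------------
# edge-correction geometry


class TestEdgeArcFraction:
    def test_interior_circle_fully_inside(self, canvas):
        assert edge_arc_fraction((500, 500), 499.0, canvas) == pytest.approx(1.0)

    def test_corner_quarter_circle(self, canvas):
        assert edge_arc_fraction((0, 0), 100.0, canvas) == pytest.approx(0.25)
        assert edge_arc_fraction((1000, 1000), 50.0, canvas) == pytest.approx(0.25)

    def test_edge_midpoint_half_circle(self, canvas):
        assert edge_arc_fraction((500, 0), 100.0, canvas) == pytest.approx(0.5)
        assert edge_arc_fraction((0, 500), 100.0, canvas) == pytest.approx(0.5)

    def test_origin_outside_rejected(self, canvas):
        with pytest.raises(ValueError):
            edge_arc_fraction((-1, 50), 10.0, canvas)

    def test_matches_monte_carlo_sampling(self, canvas, rng):
        # random origins and radii, including corner-overlap regimes
        origins = rng.uniform(0, 1000, size=(30, 2))
        radii = np.array([30.0, 120.0, 450.0])
        frac = edge_arc_fractions(origins, radii, canvas)
        theta = np.linspace(0, 2 * np.pi, 20_000, endpoint=False)
        for i, o in enumerate(origins):
            for j, r in enumerate(radii):
                pts = o + r * np.column_stack([np.cos(theta), np.sin(theta)])
                mc = canvas.contains(pts).mean()
                assert frac[i, j] == pytest.approx(mc, abs=3e-4)


# ---------------------------------------------------------------------------
# pair correlation


class TestPairCorrelation:
    def test_single_pair_lands_in_its_distance_bin(self):
        cv = Canvas(0, 2000, 0, 2000)
        a = make_set("A", [[1000.0, 1000.0]], cv)
        b = make_set("B", [[1100.0, 1000.0]], cv)
        prof = compute_pair_correlation(a, b)
        nz = np.flatnonzero(prof.sum_w)
        assert list(nz) == [9]  # bin (90, 100] holds the 100 nm pair
        assert prof.g[9] > 0

    def test_shifted_copy_peaks_at_shift_distance(self, rng):
        cv = Canvas(0, 5000, 0, 5000)
        xy = rng.uniform(100, 4900, size=(400, 2))
        a = make_set("A", xy, cv)
        b = make_set("B", xy + [50.0, 0.0], cv)
        prof = compute_pair_correlation(a, b)
        assert int(np.nanargmax(prof.g)) == 4  # bin (40, 50] contains 50 nm

    def test_csr_null_within_monte_carlo_error(self):
        sets = csr(presets.csr_spec(31, density_per_um2=100, canvas_nm=10_000))
        prof = compute_pair_correlation(sets["B"], sets["G"])
        assert fraction_within_csr_noise(prof) >= 0.99
        assert np.nanmean(prof.g) == pytest.approx(1.0, abs=0.05)

    def test_auto_mode_excludes_self_pairs(self):
        cv = Canvas(0, 2000, 0, 2000)
        a = make_set("A", [[1000.0, 1000.0], [1050.0, 1000.0]], cv)
        prof = compute_pair_correlation(a, a)
        assert prof.auto
        assert prof.sum_w.sum() == pytest.approx(2.0)  # the two cross pairs only

    def test_empty_channel_rejected(self, canvas):
        empty = make_set("A", np.zeros((0, 2)), canvas)
        full = make_set("B", [[10.0, 10.0]], canvas)
        with pytest.raises(EmptyProfileError):
            compute_pair_correlation(empty, full)


# ---------------------------------------------------------------------------
# triple correlation


def small_csr_sets(seed=11, density=4.0, canvas_nm=5000.0):
    return csr(presets.csr_spec(seed, density_per_um2=density, canvas_nm=canvas_nm))


class TestTripleCorrelation:
    def test_brute_force_oracle_equivalence(self):
        sets = small_csr_sets()
        fast = compute_triple_correlation(sets["R"], sets["B"], sets["G"], min_expected=0)
        brute = tc_bruteforce(sets["R"], sets["B"], sets["G"], min_expected=0)
        np.testing.assert_array_equal(fast.mask, brute.mask)
        assert np.nanmax(np.abs(fast.g[fast.mask] - brute.g[brute.mask])) <= 1e-9
        np.testing.assert_allclose(fast.sum_w, brute.sum_w, atol=1e-9)

    def test_single_triple_weight_matches_hand_formula(self):
        cv = Canvas(0, 4000, 0, 4000)
        bins = RadialBins(dr=10.0, r_max=300.0, n_theta=72)
        o = np.array([2000.0, 2000.0])
        r1, r2, dth = 95.0, 195.0, np.deg2rad(41.0)  # off any bin edge
        set_r = make_set("R", [o], cv)
        set_b = make_set("B", [o + [r1, 0.0]], cv)
        set_g = make_set("G", [o + r2 * np.array([np.cos(dth), np.sin(dth)])], cv)
        prof = compute_triple_correlation(set_r, set_b, set_g, bins, min_expected=0)
        assert prof.sum_w.sum() == pytest.approx(1.0)  # interior origin, weight 1
        idx = np.argwhere(prof.sum_w > 0)
        assert len(idx) == 1
        i, j, k = idx[0]
        assert (i, j) == (9, 19)  # bins holding 95 and 195
        # expected r3 from the law of cosines at bin centers
        theta_c = prof.bins.theta_centers[int(dth / prof.bins.dtheta)]
        r3 = np.sqrt(95.0**2 + 195.0**2 - 2 * 95.0 * 195.0 * np.cos(theta_c))
        assert prof.bins.r3_edges[k] < r3 <= prof.bins.r3_edges[k + 1]
        # normalization: g = sum_w / csr_expected at that bin
        assert prof.g[i, j, k] == pytest.approx(
            prof.sum_w[i, j, k] / prof.csr_expected[i, j, k]
        )

    def test_csr_null_mean_and_noise(self):
        sets = csr(presets.csr_spec(5, density_per_um2=100, canvas_nm=10_000))
        prof = compute_triple_correlation(sets["R"], sets["B"], sets["G"], edge="guard")
        assert np.nanmean(prof.g[prof.mask]) == pytest.approx(1.0, abs=0.02)
        assert fraction_within_csr_noise(prof) >= 0.985

    def test_channel_swap_transposes_satellite_axes(self):
        sets = small_csr_sets(seed=17, density=8.0)
        ab = compute_triple_correlation(sets["R"], sets["B"], sets["G"], min_expected=0)
        ba = compute_triple_correlation(sets["R"], sets["G"], sets["B"], min_expected=0)
        np.testing.assert_array_equal(ab.mask, np.swapaxes(ba.mask, 0, 1))
        np.testing.assert_allclose(
            np.nan_to_num(ab.g), np.nan_to_num(np.swapaxes(ba.g, 0, 1)), atol=1e-9
        )

    def test_translation_invariance_away_from_edges(self, rng):
        cv = Canvas(0, 5000, 0, 5000)
        xy = {ch: rng.uniform(1000, 3500, size=(60, 2)) for ch in "RBG"}
        shift = np.array([300.0, -200.0])
        prof0 = compute_triple_correlation(
            *(make_set(ch, xy[ch], cv) for ch in "RBG"), min_expected=0
        )
        prof1 = compute_triple_correlation(
            *(make_set(ch, xy[ch] + shift, cv) for ch in "RBG"), min_expected=0
        )
        np.testing.assert_array_equal(prof0.sum_w, prof1.sum_w)

    def test_deterministic_across_runs(self):
        sets = small_csr_sets(seed=23)
        a = compute_triple_correlation(sets["R"], sets["B"], sets["G"], min_expected=0)
        b = compute_triple_correlation(sets["R"], sets["B"], sets["G"], min_expected=0)
        np.testing.assert_array_equal(a.sum_w, b.sum_w)
        np.testing.assert_array_equal(np.nan_to_num(a.g), np.nan_to_num(b.g))

    def test_mask_respects_triangle_inequality(self):
        sets = small_csr_sets(seed=29)
        prof = compute_triple_correlation(sets["R"], sets["B"], sets["G"], min_expected=0)
        b = prof.bins
        r1 = b.r_centers[:, None, None]
        r2 = b.r_centers[None, :, None]
        r3 = b.r3_centers[None, None, :]
        infeasible = (r3 > r1 + r2) | (r3 < np.abs(r1 - r2))
        assert not (prof.mask & infeasible).any()
        assert np.isnan(prof.g[~prof.mask]).all()

    def test_empty_satellite_channel_rejected(self, canvas):
        full = make_set("R", [[100.0, 100.0]], canvas)
        empty = make_set("G", np.zeros((0, 2)), canvas)
        with pytest.raises(EmptyProfileError):
            tc_bruteforce(full, full, empty)

    def test_brute_force_cap(self, canvas, rng):
        big = make_set("X", rng.uniform(0, 1000, (600, 2)), canvas)
        with pytest.raises(ValueError, match="cap"):
            tc_bruteforce(big, big, big)

    def test_pooled_profiles_average_toward_csr(self):
        profs = []
        for seed in (41, 43):
            sets = csr(presets.csr_spec(seed, density_per_um2=50, canvas_nm=5000))
            profs.append(compute_triple_correlation(sets["R"], sets["B"], sets["G"]))
        pooled = pool_triple_profiles(profs)
        assert pooled.n_origins_used == sum(p.n_origins_used for p in profs)
        assert np.nanmean(pooled.g[pooled.mask]) == pytest.approx(1.0, abs=0.05)

    def test_background_dilutes_amplitude_without_moving_peak(self):
        spec_clean = presets.single_triangle_spec(19, n_instances=300)
        spec_noisy = presets.single_triangle_spec(19, n_instances=300)
        spec_noisy.background = {ch: 60.0 for ch in "RBG"}
        profs = {}
        for name, spec in (("clean", spec_clean), ("noisy", spec_noisy)):
            sets, _ = simulate(spec)
            profs[name] = compute_triple_correlation(sets["R"], sets["B"], sets["G"])
        i0 = profs["clean"].argmax()
        i1 = profs["noisy"].argmax()
        assert max(abs(a - b) for a, b in zip(i0, i1)) <= 1
        assert profs["noisy"].g[i1] < profs["clean"].g[i0]
        assert profs["noisy"].g[i1] > 1.0


# ---------------------------------------------------------------------------
# Fourier reference


class TestFourierReference:
    def test_csr_input_mean_near_one(self):
        sets = csr(presets.csr_spec(13, density_per_um2=300, canvas_nm=1280))
        prof = tc_fourier_reference(sets["R"], sets["B"], sets["G"], pixel_nm=10.0)
        assert np.nanmean(prof.g[prof.mask]) == pytest.approx(1.0, abs=0.05)

    def test_deterministic(self):
        sets = csr(presets.csr_spec(13, density_per_um2=200, canvas_nm=1280))
        a = tc_fourier_reference(sets["R"], sets["B"], sets["G"], pixel_nm=10.0)
        b = tc_fourier_reference(sets["R"], sets["B"], sets["G"], pixel_nm=10.0)
        np.testing.assert_array_equal(a.sum_w, b.sum_w)

    def test_grid_size_guard(self):
        sets = csr(presets.csr_spec(13, density_per_um2=10, canvas_nm=10_000))
        with pytest.raises(ValueError, match="max_grid"):
            tc_fourier_reference(sets["R"], sets["B"], sets["G"], pixel_nm=1.0)
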