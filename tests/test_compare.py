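"""Tests for the cross-technique comparison utilities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slimaps import (
    AngularProfile,
    DegenerateProfileError,
    MapImage,
    ScatteringPattern,
    binned_std,
    compare_profiles,
    detect_peaks,
    direction_difference_map,
    line_profile_from_pattern,
    match_peak_sets,
    normalize_minmean,
    profile_difference_sum,
    retardation_from_inclination,
    synth_profile,
    Bundle,
)
from conftest import F24_VALUES


# --- min-mean normalization ----------------------------------------------

class TestNormalizeMinMean:
    def test_two_point_example(self):
        assert np.allclose(normalize_minmean(np.array([1.0, 3.0])), [0.0, 2.0])

    def test_f24_peak_becomes_eight(self):
        out = normalize_minmean(AngularProfile(F24_VALUES, 15.0))
        assert out.values[2] == pytest.approx(8.0)
        assert out.values.min() == 0.0

    def test_constant_profile_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            normalize_minmean(np.array([2.0, 2.0, 2.0]))

    @given(st.lists(st.floats(0, 100), min_size=6, max_size=24))
    def test_output_min_zero_mean_one(self, vals):
        arr = np.asarray(vals)
        if arr.max() == arr.min():
            return
        out = normalize_minmean(arr)
        assert out.min() == 0.0
        assert out.mean() == pytest.approx(1.0)


# --- profile difference sum ----------------------------------------------

class TestProfileDifferenceSum:
    def test_identical_profiles_give_zero(self):
        p = AngularProfile(F24_VALUES, 15.0)
        assert profile_difference_sum(p, p) == 0.0

    def test_shifted_constant_blocks(self):
        a = AngularProfile([0, 2, 0, 2, 0, 2], 60.0)
        b = AngularProfile([2, 0, 2, 0, 2, 0], 60.0)
        assert profile_difference_sum(a, b) == pytest.approx(12.0)

    def test_interpolated_onto_coarse_grid(self):
        # b is a circularly linear "tent" sampled at 1 deg; interpolating it
        # at a's 15-deg azimuths reproduces the tent exactly, so the sum of
        # differences against the same tent at 15 deg is zero.
        ang_fine = np.arange(360.0)
        tent_fine = 180.0 - np.abs(((ang_fine + 180.0) % 360.0) - 180.0)
        ang_coarse = 15.0 * np.arange(24)
        tent_coarse = 180.0 - np.abs(((ang_coarse + 180.0) % 360.0) - 180.0)
        a = AngularProfile(tent_coarse, 15.0)
        b = AngularProfile(tent_fine, 1.0)
        assert profile_difference_sum(a, b) == pytest.approx(0.0, abs=1e-9)
        # and a constant vertical offset sums over a's 24 grid points
        b_off = AngularProfile(tent_fine + 0.5, 1.0)
        assert profile_difference_sum(a, b_off) == pytest.approx(12.0)

    @given(
        st.lists(st.floats(0, 10), min_size=8, max_size=8),
        st.lists(st.floats(0, 10), min_size=8, max_size=8),
        st.lists(st.floats(0, 10), min_size=8, max_size=8),
    )
    def test_pseudometric_axioms(self, va, vb, vc):
        a = AngularProfile(va, 45.0)
        b = AngularProfile(vb, 45.0)
        c = AngularProfile(vc, 45.0)
        dab = profile_difference_sum(a, b)
        assert dab == profile_difference_sum(b, a)  # symmetry
        assert (dab == 0.0) == bool(np.array_equal(a.values, b.values))
        assert dab <= (
            profile_difference_sum(a, c) + profile_difference_sum(c, b) + 1e-9
        )


# --- peak-set matching ----------------------------------------------------

class TestMatchPeakSets:
    def test_equal_counts_small_shifts(self):
        rec = match_peak_sets([30.0, 210.0], [28.0, 212.0])
        assert rec.n_peaks_delta == 0
        assert sorted(rec.position_deltas_deg) == pytest.approx([-2.0, 2.0])

    def test_extra_reference_peak_unmatched(self):
        rec = match_peak_sets([30.0, 210.0], [28.0, 150.0, 212.0])
        assert rec.n_peaks_delta == -1
        assert sorted(rec.position_deltas_deg) == pytest.approx([-2.0, 2.0])

    def test_identical_sets_all_zero(self):
        pos = [10.0, 100.0, 190.0, 280.0]
        rec = match_peak_sets(pos, pos)
        assert rec.n_peaks_delta == 0
        assert rec.position_deltas_deg == (0.0, 0.0, 0.0, 0.0)

    def test_matching_across_the_circular_wrap(self):
        rec = match_peak_sets([358.0], [2.0])
        assert rec.position_deltas_deg == pytest.approx((-4.0,))

    def test_far_peaks_stay_unmatched(self):
        rec = match_peak_sets([0.0], [90.0])
        assert rec.n_peaks_delta == 0
        assert rec.position_deltas_deg == ()

    @given(st.lists(st.floats(0, 359.9), min_size=1, max_size=6))
    def test_self_match_is_exact(self, pos):
        rec = match_peak_sets(pos, pos)
        assert rec.n_peaks_delta == 0
        assert all(d == 0.0 for d in rec.position_deltas_deg)


class TestCompareProfiles:
    def test_sli_against_finely_sampled_reference(self):
        bundles = [Bundle(20.0)]
        sli, _ = synth_profile(bundles, step_deg=15.0)
        ref, _ = synth_profile(bundles, step_deg=1.0)
        rec = compare_profiles(sli, ref)
        assert rec.n_peaks_delta == 0
        assert len(rec.position_deltas_deg) == 2
        assert max(abs(d) for d in rec.position_deltas_deg) < 2.5
        assert rec.diff_sum < 1.0


# --- scattering-pattern line profiles ------------------------------------

def _lobe_pattern(psi_centers, theta_center=48.0, theta_max=80.0,
                  res=1.0, sigma_psi=6.0, sigma_theta=6.0):
    theta = np.arange(0.0, theta_max + res, res)[:, None]
    psi = np.arange(0.0, 360.0, res)[None, :]
    vals = np.zeros((theta.size, psi.shape[1]))
    for pc in psi_centers:
        dpsi = ((psi - pc + 180.0) % 360.0) - 180.0
        vals += np.exp(
            -(dpsi**2 / (2 * sigma_psi**2))
            - (theta - theta_center) ** 2 / (2 * sigma_theta**2)
        )
    return ScatteringPattern(vals, theta_res_deg=res, psi_res_deg=res)


class TestLineProfileFromPattern:
    def test_isotropic_pattern_gives_constant_profile(self):
        pat = ScatteringPattern(np.ones((81, 360)), 1.0, 1.0)
        prof = line_profile_from_pattern(pat)
        assert np.allclose(prof.values, prof.values[0])
        assert detect_peaks(prof) == []

    def test_two_lobes_give_peaks_at_lobe_azimuths(self):
        pat = _lobe_pattern([45.0, 225.0])
        prof = line_profile_from_pattern(pat, out_step_deg=1.0)
        peaks = sorted(pk.index for pk in detect_peaks(prof))
        assert peaks == [45, 225]

    def test_blur_preserves_ring_integral_for_centered_lobes(self):
        # Scattering bands are elongated along the polar axis; for a lobe
        # much broader in theta than the 8-deg blur, the ring sum is
        # conserved to < 1% (azimuthal blur conserves it exactly, polar
        # blur barely moves flux across a slowly varying theta profile).
        pat = _lobe_pattern([90.0], theta_max=120.0, sigma_theta=30.0)
        raw = line_profile_from_pattern(pat, blur_fwhm_deg=1e-9)
        blurred = line_profile_from_pattern(pat, blur_fwhm_deg=8.0)
        assert blurred.values.sum() == pytest.approx(raw.values.sum(), rel=0.01)

    def test_theta_outside_pattern_rejected(self):
        pat = ScatteringPattern(np.ones((20, 360)), 1.0, 1.0)
        with pytest.raises(ValueError):
            line_profile_from_pattern(pat, circle_theta_deg=48.0)


# --- direction difference and binning -------------------------------------

class TestDirectionDifferenceMap:
    def _map(self, arr, sentinel=-1.0):
        return MapImage(np.asarray(arr, np.float32), "dir", sentinel)

    def test_identical_maps_give_zero(self):
        m = self._map([[10.0, 170.0]])
        assert np.allclose(direction_difference_map(m, m).data, 0.0)

    def test_axial_wrap(self):
        sli = self._map([[5.0]])
        ref = self._map([[175.0]])
        assert direction_difference_map(sli, ref).data[0, 0] == pytest.approx(10.0)

    def test_boundary_maps_to_plus_90(self):
        sli = self._map([[90.0]])
        ref = self._map([[0.0]])
        assert direction_difference_map(sli, ref).data[0, 0] == 90.0
        assert direction_difference_map(ref, sli).data[0, 0] == 90.0

    def test_antisymmetric_off_boundary(self):
        rng = np.random.default_rng(5)
        a = self._map(rng.uniform(0, 180, (4, 4)))
        b = self._map(rng.uniform(0, 180, (4, 4)))
        ab = direction_difference_map(a, b).data
        ba = direction_difference_map(b, a).data
        off = np.abs(ab) != 90.0
        assert np.allclose(ab[off], -ba[off], atol=1e-5)

    def test_undefined_propagates(self):
        sli = self._map([[-1.0, 20.0]])
        ref = self._map([[30.0, -1.0]])
        out = direction_difference_map(sli, ref)
        assert np.all(np.isnan(out.data))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            direction_difference_map(
                self._map(np.zeros((2, 2))), self._map(np.zeros((3, 3)))
            )


class TestBinnedStd:
    def test_zero_values_give_zero_sigma(self):
        values = MapImage(np.zeros((10, 10), np.float32), "v")
        binner = MapImage(np.full((10, 10), 0.45, np.float32), "b")
        rows = binned_std(values, binner)
        occupied = [r for r in rows if r[2] > 0]
        assert occupied == [(pytest.approx(0.4), 0.0, 100)]

    def test_normal_spread_recovered(self):
        rng = np.random.default_rng(17)
        n = 10_000
        vals = rng.normal(0.0, 5.0, (100, 100)).astype(np.float32)
        binner = np.full((100, 100), 0.75, np.float32)
        rows = binned_std(MapImage(vals, "v"), MapImage(binner, "b"))
        (row,) = [r for r in rows if r[2] > 0]
        assert row[0] == pytest.approx(0.7)
        assert row[2] == n
        assert row[1] == pytest.approx(5.0, abs=0.2)

    def test_empty_bins_report_nan(self):
        values = MapImage(np.zeros((2, 2), np.float32), "v")
        binner = MapImage(np.zeros((2, 2), np.float32), "b")
        rows = binned_std(values, binner)
        assert all(math.isnan(r[1]) and r[2] == 0 for r in rows[1:])


# --- retardation model ----------------------------------------------------

class TestRetardationFromInclination:
    def test_in_plane_limit_is_ret_max(self):
        assert retardation_from_inclination(0.0, 0.63) == pytest.approx(0.63)

    def test_vertical_fiber_gives_zero(self):
        assert retardation_from_inclination(90.0, 0.8) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert retardation_from_inclination(60.0, 0.8) == pytest.approx(
            0.2298, abs=1e-4
        )

    def test_monotonically_decreasing_in_alpha(self):
        vals = [retardation_from_inclination(a, 0.9) for a in np.linspace(0, 90, 50)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            retardation_from_inclination(-1.0, 0.5)
        with pytest.raises(ValueError):
            retardation_from_inclination(10.0, 1.5)
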