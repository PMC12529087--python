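"""Streamline propagation, termination rules, trimming, filtering, smoothing."""

import numpy as np
import pytest
from conftest import make_field_tensor_volume, make_uniform_tensor_volume

from myotract import (
    FilterCriteria,
    LabelVolume,
    SeedSet,
    Streamline,
    TrackOptions,
    filter_tracts,
    propagate,
    smooth,
    tract_length,
    trim_aponeurosis,
)

VD_ANISO = (1.0, 1.0, 6.0)
VD_ISO = (1.0, 1.0, 1.0)


def seedset(points, scheme="VXL"):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return SeedSet(
        scheme=scheme,
        points=pts,
        lookup_voxels=np.round(pts).astype(int),
        skipped=np.zeros(len(pts), dtype=bool),
    )


def full_labels(shape, vd):
    return LabelVolume(np.ones(shape, dtype=bool), np.zeros(shape, dtype=bool), vd)


class TestPropagation:
    def test_uniform_z_field_advances_sixth_of_slice(self):
        shape = (9, 9, 20)
        tv = make_uniform_tensor_volume(shape, (0, 0, 1))
        lab = full_labels(shape, VD_ANISO)
        t = propagate(0, seedset((4, 4, 2)), tv, lab)
        d = np.diff(t.points, axis=0)
        assert np.allclose(d[:, 2], 1.0 / 6.0)
        assert np.allclose(d[:, :2], 0.0)
        assert t.termination_reasons == ("boundary",)

    def test_constant_mm_step_spacing(self):
        shape = (30, 30, 30)
        tv = make_uniform_tensor_volume(shape, (0.3, 0.2, 0.933))
        lab = full_labels(shape, VD_ANISO)
        t = propagate(0, seedset((15, 15, 2)), tv, lab)
        mm = t.points * np.array([1.0, 1.0, 6.0])
        steps = np.linalg.norm(np.diff(mm, axis=0), axis=1)
        assert np.abs(steps - 1.0).max() < 1e-9

    def test_oblique_field_matches_analytic_ray(self):
        """Uniform direction 45 deg in the X-Z mm plane traces a straight ray."""
        shape = (9, 40, 40)
        e = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        tv = make_uniform_tensor_volume(shape, e)
        lab = full_labels(shape, VD_ISO)
        seed = np.array([4.0, 2.0, 2.0])
        t = propagate(0, seedset(seed), tv, lab)
        k = np.arange(len(t.points))[:, None]
        expected = seed + k * np.array([0.0, e[0], e[2]])  # (row, col, slice)
        assert np.abs(t.points - expected).max() < 1e-9

    def test_apo_first_step_heads_proximal_to_distal(
        self, seeds_by_scheme, fitted, labels
    ):
        ss = seeds_by_scheme["APO"]
        for i in (0, len(ss) // 2, len(ss) - 1):
            t = propagate(i, ss, fitted, labels)
            if len(t.points) > 1:
                assert t.points[1, 2] > t.points[0, 2]

    def test_trilinear_lookup_matches_nearest_in_uniform_field(self):
        shape = (9, 9, 20)
        tv = make_uniform_tensor_volume(shape, (0.2, 0.1, 0.974679))
        lab = full_labels(shape, VD_ANISO)
        a = propagate(0, seedset((4, 4, 2)), tv, lab)
        b = propagate(0, seedset((4, 4, 2)), tv, lab, TrackOptions(interp="trilinear"))
        assert np.allclose(a.points, b.points, atol=1e-9)

    def test_bidirectional_merges_branches_around_seed(self):
        shape = (9, 9, 40)
        tv = make_uniform_tensor_volume(shape, (0, 0, 1))
        lab = full_labels(shape, VD_ISO)
        t = propagate(0, seedset((4, 4, 20)), tv, lab, bidirectional=True)
        j = t.junction_index
        assert np.allclose(t.points[j], (4, 4, 20))
        assert len(t.points) == shape[2]  # spans the whole column, no duplicate
        assert np.all(np.diff(t.points[:, 2]) > 0)
        assert t.termination_reasons == ("boundary", "boundary")


class TestTermination:
    def test_fa_outside_window_stops_immediately(self):
        shape = (9, 9, 9)
        tv = make_uniform_tensor_volume(shape, (0, 0, 1), fa_value=0.45)
        lab = full_labels(shape, VD_ISO)
        t = propagate(0, seedset((4, 4, 4)), tv, lab)
        assert len(t.points) == 1
        assert t.termination_reasons == ("fa_window",)

    def test_fa_window_configurable(self):
        shape = (9, 9, 9)
        tv = make_uniform_tensor_volume(shape, (0, 0, 1), fa_value=0.45)
        lab = full_labels(shape, VD_ISO)
        t = propagate(0, seedset((4, 4, 1)), tv, lab, TrackOptions(fa_high=0.5))
        assert len(t.points) > 1

    def test_boundary_candidate_not_appended(self):
        shape = (9, 9, 9)
        tv = make_uniform_tensor_volume(shape, (0, 0, 1))
        lab = full_labels(shape, VD_ISO)
        t = propagate(0, seedset((4, 4, 6)), tv, lab)
        assert t.points[-1, 2] <= 8.5
        assert t.termination_reasons == ("boundary",)

    @staticmethod
    def _turning_field(persistent: bool):
        """Direction turns 35 deg at slice 12, either permanently or for a
        single voxel layer."""
        shape = (40, 40, 30)
        d0 = np.array([0.0, 0.0, 1.0])
        a = np.radians(35.0)
        d1 = np.array([np.sin(a), 0.0, np.cos(a)])
        field = np.broadcast_to(d0, shape + (3,)).copy()
        if persistent:
            field[:, :, 12:] = d1
        else:
            field[:, :, 12:13] = d1
        return make_field_tensor_volume(field)

    def test_two_consecutive_large_angles_terminate_and_trim(self):
        tv = self._turning_field(persistent=True)
        lab = full_labels(tv.fa.shape, VD_ISO)
        t = propagate(0, seedset((20, 20, 2)), tv, lab)
        assert t.termination_reasons == ("angle",)
        # the two offending points are removed: all retained points precede
        # the turn by construction
        assert np.all(t.points[:, 2] <= 13.0 + 1e-9)

    def test_single_large_angle_then_small_continues(self):
        tv = self._turning_field(persistent=False)
        lab = full_labels(tv.fa.shape, VD_ISO)
        t = propagate(0, seedset((20, 20, 2)), tv, lab)
        assert t.termination_reasons == ("boundary",)
        assert t.points[-1, 2] > 25


class TestTrimming:
    @staticmethod
    def _tract(n_inside):
        """Bidirectional tract crossing an aponeurosis column at its inner end."""
        apo = np.zeros((20, 20, 5), dtype=bool)
        apo[5, 0:n_inside, 2] = True
        pts = np.array([[5.0, c, 2.0] for c in range(10)])
        t = Streamline(
            points=pts,
            seed_index=0,
            seed_point=pts[0],
            termination_reasons=("boundary", "boundary"),
            junction_index=0,
        )
        return t, apo

    def test_three_inner_points_removed(self):
        t, apo = self._tract(3)
        out = trim_aponeurosis(t, apo)
        assert len(out.points) == 7
        assert out.points[0, 1] == 3.0

    def test_at_most_four_removed(self):
        t, apo = self._tract(6)
        out = trim_aponeurosis(t, apo)
        assert len(out.points) == 6
        assert out.points[0, 1] == 4.0

    def test_no_inside_points_is_identity(self):
        t, apo = self._tract(0)
        out = trim_aponeurosis(t, apo)
        assert np.array_equal(out.points, t.points)


class TestFiltering:
    def test_short_tract_excluded_at_threshold(self):
        tracts = ["a", "b"]
        lengths = np.array([4.9, 5.1])
        kept, idx, counts = filter_tracts(tracts, lengths, FilterCriteria(min_length_mm=5.0))
        assert kept == ["b"] and counts["min_length"] == 1

    def test_disabled_criteria_identity(self):
        tracts = list("abcd")
        kept, idx, counts = filter_tracts(
            tracts, np.array([1, 2, 3, 4.0]), FilterCriteria(min_length_mm=None)
        )
        assert kept == tracts and counts == {}

    def test_preset_matches_per_tract_reevaluation(self):
        rng = np.random.default_rng(3)
        n = 200
        lengths = rng.uniform(2, 40, n)
        alphas = rng.uniform(0, 50, n)
        kappas = rng.uniform(0, 40, n)
        crit = FilterCriteria(min_length_mm=10.0, max_alpha_deg=25.0, max_kappa_per_m=20.0)
        kept, idx, _ = filter_tracts(list(range(n)), lengths, crit, alphas, kappas)
        expected = [
            i
            for i in range(n)
            if lengths[i] >= 10.0 and alphas[i] <= 25.0 and kappas[i] <= 20.0
        ]
        assert list(idx) == expected


class TestSmoothing:
    @staticmethod
    def _stream(pts):
        pts = np.asarray(pts, dtype=float)
        return Streamline(
            points=pts,
            seed_index=0,
            seed_point=pts[0],
            termination_reasons=("boundary",),
        )

    def test_collinear_points_reproduced(self):
        k = np.arange(12.0)
        pts = np.column_stack([2 + 0.5 * k, 3 - 0.25 * k, 1 + k / 6])
        out = smooth(self._stream(pts))
        assert np.abs(out.fitted_points - pts).max() < 1e-9

    def test_exact_quadratic_recovered(self):
        k = np.arange(15.0)
        pts = np.column_stack([1 + k + 0.05 * k**2, 2 - 0.02 * k**2, 0.1 * k])
        out = smooth(self._stream(pts), orders=(2, 2, 3))
        assert np.abs(out.fitted_points - pts).max() < 1e-9

    def test_coefficient_counts(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (30, 3))
        out = smooth(self._stream(pts), orders=(2, 2, 3))
        assert tuple(len(c) for c in out.coefficients) == (3, 3, 4)
        assert len(out.fitted_points) == 30

    def test_too_few_points_pass_through_with_warning(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        with pytest.warns(UserWarning, match="not smoothed"):
            out = smooth(self._stream(pts), orders=(2, 2, 3))
        assert out.unfitted
        assert np.array_equal(out.fitted_points, pts)


def test_no_premature_termination_on_noise_free_phantom(smoothed_by_scheme):
    """Only boundary terminations occur without noise, for every scheme."""
    for scheme, smoothed in smoothed_by_scheme.items():
        reasons = {r for sm in smoothed for r in sm.raw.termination_reasons}
        assert reasons <= {"boundary"}, f"{scheme}: {reasons}"
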