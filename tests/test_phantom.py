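"""Phantom geometry, orientation field, tensors, encoding, signals, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotract import (
    PhantomSpec,
    add_noise,
    build_geometry,
    build_orientation_field,
    build_tensor_field,
    make_encoding,
    synthesize_dwi,
    tensor_from_orientation,
)


class TestGeometry:
    def test_default_has_37_tissue_slices(self, labels):
        n = sum(labels.muscle_mask[:, :, s].any() for s in range(labels.shape[2]))
        assert n == 37
        # one proximal and two distal padded slices
        assert not labels.tissue_mask[:, :, 0].any()
        assert not labels.tissue_mask[:, :, 38:].any()

    def test_masks_disjoint(self, labels):
        assert not (labels.muscle_mask & labels.aponeurosis_mask).any()

    def test_empty_phantom(self):
        spec = PhantomSpec(muscle_slices=0)
        lab = build_geometry(spec)
        assert not lab.muscle_mask.any() and not lab.aponeurosis_mask.any()

    def test_slice10_matches_bruteforce_enumeration(self, spec, labels):
        s = 10
        a_r, a_c = spec.semi_axes(s)
        cr, cc = spec.grid_rows // 2, spec.grid_cols // 2
        count = 0
        for r in range(spec.grid_rows):
            for c in range(spec.grid_cols):
                inside = ((r - cr) / a_r) ** 2 + ((c - cc) / a_c) ** 2 <= 1.0
                apo = inside and c == cc and abs(r - cr) <= spec.apo_row_fraction * a_r
                count += inside and not apo
        assert labels.muscle_mask[:, :, s].sum() == count

    def test_oversized_ellipse_names_slice(self):
        spec = PhantomSpec(semi_axes_end=(30.0, 30.0))
        with pytest.raises(ValueError, match="slice"):
            build_geometry(spec)


class TestOrientation:
    def test_theta_spans_configured_range(self, orient, labels):
        th = orient.theta_deg[labels.muscle_mask]
        assert th.min() == pytest.approx(66.4, abs=1e-9)
        assert th.max() == pytest.approx(82.0, abs=1e-9)

    def test_aponeurosis_direction_is_slice_axis(self, orient, labels):
        e = orient.eps1[labels.aponeurosis_mask]
        assert np.allclose(e, [0.0, 0.0, 1.0])

    def test_phi_covers_four_quadrants(self, orient, labels):
        phi = orient.phi_deg[labels.muscle_mask]
        for lo, hi in [(0, 90), (90, 180), (-180, -90), (-90, 0)]:
            assert ((phi > lo) & (phi < hi)).any()

    def test_eps1_unit_length(self, orient, labels):
        e = orient.eps1[labels.tissue_mask]
        assert np.abs(np.linalg.norm(e, axis=1) - 1).max() < 1e-12

    def test_single_voxel_closed_form(self, spec, labels, orient):
        """theta/phi at one muscle voxel match a brute-force evaluation."""
        s = 20
        msk = labels.muscle_mask[:, :, s]
        apo = np.argwhere(labels.aponeurosis_mask[:, :, s])
        rr, cc = np.argwhere(msk)[17]
        d_all = {}
        for r, c in np.argwhere(msk):
            d_all[(r, c)] = min(np.hypot(r - ar, c - ac) for ar, ac in apo)
        d = d_all[(rr, cc)]
        dmin, dmax = min(d_all.values()), max(d_all.values())
        nearest = min(apo, key=lambda a: np.hypot(rr - a[0], cc - a[1]))
        phi_exp = np.degrees(np.arctan2(rr - nearest[0], cc - nearest[1]))
        tissue_slices = [z for z in range(spec.grid_slices) if labels.tissue_mask[:, :, z].any()]
        z_hat = tissue_slices.index(s) / (len(tissue_slices) - 1)
        d_hat = (d - dmin) / (dmax - dmin)
        w_s, w_d = spec.theta_weights
        theta_exp = 66.4 + (82.0 - 66.4) * (w_s * z_hat + w_d * d_hat)
        assert orient.theta_deg[rr, cc, s] == pytest.approx(theta_exp, abs=1e-9)
        assert orient.phi_deg[rr, cc, s] == pytest.approx(phi_exp, abs=1e-9)

    def test_muscle_slice_without_aponeurosis_raises(self, spec):
        lab = build_geometry(spec)
        lab.aponeurosis_mask[:, :, 20] = False
        with pytest.raises(ValueError, match="aponeurosis"):
            build_orientation_field(lab, spec)


class TestTensor:
    LAM = (2.1e-3, 1.6e-3, 1.4e-3)

    def test_axis_aligned(self):
        D = tensor_from_orientation((1.0, 0.0, 0.0), self.LAM)
        assert D[0, 0] == pytest.approx(2.1e-3)
        assert abs(D[0, 1]) < 1e-18 and abs(D[0, 2]) < 1e-18

    def test_trace_is_eigenvalue_sum(self, true_tensors, labels):
        tr = np.trace(true_tensors[labels.muscle_mask], axis1=-2, axis2=-1)
        assert np.allclose(tr, 5.1e-3)

    def test_non_unit_direction_raises(self):
        with pytest.raises(ValueError, match="unit"):
            tensor_from_orientation((2.0, 0.0, 0.0), self.LAM)

    def test_eigendecomposition_roundtrip_random_directions(self):
        rng = np.random.default_rng(42)
        v = rng.standard_normal((1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        for e1 in v:
            D = tensor_from_orientation(e1, self.LAM)
            w, V = np.linalg.eigh(D)
            assert np.allclose(w[::-1], self.LAM, rtol=1e-9)
            assert abs(abs(np.dot(V[:, 2], e1)) - 1.0) < 1e-9

    def test_field_construction_matches_scalar_path(self, orient, spec, labels):
        D = build_tensor_field(orient, spec)
        idx = tuple(np.argwhere(labels.muscle_mask)[123])
        D_one = tensor_from_orientation(orient.eps1[idx], spec.eigenvalues)
        assert np.allclose(D[idx], D_one, atol=1e-18)


class TestEncoding:
    def test_twelve_directions_well_separated(self):
        enc = make_encoding(12, 475.0, 0)
        assert (enc.b_values > 0).sum() == 12
        assert enc.b_values[0] == 0.0
        assert enc.min_folded_angle_deg() >= 30.0

    def test_unit_norms(self):
        enc = make_encoding(12, 475.0, 0)
        d = enc.directions[1:]
        assert np.abs(np.linalg.norm(d, axis=1) - 1).max() < 1e-12

    def test_deterministic_per_seed(self):
        a = make_encoding(12, 475.0, 3)
        b = make_encoding(12, 475.0, 3)
        assert np.array_equal(a.directions, b.directions)

    def test_too_few_directions_raises(self):
        with pytest.raises(ValueError):
            make_encoding(5, 475.0, 0)


class TestSignals:
    def test_b0_is_unity_in_tissue(self, clean_dwi, labels):
        assert np.allclose(clean_dwi.signals[labels.tissue_mask][:, 0], 1.0)
        assert np.all(clean_dwi.signals[~labels.tissue_mask] == 0)

    def test_scalar_attenuation_oracle(self):
        """Diagonal D, r along x, b = 475 -> S = exp(-475 * 2.1e-3)."""
        from myotract.phantom import EncodingScheme

        D = np.zeros((1, 1, 1, 3, 3))
        D[0, 0, 0] = np.diag([2.1e-3, 1.6e-3, 1.4e-3])
        enc = EncodingScheme(
            directions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            b_values=np.array([0.0, 475.0]),
        )
        stack = synthesize_dwi(D, enc, np.ones((1, 1, 1), dtype=bool))
        assert stack.signals[0, 0, 0, 1] == pytest.approx(np.exp(-0.9975), rel=1e-12)

    def test_antipodal_symmetry_and_b_monotonicity(self, true_tensors, labels):
        from myotract.phantom import EncodingScheme

        r = np.array([0.3, -0.5, 0.81240384])
        r /= np.linalg.norm(r)
        bs = [0.0, 200.0, 475.0, 900.0]
        enc = EncodingScheme(
            directions=np.vstack([r, -r, [r] * (len(bs) - 1)]),
            b_values=np.array([475.0, 475.0] + bs[1:]),
        )
        stack = synthesize_dwi(true_tensors, enc, labels.tissue_mask)
        sig = stack.signals[labels.muscle_mask]
        assert np.allclose(sig[:, 0], sig[:, 1])  # S(r) == S(-r)
        s_b = sig[:, 2:]
        assert np.all(np.diff(s_b, axis=1) < 0)  # decreasing in b

    def test_negative_b_raises(self, true_tensors, labels):
        from myotract.phantom import EncodingScheme

        enc = EncodingScheme(
            directions=np.array([[1.0, 0, 0]]), b_values=np.array([-1.0])
        )
        with pytest.raises(ValueError):
            synthesize_dwi(true_tensors, enc, labels.tissue_mask)


class TestNoise:
    def test_infinite_snr_is_identity(self, clean_dwi):
        out = add_noise(clean_dwi, np.inf, 0)
        assert out is clean_dwi

    def test_empirical_sigma_matches(self, clean_dwi):
        noisy = add_noise(clean_dwi, 39.0, 5)
        resid = (noisy.signals - clean_dwi.signals).ravel()
        assert len(resid) > 1e5
        assert abs(resid.std() - 1 / 39) / (1 / 39) < 0.02

    def test_trial_substreams_reproducible_and_independent(self, clean_dwi):
        a = add_noise(clean_dwi, 39.0, 5, trial_index=2)
        b = add_noise(clean_dwi, 39.0, 5, trial_index=2)
        c = add_noise(clean_dwi, 39.0, 5, trial_index=3)
        assert np.array_equal(a.signals, b.signals)
        assert not np.array_equal(a.signals, c.signals)

    def test_invalid_snr_raises(self, clean_dwi):
        with pytest.raises(ValueError):
            add_noise(clean_dwi, 0.0, 0)

    def test_rician_option_yields_nonnegative_biased_magnitudes(self, clean_dwi):
        out = add_noise(clean_dwi, 39.0, 5, rician=True)
        assert np.all(out.signals >= 0)
        # magnitude noise biases the background upward (Rayleigh floor)
        bg = clean_dwi.signals[..., 0] == 0
        assert out.signals[..., 0][bg].mean() > 0.5 / 39


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(min_value=0.2, max_value=5.0),
    z=st.floats(min_value=-0.95, max_value=0.95),
    phi=st.floats(min_value=-np.pi, max_value=np.pi),
)
def test_tensor_invariant_under_any_direction(scale, z, phi):
    """Constructed tensors are SPD with the requested eigen-system."""
    r = np.sqrt(1 - z**2)
    e1 = np.array([r * np.cos(phi), r * np.sin(phi), z])
    lam = np.array([2.1e-3, 1.6e-3, 1.4e-3]) * scale
    D = tensor_from_orientation(e1, lam)
    assert np.allclose(D, D.T)
    w = np.linalg.eigvalsh(D)
    assert np.all(w > 0)
    assert np.trace(D) == pytest.approx(lam.sum(), rel=1e-12)
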