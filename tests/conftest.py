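"""Shared fixtures: the default simulated muscle, its noise-free pipeline
products, and small synthetic helpers."""

from __future__ import annotations

import numpy as np
import pytest

from myotract import (
    PhantomSpec,
    TensorVolume,
    build_geometry,
    build_orientation_field,
    build_tensor_field,
    central_axis,
    ground_truth_alpha_map,
    make_encoding,
    make_seeds,
    run_tractography,
    synthesize_dwi,
    wls_fit,
)


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def labels(spec):
    return build_geometry(spec)


@pytest.fixture(scope="session")
def orient(labels, spec):
    return build_orientation_field(labels, spec)


@pytest.fixture(scope="session")
def true_tensors(orient, spec):
    return build_tensor_field(orient, spec)


@pytest.fixture(scope="session")
def encoding(spec):
    return make_encoding(spec.n_directions, spec.b_value, spec.rng_seed)


@pytest.fixture(scope="session")
def clean_dwi(true_tensors, encoding, labels):
    return synthesize_dwi(true_tensors, encoding, labels.tissue_mask)


@pytest.fixture(scope="session")
def fitted(clean_dwi, encoding, labels):
    return wls_fit(clean_dwi, encoding, labels.tissue_mask)


@pytest.fixture(scope="session")
def axis(labels):
    return central_axis(labels.muscle_mask, labels.voxel_dims_mm)


@pytest.fixture(scope="session")
def gt_alpha(orient, axis):
    return ground_truth_alpha_map(orient, axis)


@pytest.fixture(scope="session")
def seeds_by_scheme(labels):
    return {s: make_seeds(s, labels) for s in ("APO", "VXL", "EDGE")}


@pytest.fixture(scope="session")
def smoothed_by_scheme(fitted, labels, seeds_by_scheme):
    """Noise-free all-tract smoothed streamlines per seeding scheme."""
    return {
        s: run_tractography(fitted, labels, seeds_by_scheme[s])
        for s in ("APO", "VXL", "EDGE")
    }


@pytest.fixture(scope="session")
def small_spec():
    """A reduced muscle for cheap end-to-end tests."""
    return PhantomSpec(
        grid_rows=28,
        grid_cols=28,
        grid_slices=12,
        muscle_slices=9,
        semi_axes_start=(5.0, 8.0),
        semi_axes_end=(7.0, 10.0),
    )


def make_uniform_tensor_volume(shape, eps1, fa_value=0.2):
    """TensorVolume stand-in with one direction and FA everywhere (synthetic)."""
    e = np.asarray(eps1, dtype=float)
    e = e / np.linalg.norm(e)
    evecs = np.zeros(shape + (3, 3))
    evecs[..., :, 0] = e
    return TensorVolume(
        D=np.zeros(shape + (3, 3)),
        evecs=evecs,
        evals=np.tile(np.array([2.1e-3, 1.6e-3, 1.4e-3]), shape + (1,)),
        fa=np.full(shape, fa_value),
        valid_mask=np.ones(shape, dtype=bool),
    )


def make_field_tensor_volume(eps1_field, fa_value=0.2):
    """TensorVolume stand-in from an explicit per-voxel direction field."""
    eps1_field = np.asarray(eps1_field, dtype=float)
    shape = eps1_field.shape[:3]
    evecs = np.zeros(shape + (3, 3))
    evecs[..., :, 0] = eps1_field
    return TensorVolume(
        D=np.zeros(shape + (3, 3)),
        evecs=evecs,
        evals=np.tile(np.array([2.1e-3, 1.6e-3, 1.4e-3]), shape + (1,)),
        fa=np.full(shape, fa_value),
        valid_mask=np.ones(shape, dtype=bool),
    )
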