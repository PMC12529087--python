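"""Shared small helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x):
    """Round to nearest integer, halves away from the origin toward +inf.

    Used consistently for slice-coordinate rounding and nearest-voxel
    lookup so tracking, binning, and seeding agree on voxel membership.
    """
    return np.floor(np.asarray(x) + 0.5).astype(int)


def to_mm(vec_rcs: np.ndarray, voxel_dims_mm) -> np.ndarray:
    """Convert (row, col, slice) displacement(s) to (x, y, z) mm.

    x = +col, y = +row, z = +slice.
    """
    v = np.asarray(vec_rcs, dtype=float)
    dy, dx, dz = voxel_dims_mm[0], voxel_dims_mm[1], voxel_dims_mm[2]
    return np.stack(
        [v[..., 1] * dx, v[..., 0] * dy, v[..., 2] * dz], axis=-1
    )


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length vector")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def fold_to_90(angles_deg):
    """Fold angles (deg) into [0, 90] by reflecting about 90."""
    a = np.abs(np.asarray(angles_deg, dtype=float))
    return np.where(a > 90.0, 180.0 - a, a)
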