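"""Architecture quantification: farthest streamline sampling, central axis,
pennation angle, curvature, fiber-tract length, and aponeurosis angles.

All geometry is evaluated in physical (mm) space; tract points live in
(row, col, slice) voxel coordinates and are converted with the voxel
dimensions.  Angles are reported in degrees, curvature in 1/m, lengths in
mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import angle_between_deg, fold_to_90, round_half_up, to_mm
from .phantom import OrientationField
from .seeding import ApoMesh
from .tracking import SmoothedStreamline

__all__ = [
    "CentralAxis",
    "ArchitectureRecord",
    "fss_sample",
    "streamline_distance",
    "central_axis",
    "pennation_alpha",
    "segment_alphas",
    "ground_truth_alpha_map",
    "curvature_kappa",
    "tract_length",
    "gamma_beta",
    "quantify_tracts",
]


# ---------------------------------------------------------------------------
# farthest streamline sampling


def _resample_polyline(points_mm: np.ndarray, n: int) -> np.ndarray:
    """Arc-length-uniform resampling of an open polyline to n points."""
    if len(points_mm) == 1:
        return np.repeat(points_mm, n, axis=0)
    seg = np.linalg.norm(np.diff(points_mm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(points_mm[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, points_mm.shape[1]))
    for i in range(points_mm.shape[1]):
        out[:, i] = np.interp(t, s, points_mm[:, i])
    return out


def streamline_distance(a_mm: np.ndarray, b_mm: np.ndarray) -> float:
    """Symmetric mean-of-mean-closest-point distance between two polylines."""
    d = np.linalg.norm(a_mm[:, None, :] - b_mm[None, :, :], axis=-1)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def fss_sample(
    tracts_points_mm: Sequence[np.ndarray],
    n_keep: int,
    n_resample: int = 15,
) -> np.ndarray:
    """Greedy farthest-point subsampling of streamlines.

    Starts from the longest tract and iteratively adds the tract whose
    minimum symmetric mean-closest-point distance to the already selected
    set is largest (ties broken by lowest tract index).  Tracts are
    resampled to ``n_resample`` points for the distance computation.
    Returns the selected indices in selection order; if ``n_keep`` is at
    least the population size, all indices are returned.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    n = len(tracts_points_mm)
    if n_keep >= n:
        return np.arange(n)
    lengths = np.array(
        [np.linalg.norm(np.diff(p, axis=0), axis=1).sum() if len(p) > 1 else 0.0 for p in tracts_points_mm]
    )
    rs = np.stack([_resample_polyline(p, n_resample) for p in tracts_points_mm])
    selected = [int(np.argmax(lengths))]
    # min distance from each tract to the selected set
    min_d = _mcp_to_one(rs, rs[selected[0]])
    min_d[selected[0]] = -np.inf
    for _ in range(n_keep - 1):
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        d = _mcp_to_one(rs, rs[nxt])
        min_d = np.minimum(min_d, d)
        min_d[nxt] = -np.inf
    return np.asarray(selected)


def _mcp_to_one(all_rs: np.ndarray, one: np.ndarray) -> np.ndarray:
    """Symmetric MCP distance from every resampled tract to one tract."""
    d = np.linalg.norm(all_rs[:, :, None, :] - one[None, None, :, :], axis=-1)
    return 0.5 * (d.min(axis=2).mean(axis=1) + d.min(axis=1).mean(axis=1))


# ---------------------------------------------------------------------------
# central axis


@dataclass
class CentralAxis:
    """The muscle's mechanical line of action.

    Third-order polynomial fits of the per-slice mask centroids (row and
    column vs slice number), with a per-slice unit tangent (xyz, mm space)
    from the slice-wise difference of the fitted positions.
    """

    slices: np.ndarray  # (k,) slice indices containing muscle
    row_coeffs: np.ndarray  # ascending-power polynomial coefficients
    col_coeffs: np.ndarray
    fitted_row: np.ndarray  # (k,)
    fitted_col: np.ndarray
    tangents: np.ndarray  # (k, 3) xyz unit vectors

    def tangent_at(self, slice_coord: float) -> np.ndarray:
        """Tangent of the nearest muscle slice (clamped to the range)."""
        s = int(round_half_up(slice_coord))
        i = int(np.clip(np.searchsorted(self.slices, s), 0, len(self.slices) - 1))
        if i > 0 and abs(self.slices[i - 1] - s) <= abs(self.slices[i] - s):
            i -= 1
        return self.tangents[i]


def central_axis(muscle_mask: np.ndarray, voxel_dims_mm) -> CentralAxis:
    """Fit the central line of action through the slice-wise centroids."""
    slices = np.array([s for s in range(muscle_mask.shape[2]) if muscle_mask[:, :, s].any()])
    if len(slices) < 4:
        raise ValueError("central axis requires at least 4 muscle slices")
    cr = np.empty(len(slices))
    cc = np.empty(len(slices))
    for i, s in enumerate(slices):
        rr, ccol = np.nonzero(muscle_mask[:, :, s])
        cr[i] = rr.mean()
        cc[i] = ccol.mean()
    z = slices.astype(float)
    row_coeffs = np.polynomial.polynomial.polyfit(z, cr, 3)
    col_coeffs = np.polynomial.polynomial.polyfit(z, cc, 3)
    fr = np.polynomial.polynomial.polyval(z, row_coeffs)
    fc = np.polynomial.polynomial.polyval(z, col_coeffs)
    # forward difference of fitted positions, in mm; backward at the end
    dy, dx, dz = voxel_dims_mm
    pos_mm = np.stack([fc * dx, fr * dy, z * dz], axis=-1)
    diff = np.diff(pos_mm, axis=0)
    tangents = np.vstack([diff, diff[-1:]])
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    return CentralAxis(
        slices=slices,
        row_coeffs=row_coeffs,
        col_coeffs=col_coeffs,
        fitted_row=fr,
        fitted_col=fc,
        tangents=tangents,
    )


# ---------------------------------------------------------------------------
# per-tract properties


def tract_length(points_vox: np.ndarray, voxel_dims_mm) -> float:
    """Summed Euclidean distance between consecutive points, in mm."""
    if len(points_vox) < 2:
        return 0.0
    mm = to_mm(points_vox, voxel_dims_mm)
    return float(np.linalg.norm(np.diff(mm, axis=0), axis=1).sum())


def pennation_alpha(
    points_vox: np.ndarray,
    seed_point_vox: np.ndarray,
    axis: CentralAxis,
    voxel_dims_mm,
) -> tuple[np.ndarray, float]:
    """Pointwise pennation angle and its tract mean.

    For each point beyond the first, alpha is the angle (mm space, folded
    to [0, 90] deg) between the chord from the seed point to the tract
    point and the central-axis tangent at the seed's slice.
    """
    if len(points_vox) < 2:
        raise ValueError("pennation angle requires at least 2 points")
    tangent = axis.tangent_at(float(seed_point_vox[2]))
    seed_mm = to_mm(np.asarray(seed_point_vox, dtype=float), voxel_dims_mm)
    pts_mm = to_mm(points_vox, voxel_dims_mm)
    chords = pts_mm - seed_mm
    norms = np.linalg.norm(chords, axis=1)
    keep = norms > 1e-12
    keep[0] = False  # the seed point itself has a zero chord
    cosang = np.clip((chords[keep] @ tangent) / norms[keep], -1.0, 1.0)
    alphas = fold_to_90(np.degrees(np.arccos(cosang)))
    return alphas, float(alphas.mean())


def segment_alphas(
    fitted_points_vox: np.ndarray, axis: CentralAxis, voxel_dims_mm
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment pennation angle of a smoothed tract.

    Each segment's direction (mm space) is compared with the central-axis
    tangent at the segment midpoint's slice, folded to [0, 90] deg.
    Returns (angles, segment midpoint voxels) for ground-truth lookup.
    """
    pts_mm = to_mm(fitted_points_vox, voxel_dims_mm)
    seg = np.diff(pts_mm, axis=0)
    mids = 0.5 * (fitted_points_vox[1:] + fitted_points_vox[:-1])
    vox = round_half_up(mids)
    norms = np.linalg.norm(seg, axis=1)
    keep = norms > 1e-12
    angles = np.full(len(seg), np.nan)
    for i in np.nonzero(keep)[0]:
        tangent = axis.tangent_at(float(mids[i, 2]))
        c = np.clip(np.dot(seg[i], tangent) / norms[i], -1.0, 1.0)
        angles[i] = fold_to_90(np.degrees(np.arccos(c)))
    return angles[keep], vox[keep]


def ground_truth_alpha_map(orient: OrientationField, axis: CentralAxis) -> np.ndarray:
    """Ground-truth pennation angle per voxel, from eps1 and the axis tangent."""
    shape = orient.eps1.shape[:3]
    out = np.full(shape, np.nan)
    for k, s in enumerate(axis.slices):
        e = orient.eps1[:, :, s]
        valid = np.isfinite(e[..., 0])
        t = axis.tangents[k]
        c = np.clip(np.einsum("rci,i->rc", e, t), -1.0, 1.0)
        a = fold_to_90(np.degrees(np.arccos(c)))
        out[:, :, s][valid] = a[valid]
    return out


def curvature_kappa(
    smoothed: SmoothedStreamline, voxel_dims_mm
) -> tuple[np.ndarray, float]:
    """Pointwise Frenet-Serret curvature of the fitted polynomials, in 1/m.

    kappa = |r' x r''| / |r'|^3 with analytic derivatives with respect to
    point number; coordinates are converted to mm so the result is
    parameterization-invariant.
    """
    if smoothed.unfitted:
        raise ValueError("curvature requires a fitted tract")
    n = len(smoothed.fitted_points)
    t = np.arange(n, dtype=float)
    dy, dx, dz = voxel_dims_mm
    scale = (dy, dx, dz)  # per (row, col, slice) coordinate
    d1 = np.empty((n, 3))
    d2 = np.empty((n, 3))
    for i in range(3):
        c = np.polynomial.polynomial.Polynomial(smoothed.coefficients[i] * scale[i])
        d1[:, i] = c.deriv(1)(t)
        d2[:, i] = c.deriv(2)(t)
    # (row, col, slice) mm components; cross/norm are basis-agnostic
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=1)
    keep = speed > 1e-9
    kappa_mm = np.linalg.norm(cross[keep], axis=1) / speed[keep] ** 3
    kappa = kappa_mm * 1000.0  # 1/mm -> 1/m
    return kappa, float(kappa.mean())


def gamma_beta(
    smoothed: SmoothedStreamline, alpha_mean_deg: float, voxel_dims_mm
) -> tuple[float, float]:
    """Aponeurosis angles for an APO-seeded tract.

    gamma is the elevation of the initial (first smoothed segment) fiber
    direction out of the local aponeurosis tangent plane: 90 deg minus the
    angle between that segment and the mesh normal at the seed vertex.
    beta = alpha - gamma.
    """
    if smoothed.raw.normal is None:
        raise ValueError("tract has no mesh association; gamma/beta undefined")
    pts_mm = to_mm(smoothed.fitted_points, voxel_dims_mm)  # xyz
    if len(pts_mm) < 2:
        raise ValueError("gamma requires at least 2 points")
    seg = pts_mm[1] - pts_mm[0]
    ang = angle_between_deg(seg, np.asarray(smoothed.raw.normal, dtype=float))
    gamma = 90.0 - float(fold_to_90(ang))
    return gamma, alpha_mean_deg - gamma


# ---------------------------------------------------------------------------
# batch records


@dataclass
class ArchitectureRecord:
    """Per-tract architecture summary."""

    tract_id: int
    length_mm: float
    alpha_mean_deg: float
    kappa_mean_per_m: float
    gamma_deg: Optional[float] = None
    beta_deg: Optional[float] = None


def quantify_tracts(
    smoothed: Sequence[SmoothedStreamline],
    axis: CentralAxis,
    voxel_dims_mm,
    with_gamma: bool = False,
) -> pd.DataFrame:
    """Quantify a batch of smoothed tracts into a tidy per-tract table.

    The seed point for the chord-based pennation angle is the tract's own
    seed for APO tracts and the innermost point (smallest in-plane distance
    to the central axis at its slice) for bidirectional tracts.
    """
    rows = []
    for i, sm in enumerate(smoothed):
        pts = sm.fitted_points
        if len(pts) < 2:
            continue
        L = tract_length(pts, voxel_dims_mm)
        if sm.raw.junction_index > 0:  # bidirectional: innermost end as seed
            seed = _innermost_point(pts, axis)
        else:
            seed = sm.raw.seed_point
        _, a_mean = pennation_alpha(pts, seed, axis, voxel_dims_mm)
        if sm.unfitted:
            k_mean = np.nan
        else:
            _, k_mean = curvature_kappa(sm, voxel_dims_mm)
        rec = {
            "tract_id": i,
            "length_mm": L,
            "alpha_mean_deg": a_mean,
            "kappa_mean_per_m": k_mean,
        }
        if with_gamma and sm.raw.normal is not None:
            g, b = gamma_beta(sm, a_mean, voxel_dims_mm)
            rec["gamma_deg"] = g
            rec["beta_deg"] = b
        rows.append(rec)
    return pd.DataFrame(rows)


def _innermost_point(points_vox: np.ndarray, axis: CentralAxis) -> np.ndarray:
    """Endpoint nearest the central axis in-plane (the fiber's origin end)."""
    ends = points_vox[[0, -1]]
    d = []
    for p in ends:
        s = float(p[2])
        i = int(np.clip(np.searchsorted(axis.slices, round_half_up(s)), 0, len(axis.slices) - 1))
        d.append(np.hypot(p[0] - axis.fitted_row[i], p[1] - axis.fitted_col[i]))
    return ends[int(np.argmin(d))]
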