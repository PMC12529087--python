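"""Deterministic streamline propagation, termination, trimming, filtering,
and polynomial smoothing.

Tracking is Euler integration of the first eigenvector field at a fixed
physical step of one in-plane voxel width, with nearest-voxel direction
lookup.  Steps are converted from mm to voxel coordinates by dividing each
component by the corresponding voxel dimension, so 6-mm slices advance by
1/6 voxel per 1-mm step along the slice axis.

Termination: leaving the muscle mask (boundary); FA outside the allowed
window (fa_window); the angle between the propagated segment and the second
segment preceding it exceeding the threshold on two consecutive points
(angle; the two offending points are removed); or the step-count safety
cap (max_steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._utils import round_half_up
from .phantom import LabelVolume
from .seeding import SeedSet
from .tensorfit import TensorVolume

__all__ = [
    "TrackOptions",
    "Streamline",
    "SmoothedStreamline",
    "propagate",
    "track_all",
    "trim_aponeurosis",
    "filter_tracts",
    "smooth",
]


@dataclass
class TrackOptions:
    """Tracking parameters.

    ``step_mm`` defaults to the in-plane voxel width at track time.
    FA window defaults are the simulation settings (0.1-0.4); in vivo
    tracking typically widens the lower bound to 0.05.
    """

    step_mm: Optional[float] = None
    fa_low: float = 0.1
    fa_high: float = 0.4
    angle_max_deg: float = 30.0
    max_steps: int = 1000
    interp: str = "nearest"  # or "trilinear" (direction lookup only)


@dataclass
class Streamline:
    """Raw fiber tract in continuous (row, col, slice) voxel coordinates.

    For bidirectional tracts ``junction_index`` is the position of the seed
    point inside ``points`` and ``termination_reasons`` holds the reasons
    for the (reverse, forward) branch ends; unidirectional tracts have a
    single reason.
    """

    points: np.ndarray  # (n, 3)
    seed_index: int
    seed_point: np.ndarray  # (3,)
    termination_reasons: tuple[str, ...]
    junction_index: int = 0
    mesh_index: Optional[tuple[int, int]] = None
    normal: Optional[np.ndarray] = None  # xyz mesh normal (APO)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SmoothedStreamline:
    """Polynomial-smoothed tract: per-coordinate coefficients vs point number.

    Coefficients are in ascending power order; ``fitted_points`` are the
    polynomials evaluated at the original point numbers.  ``unfitted`` is
    set when the tract had too few points to support the requested orders
    (the raw points are then passed through).
    """

    raw: Streamline
    coefficients: tuple[np.ndarray, np.ndarray, np.ndarray]
    fitted_points: np.ndarray  # (n, 3)
    polynomial_orders: tuple[int, int, int]
    unfitted: bool = False


def _interp_eps1(eps1: np.ndarray, point: np.ndarray) -> Optional[np.ndarray]:
    """Trilinear, sign-coherent interpolation of the direction field."""
    shape = eps1.shape[:3]
    base = np.floor(point).astype(int)
    frac = point - base
    acc = np.zeros(3)
    ref = None
    for dr in (0, 1):
        for dc in (0, 1):
            for ds in (0, 1):
                idx = (base[0] + dr, base[1] + dc, base[2] + ds)
                if not all(0 <= idx[i] < shape[i] for i in range(3)):
                    continue
                v = eps1[idx]
                if not np.all(np.isfinite(v)) or np.linalg.norm(v) < 1e-12:
                    continue
                if ref is None:
                    ref = v
                elif np.dot(v, ref) < 0:
                    v = -v
                w = (
                    (frac[0] if dr else 1 - frac[0])
                    * (frac[1] if dc else 1 - frac[1])
                    * (frac[2] if ds else 1 - frac[2])
                )
                acc += w * v
    n = np.linalg.norm(acc)
    return acc / n if n > 1e-12 else None


def _branch(
    seed_point: np.ndarray,
    first_voxel: tuple[int, int, int],
    tensors: TensorVolume,
    mask: np.ndarray,
    voxel_dims_mm,
    opts: TrackOptions,
    init_sign: float,
) -> tuple[list[np.ndarray], str]:
    """Track one branch; returns appended points (excluding seed) + reason."""
    dy, dx, dz = voxel_dims_mm
    step = opts.step_mm if opts.step_mm is not None else dx
    shape = mask.shape
    eps1 = tensors.eps1
    fa = tensors.fa

    cur = np.asarray(seed_point, dtype=float)
    vox = tuple(int(v) for v in first_voxel)
    pts: list[np.ndarray] = []
    seg_dirs: list[np.ndarray] = []  # unit directions in xyz mm space
    prev_dir = None
    streak = 0

    for k in range(opts.max_steps):
        e = np.asarray(eps1[vox], dtype=float)
        if not np.all(np.isfinite(e)) or np.linalg.norm(e) < 1e-12:
            return pts, "fa_window"
        if opts.interp == "trilinear" and k > 0:
            e_t = _interp_eps1(eps1, cur)
            if e_t is not None:
                e = e_t
        f = fa[vox]
        if not np.isfinite(f) or f < opts.fa_low or f > opts.fa_high:
            return pts, "fa_window"
        if prev_dir is None:
            if e[2] * init_sign < 0:
                e = -e
        elif np.dot(e, prev_dir) < 0:
            e = -e
        cand = cur + np.array([e[1] * step / dy, e[0] * step / dx, e[2] * step / dz])
        cvox = tuple(round_half_up(cand))
        if not (
            0 <= cvox[0] < shape[0] and 0 <= cvox[1] < shape[1] and 0 <= cvox[2] < shape[2]
        ) or not mask[cvox]:
            return pts, "boundary"
        # inter-segment angle: propagated segment vs second preceding segment
        if len(seg_dirs) >= 2:
            cosang = np.clip(np.dot(e, seg_dirs[-2]), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) > opts.angle_max_deg:
                streak += 1
                if streak >= 2:
                    if pts:
                        pts.pop()  # drop the first offending point
                    return pts, "angle"  # second offending point never appended
            else:
                streak = 0
        pts.append(cand)
        seg_dirs.append(e)
        prev_dir = e
        cur = cand
        vox = cvox
    return pts, "max_steps"


def propagate(
    seed_index: int,
    seeds: SeedSet,
    tensors: TensorVolume,
    labels: LabelVolume,
    opts: Optional[TrackOptions] = None,
    bidirectional: bool = False,
) -> Streamline:
    """Propagate one streamline from a seed.

    APO tracts run in the +Z direction only; VXL/EDGE tracts run both ways
    along +-eps1 and are concatenated with the reverse branch reversed (the
    duplicated seed point dropped once).
    """
    opts = opts or TrackOptions()
    seed_point = seeds.points[seed_index]
    if seeds.lookup_voxels is None or seeds.lookup_voxels[seed_index][0] < 0:
        raise ValueError(f"seed {seed_index} has no valid lookup voxel")
    first_voxel = tuple(seeds.lookup_voxels[seed_index])
    mask = labels.muscle_mask
    mesh_idx = tuple(seeds.mesh_index[seed_index]) if seeds.mesh_index is not None else None
    normal = seeds.normals[seed_index] if seeds.normals is not None else None

    fwd, fwd_reason = _branch(
        seed_point, first_voxel, tensors, mask, labels.voxel_dims_mm, opts, +1.0
    )
    if not bidirectional:
        points = np.vstack([seed_point[None, :]] + [p[None, :] for p in fwd]) if fwd else seed_point[None, :].copy()
        return Streamline(
            points=points,
            seed_index=seed_index,
            seed_point=np.asarray(seed_point, dtype=float),
            termination_reasons=(fwd_reason,),
            junction_index=0,
            mesh_index=mesh_idx,
            normal=normal,
        )
    rev, rev_reason = _branch(
        seed_point, first_voxel, tensors, mask, labels.voxel_dims_mm, opts, -1.0
    )
    parts = [p[None, :] for p in reversed(rev)] + [np.asarray(seed_point, dtype=float)[None, :]] + [
        p[None, :] for p in fwd
    ]
    return Streamline(
        points=np.vstack(parts),
        seed_index=seed_index,
        seed_point=np.asarray(seed_point, dtype=float),
        termination_reasons=(rev_reason, fwd_reason),
        junction_index=len(rev),
        mesh_index=mesh_idx,
        normal=normal,
    )


def track_all(
    seeds: SeedSet,
    tensors: TensorVolume,
    labels: LabelVolume,
    opts: Optional[TrackOptions] = None,
) -> list[Streamline]:
    """Track every non-skipped seed; APO unidirectional, VXL/EDGE bidirectional."""
    bidir = seeds.scheme in ("VXL", "EDGE")
    out = []
    for i in range(len(seeds)):
        if seeds.skipped is not None and seeds.skipped[i]:
            continue
        out.append(propagate(i, seeds, tensors, labels, opts, bidirectional=bidir))
    return out


def trim_aponeurosis(tract: Streamline, aponeurosis_mask: np.ndarray) -> Streamline:
    """Remove up to four innermost points that lie inside the aponeurosis.

    The innermost point is the tract point nearest the aponeurosis (by
    voxel membership scanning outward from the seed junction on each
    branch); at most four points are removed in total.
    """
    pts = tract.points
    if len(pts) == 0:
        return tract
    vox = round_half_up(pts)
    shape = aponeurosis_mask.shape
    inside = np.zeros(len(pts), dtype=bool)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    inside[ok] = aponeurosis_mask[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
    if not inside.any():
        return tract
    j = int(np.clip(tract.junction_index, 0, len(pts) - 1))
    remove = np.zeros(len(pts), dtype=bool)
    budget = 4
    # scan outward from the junction on each branch, stopping at the first
    # point outside the aponeurosis
    for idx_iter in (range(j, -1, -1), range(j + 1, len(pts))):
        for i in idx_iter:
            if budget == 0 or not inside[i]:
                break
            remove[i] = True
            budget -= 1
    if not remove.any():
        return tract
    kept = ~remove
    new_pts = pts[kept]
    new_junction = int(np.clip(kept[: j + 1].sum() - 1, 0, max(len(new_pts) - 1, 0)))
    return Streamline(
        points=new_pts,
        seed_index=tract.seed_index,
        seed_point=tract.seed_point,
        termination_reasons=tract.termination_reasons,
        junction_index=new_junction,
        mesh_index=tract.mesh_index,
        normal=tract.normal,
    )


@dataclass
class FilterCriteria:
    """Tract exclusion thresholds; None disables a criterion."""

    min_length_mm: Optional[float] = 5.0
    max_alpha_deg: Optional[float] = None
    max_kappa_per_m: Optional[float] = None


def filter_tracts(
    tracts: Sequence,
    lengths_mm: np.ndarray,
    criteria: FilterCriteria,
    alphas_deg: Optional[np.ndarray] = None,
    kappas_per_m: Optional[np.ndarray] = None,
) -> tuple[list, np.ndarray, dict[str, int]]:
    """Drop tracts failing any enabled criterion.

    Returns (kept tracts, kept index array, per-criterion removal counts).
    A tract failing several criteria is counted under each.
    """
    n = len(tracts)
    bad = np.zeros(n, dtype=bool)
    counts = {}
    if criteria.min_length_mm is not None:
        hit = np.asarray(lengths_mm) < criteria.min_length_mm
        counts["min_length"] = int(hit.sum())
        bad |= hit
    if criteria.max_alpha_deg is not None and alphas_deg is not None:
        hit = np.asarray(alphas_deg) > criteria.max_alpha_deg
        counts["max_alpha"] = int(hit.sum())
        bad |= hit
    if criteria.max_kappa_per_m is not None and kappas_per_m is not None:
        hit = np.asarray(kappas_per_m) > criteria.max_kappa_per_m
        counts["max_kappa"] = int(hit.sum())
        bad |= hit
    keep_idx = np.nonzero(~bad)[0]
    return [tracts[i] for i in keep_idx], keep_idx, counts


def smooth(
    tract: Streamline, orders: tuple[int, int, int] = (2, 2, 3)
) -> SmoothedStreamline:
    """Least-squares polynomial fit of each coordinate vs point number.

    Row, column, and slice coordinates get independent polynomial orders
    (default 2, 2, 3).  Tracts with too few points pass through unfitted
    with a warning.
    """
    n = len(tract.points)
    t = np.arange(n, dtype=float)
    if n <= max(orders):
        warnings.warn(f"tract with {n} points not smoothed (orders {orders})")
        coeffs = tuple(np.asarray(tract.points[:, i], dtype=float) for i in range(3))
        return SmoothedStreamline(
            raw=tract,
            coefficients=coeffs,  # placeholder; unfitted flag set
            fitted_points=tract.points.copy(),
            polynomial_orders=orders,
            unfitted=True,
        )
    coeffs = []
    fitted = np.empty_like(tract.points)
    for i, order in enumerate(orders):
        c = np.polynomial.polynomial.polyfit(t, tract.points[:, i], order)
        coeffs.append(c)
        fitted[:, i] = np.polynomial.polynomial.polyval(t, c)
    return SmoothedStreamline(
        raw=tract,
        coefficients=tuple(coeffs),
        fitted_points=fitted,
        polynomial_orders=orders,
    )
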