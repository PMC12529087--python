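"""Seed-point generation: aponeurosis mesh (APO), voxel (VXL), edge (EDGE).

APO seeding digitizes the muscle-aponeurosis boundary into a rows x cols
mesh of fractional-coordinate seed points.  Because rounding a boundary
point can land it inside the aponeurosis (where the mask is zero and no
diffusion direction is defined), each seed is resolved with the updated
lookup: round the slice coordinate, enumerate the four floor/ceil
combinations of the row and column coordinates, and take the in-muscle
candidate closest (in mm) to the seed as the voxel that supplies the
initial propagation direction.  The tract still originates at the seed
point itself.

VXL and EDGE place seeds at voxel centers: VXL on a regular in-plane grid
inside a once-eroded muscle mask, EDGE along the inner boundary layer of
the eroded muscle mask plus the muscle voxels adjacent to the aponeurosis.
Morphology is 2-D per slice with a 3 x 3 (8-connected) structuring element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from ._utils import round_half_up
from .phantom import LabelVolume

__all__ = ["ApoMesh", "SeedSet", "build_apo_mesh", "apo_seed_lookup", "apo_seeds", "vxl_seeds", "edge_seeds"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ApoMesh:
    """Seeding mesh on the muscle-aponeurosis boundary.

    ``vertices[i, j]`` is a continuous (row, col, slice) point; ``normals``
    are unit vectors in (x, y, z) mm space from the cross product of the
    local row- and column-direction mesh tangents.
    """

    vertices: np.ndarray  # (mesh_rows, mesh_cols, 3)
    normals: np.ndarray  # (mesh_rows, mesh_cols, 3), xyz

    @property
    def shape(self) -> tuple[int, int]:
        return self.vertices.shape[:2]


@dataclass
class SeedSet:
    """Ordered seed points for one scheme.

    ``points`` are continuous (row, col, slice) coordinates.  For APO,
    ``lookup_voxels`` holds the resolved in-muscle voxel per seed (-1 where
    skipped), ``mesh_index`` the originating mesh vertex, and ``normals``
    the mesh normal (xyz) per seed.  ``skipped`` flags seeds with no valid
    lookup; they are reported, never silently dropped.
    """

    scheme: str
    points: np.ndarray  # (n, 3) float
    lookup_voxels: Optional[np.ndarray] = None  # (n, 3) int
    skipped: Optional[np.ndarray] = None  # (n,) bool
    mesh_index: Optional[np.ndarray] = None  # (n, 2) int
    normals: Optional[np.ndarray] = None  # (n, 3) float, xyz

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_skipped(self) -> int:
        return 0 if self.skipped is None else int(self.skipped.sum())


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Arc-length-uniform resampling of a closed 2-D polyline to n points."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = total * np.arange(n) / n
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def _slice_boundary(apo_slice: np.ndarray, s: int, n_cols: int) -> np.ndarray:
    """Resampled boundary polyline of one aponeurosis slice."""
    if apo_slice.sum() == 1:
        raise ValueError(f"degenerate single-voxel aponeurosis at slice {s}")
    contours = measure.find_contours(apo_slice.astype(float), 0.5)
    if not contours:
        raise ValueError(f"no aponeurosis boundary found at slice {s}")
    poly = max(contours, key=len)[:-1]  # closed: drop repeated endpoint
    # consistent orientation (counterclockwise in row/col) and start point
    area = 0.5 * np.sum(
        poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1]
    )
    if area < 0:
        poly = poly[::-1]
    start = np.lexsort((poly[:, 1], poly[:, 0]))[0]
    poly = np.roll(poly, -start, axis=0)
    return _resample_closed(poly, n_cols)


def build_apo_mesh(
    labels: LabelVolume, mesh_rows: int, mesh_cols: int
) -> ApoMesh:
    """Digitize the aponeurosis boundary into a mesh_rows x mesh_cols mesh.

    Per slice containing aponeurosis, the boundary polyline is extracted
    (marching squares at the half-voxel level) and resampled to mesh_cols
    points; the per-slice polylines are then resampled along the slice
    direction to mesh_rows rows.
    """
    apo = labels.aponeurosis_mask
    slices = [s for s in range(apo.shape[2]) if apo[:, :, s].any()]
    if len(slices) < 2:
        raise ValueError("aponeurosis must span at least 2 slices")
    per_slice = np.stack(
        [_slice_boundary(apo[:, :, s], s, mesh_cols) for s in slices]
    )  # (n_slices, mesh_cols, 2)
    z = np.asarray(slices, dtype=float)
    z_targets = np.linspace(z[0], z[-1], mesh_rows)
    vertices = np.empty((mesh_rows, mesh_cols, 3))
    for j in range(mesh_cols):
        vertices[:, j, 0] = np.interp(z_targets, z, per_slice[:, j, 0])
        vertices[:, j, 1] = np.interp(z_targets, z, per_slice[:, j, 1])
        vertices[:, j, 2] = z_targets

    dy, dx, dz = labels.voxel_dims_mm
    vert_mm = np.stack(
        [vertices[..., 1] * dx, vertices[..., 0] * dy, vertices[..., 2] * dz],
        axis=-1,
    )  # xyz mm
    # row tangent: along slices (central differences, clamped at the ends)
    t_row = np.gradient(vert_mm, axis=0)
    # column tangent: along the closed boundary
    t_col = (np.roll(vert_mm, -1, axis=1) - np.roll(vert_mm, 1, axis=1)) / 2.0
    normals = np.cross(t_row, t_col)
    norm = np.linalg.norm(normals, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    normals = normals / norm
    return ApoMesh(vertices=vertices, normals=normals)


def apo_seed_lookup(
    seed: np.ndarray,
    muscle_mask: np.ndarray,
    aponeurosis_mask: np.ndarray,
    voxel_dims_mm,
) -> Optional[tuple[int, int, int]]:
    """Resolve the in-muscle voxel supplying a seed's initial direction.

    The slice coordinate is rounded (half up); the four floor/ceil row and
    column combinations are tested against the muscle mask in the fixed
    order (floor,floor), (floor,ceil), (ceil,floor), (ceil,ceil); among the
    in-muscle candidates the one nearest the seed in mm wins (ties broken
    by candidate order).  Returns None when no candidate is in muscle —
    the caller records the seed as skipped.
    """
    r, c, s = float(seed[0]), float(seed[1]), float(seed[2])
    si = int(round_half_up(s))
    shape = muscle_mask.shape
    if not (0 <= si < shape[2]):
        return None
    cands = []
    for ri in (int(np.floor(r)), int(np.ceil(r))):
        for ci in (int(np.floor(c)), int(np.ceil(c))):
            if (ri, ci) not in [(x[0], x[1]) for x in cands]:
                cands.append((ri, ci))
    dy, dx, dz = voxel_dims_mm
    best = None
    best_d = np.inf
    for ri, ci in cands:
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            continue
        if not muscle_mask[ri, ci, si]:
            continue
        d = np.sqrt(((ri - r) * dy) ** 2 + ((ci - c) * dx) ** 2 + ((si - s) * dz) ** 2)
        if d < best_d - 1e-15:
            best_d = d
            best = (ri, ci, si)
    return best


def apo_seeds(mesh: ApoMesh, labels: LabelVolume) -> SeedSet:
    """Resolve every mesh vertex into a seed with a lookup voxel.

    Vertices are ordered row-major.  Vertices with no in-muscle candidate
    are kept in the set but flagged as skipped.
    """
    nr, nc = mesh.shape
    pts = mesh.vertices.reshape(-1, 3)
    norms = mesh.normals.reshape(-1, 3)
    mesh_idx = np.stack(np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij"), axis=-1).reshape(-1, 2)
    lookup = np.full((len(pts), 3), -1, dtype=int)
    skipped = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        hit = apo_seed_lookup(p, labels.muscle_mask, labels.aponeurosis_mask, labels.voxel_dims_mm)
        if hit is None:
            skipped[i] = True
        else:
            lookup[i] = hit
    return SeedSet(
        scheme="APO",
        points=pts.copy(),
        lookup_voxels=lookup,
        skipped=skipped,
        mesh_index=mesh_idx,
        normals=norms.copy(),
    )


def _erode_per_slice(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.zeros_like(mask)
    for s in range(mask.shape[2]):
        if mask[:, :, s].any():
            out[:, :, s] = ndimage.binary_erosion(
                mask[:, :, s], structure=_STRUCT8, iterations=iterations
            )
    return out


def _dilate_per_slice(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.zeros_like(mask)
    for s in range(mask.shape[2]):
        if mask[:, :, s].any():
            out[:, :, s] = ndimage.binary_dilation(
                mask[:, :, s], structure=_STRUCT8, iterations=iterations
            )
    return out


def _voxel_seedset(scheme: str, voxels: np.ndarray) -> SeedSet:
    """Build a deterministically ordered (slice, row, col) voxel seed set."""
    if len(voxels) == 0:
        return SeedSet(scheme=scheme, points=np.empty((0, 3)))
    order = np.lexsort((voxels[:, 1], voxels[:, 0], voxels[:, 2]))
    voxels = voxels[order]
    return SeedSet(
        scheme=scheme,
        points=voxels.astype(float),
        lookup_voxels=voxels.astype(int),
        skipped=np.zeros(len(voxels), dtype=bool),
    )


def vxl_seeds(muscle_mask: np.ndarray, stride: int = 2) -> SeedSet:
    """Regularly spaced seeds inside the once-eroded muscle mask.

    Keeps voxels whose row and column indices are both multiples of
    ``stride``; every slice is seeded.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    eroded = _erode_per_slice(muscle_mask)
    if muscle_mask.any() and not eroded.any():
        warnings.warn("muscle mask vanished under erosion; empty seed set")
    keep = np.zeros_like(eroded)
    keep[::stride, ::stride, :] = True
    vox = np.argwhere(eroded & keep)
    return _voxel_seedset("VXL", vox)


def edge_seeds(muscle_mask: np.ndarray, aponeurosis_mask: np.ndarray) -> SeedSet:
    """Seeds along the inner edge of the eroded muscle mask and around the
    aponeurosis.

    The outer-boundary component is the once-eroded mask minus the
    twice-eroded mask; the aponeurosis component is the once-dilated
    aponeurosis mask intersected with the muscle mask.
    """
    eroded = _erode_per_slice(muscle_mask)
    if muscle_mask.any() and not eroded.any():
        warnings.warn("muscle mask vanished under erosion; empty seed set")
    ring = eroded & ~_erode_per_slice(muscle_mask, iterations=2)
    near_apo = _dilate_per_slice(aponeurosis_mask) & muscle_mask
    vox = np.argwhere(ring | near_apo)
    return _voxel_seedset("EDGE", vox)
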