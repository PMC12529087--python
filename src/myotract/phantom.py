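"""Synthetic bipennate-muscle phantom and diffusion-weighted image simulator.

The phantom is a stack of elliptical muscle cross-sections with a flat,
one-voxel-thick central aponeurosis sheet.  Muscle fibers project radially
away from the aponeurosis, with an elevation angle (theta) that increases
both with slice number and with in-plane distance from the aponeurosis, and
an azimuth (phi) given by the in-plane direction away from the nearest
aponeurosis voxel.  Each tissue voxel carries a diffusion tensor whose first
eigenvector is the local fiber direction; diffusion-weighted signals follow
the single-tensor Stejskal-Tanner model S = S0 * exp(-b * r' D r).

Coordinate convention: arrays are indexed (row, col, slice), 0-based, with
voxel centers at integer coordinates.  Vector components are ordered
(x, y, z) = (+col, +row, +slice).  Physical lengths use voxel_dims_mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "LabelVolume",
    "OrientationField",
    "EncodingScheme",
    "DWIStack",
    "build_geometry",
    "build_orientation_field",
    "tensor_from_orientation",
    "build_tensor_field",
    "make_encoding",
    "synthesize_dwi",
    "add_noise",
]


@dataclass
class PhantomSpec:
    """Parameters defining the simulated muscle and its acquisition.

    Defaults reproduce the reference simulation conditions: a 50 x 50 x 40
    grid at 1 x 1 x 6 mm resolution, 37 tissue slices (one proximal and two
    distal zero-padded slices), fiber elevation ramping over 66.4-82.0
    degrees, tensor eigenvalues (2.1, 1.6, 1.4) x 1e-3 mm^2/s, and a
    13-image encoding (one b=0 plus 12 directions at b = 475 s/mm^2).
    """

    grid_rows: int = 50
    grid_cols: int = 50
    grid_slices: int = 40
    inplane_mm: float = 1.0
    slice_mm: float = 6.0
    muscle_slices: int = 37
    first_muscle_slice: int = 1  # one proximal zero-padded slice
    semi_axes_start: tuple[float, float] = (8.0, 14.0)  # (row, col) voxels, proximal
    semi_axes_end: tuple[float, float] = (12.0, 20.0)  # distal
    apo_row_fraction: float = 0.75  # sheet spans this fraction of the ellipse row extent
    ellipse_semi_axes_schedule: Optional[Callable[[int], tuple[float, float]]] = None
    theta_min_deg: float = 66.4
    theta_max_deg: float = 82.0
    theta_weights: tuple[float, float] = (0.5, 0.5)  # (w_slice, w_distance)
    eigenvalues: tuple[float, float, float] = (2.1e-3, 1.6e-3, 1.4e-3)  # mm^2/s
    b_value: float = 475.0  # s/mm^2
    n_directions: int = 12
    rng_seed: int = 0

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        return (self.inplane_mm, self.inplane_mm, self.slice_mm)

    @property
    def muscle_slice_range(self) -> range:
        """0-based slice indices that contain tissue."""
        return range(self.first_muscle_slice, self.first_muscle_slice + self.muscle_slices)

    def semi_axes(self, slice_index: int) -> tuple[float, float]:
        """Ellipse semi-axes (row, col) in voxels for a tissue slice."""
        if self.ellipse_semi_axes_schedule is not None:
            return self.ellipse_semi_axes_schedule(slice_index)
        if self.muscle_slices <= 1:
            return self.semi_axes_start
        t = (slice_index - self.first_muscle_slice) / (self.muscle_slices - 1)
        a_r = self.semi_axes_start[0] + t * (self.semi_axes_end[0] - self.semi_axes_start[0])
        a_c = self.semi_axes_start[1] + t * (self.semi_axes_end[1] - self.semi_axes_start[1])
        return (a_r, a_c)

    def validate(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.grid_slices) <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.theta_min_deg < self.theta_max_deg:
            raise ValueError("theta_min_deg must be < theta_max_deg")
        lam = self.eigenvalues
        if not (lam[0] > lam[1] > lam[2] > 0):
            raise ValueError("eigenvalues must be strictly descending and positive")
        if self.muscle_slices < 0:
            raise ValueError("muscle_slices must be >= 0")
        if self.muscle_slices and (
            self.first_muscle_slice < 0
            or self.first_muscle_slice + self.muscle_slices > self.grid_slices
        ):
            raise ValueError("muscle slices do not fit inside the grid")
        if abs(sum(self.theta_weights) - 1.0) > 1e-9:
            raise ValueError("theta_weights must sum to 1")


@dataclass
class LabelVolume:
    """Binary tissue masks.  Muscle excludes the internal aponeurosis."""

    muscle_mask: np.ndarray
    aponeurosis_mask: np.ndarray
    voxel_dims_mm: tuple[float, float, float]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.muscle_mask | self.aponeurosis_mask

    @property
    def shape(self) -> tuple[int, ...]:
        return self.muscle_mask.shape


@dataclass
class OrientationField:
    """Per-voxel ground-truth fiber direction; NaN outside tissue.

    ``eps1`` has shape (rows, cols, slices, 3) with (x, y, z) components.
    """

    eps1: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray


@dataclass
class EncodingScheme:
    """Diffusion encoding: per-image b-value and unit direction.

    The first image is the non-diffusion-weighted (b = 0) image with a zero
    direction vector.
    """

    directions: np.ndarray  # (n_images, 3) incl. leading zero row
    b_values: np.ndarray  # (n_images,) s/mm^2, first entry 0

    @property
    def n_images(self) -> int:
        return len(self.b_values)

    def min_folded_angle_deg(self) -> float:
        """Smallest pairwise angle between directions after antipodal folding."""
        d = self.directions[self.b_values > 0]
        dots = np.abs(np.clip(d @ d.T, -1.0, 1.0))
        np.fill_diagonal(dots, 0.0)
        return float(np.degrees(np.arccos(dots.max())))


@dataclass
class DWIStack:
    """4-D diffusion-weighted signal array (rows x cols x slices x images)."""

    signals: np.ndarray
    S0: float = 1.0
    snr: float = np.inf


def build_geometry(spec: PhantomSpec) -> LabelVolume:
    """Build muscle and aponeurosis masks for the elliptical phantom.

    Muscle voxels are those whose center lies inside the slice's ellipse and
    outside the aponeurosis; the aponeurosis is a one-voxel-thick sheet at
    the grid mid-column, spanning all tissue slices.
    """
    spec.validate()
    shape = (spec.grid_rows, spec.grid_cols, spec.grid_slices)
    muscle = np.zeros(shape, dtype=bool)
    apo = np.zeros(shape, dtype=bool)
    cr, cc = spec.grid_rows // 2, spec.grid_cols // 2
    rows = np.arange(spec.grid_rows)[:, None]
    cols = np.arange(spec.grid_cols)[None, :]
    for s in spec.muscle_slice_range:
        a_r, a_c = spec.semi_axes(s)
        if cr - a_r < 0 or cr + a_r > spec.grid_rows - 1 or cc - a_c < 0 or cc + a_c > spec.grid_cols - 1:
            raise ValueError(f"ellipse exceeds grid at slice {s}")
        inside = ((rows - cr) / a_r) ** 2 + ((cols - cc) / a_c) ** 2 <= 1.0
        # central sheet, one voxel thick in the column direction; shorter than
        # the full ellipse so fibers fan radially around its ends (360 deg phi)
        sheet = inside & (cols == cc) & (np.abs(rows - cr) <= spec.apo_row_fraction * a_r)
        muscle[:, :, s] = inside & ~sheet
        apo[:, :, s] = sheet
    return LabelVolume(muscle, apo, spec.voxel_dims_mm)


def build_orientation_field(labels: LabelVolume, spec: PhantomSpec) -> OrientationField:
    """Assign the ground-truth fiber direction to every tissue voxel.

    For each muscle voxel, phi is the in-plane azimuth of the displacement
    from its nearest aponeurosis voxel (in the same slice), and theta ramps
    linearly from theta_min to theta_max with the weighted sum of the
    normalized slice index and the normalized in-plane distance from the
    aponeurosis.  Aponeurosis voxels get eps1 = (0, 0, 1) (collagen
    perpendicular to the slice plane).
    """
    shape = labels.shape
    theta = np.full(shape, np.nan)
    phi = np.full(shape, np.nan)
    eps1 = np.full(shape + (3,), np.nan)

    tissue_slices = [s for s in range(shape[2]) if labels.tissue_mask[:, :, s].any()]
    n_tissue = len(tissue_slices)
    w_s, w_d = spec.theta_weights
    t_min, t_max = spec.theta_min_deg, spec.theta_max_deg

    for k, s in enumerate(tissue_slices):
        msk = labels.muscle_mask[:, :, s]
        apo = labels.aponeurosis_mask[:, :, s]
        if msk.any() and not apo.any():
            raise ValueError(f"slice {s} has muscle voxels but no aponeurosis voxels")
        if not msk.any():
            if apo.any():
                eps1[:, :, s][apo] = (0.0, 0.0, 1.0)
                theta[:, :, s][apo] = 90.0
                phi[:, :, s][apo] = 0.0
            continue
        # nearest aponeurosis voxel per in-plane position (mm metric; the
        # in-plane voxel dims are isotropic so voxel units suffice)
        dist, (near_r, near_c) = ndimage.distance_transform_edt(
            ~apo, return_indices=True
        )
        rr, cc_idx = np.nonzero(msk)
        dr = (rr - near_r[rr, cc_idx]) * labels.voxel_dims_mm[0]
        dc = (cc_idx - near_c[rr, cc_idx]) * labels.voxel_dims_mm[1]
        phi_v = np.degrees(np.arctan2(dr, dc))  # dy = row displacement, dx = col
        d_mm = dist[rr, cc_idx] * labels.voxel_dims_mm[0]
        # min-max normalize so the slice's theta ramp spans its full range
        span = d_mm.max() - d_mm.min()
        d_hat = (d_mm - d_mm.min()) / span if span > 0 else np.zeros_like(d_mm)
        z_hat = k / (n_tissue - 1) if n_tissue > 1 else 0.0
        theta_v = t_min + (t_max - t_min) * (w_s * z_hat + w_d * d_hat)
        ct = np.cos(np.radians(theta_v))
        e = np.stack(
            [
                ct * np.cos(np.radians(phi_v)),
                ct * np.sin(np.radians(phi_v)),
                np.sin(np.radians(theta_v)),
            ],
            axis=-1,
        )
        theta[rr, cc_idx, s] = theta_v
        phi[rr, cc_idx, s] = phi_v
        eps1[rr, cc_idx, s] = e
        ar, ac = np.nonzero(apo)
        eps1[ar, ac, s] = (0.0, 0.0, 1.0)
        theta[ar, ac, s] = 90.0
        phi[ar, ac, s] = 0.0
    return OrientationField(eps1, theta, phi)


_Z = np.array([0.0, 0.0, 1.0])


def tensor_from_orientation(eps1: np.ndarray, eigenvalues) -> np.ndarray:
    """Construct the diffusion tensor D = E L E' from a fiber direction.

    eps3 = normalize(eps1 x z), eps2 = eps1 x eps3.  For eps1 parallel to
    the slice axis (aponeurosis voxels) this cross product degenerates; the
    eigenvector frame then falls back to the coordinate axes with eps1 = z.
    """
    e1 = np.asarray(eps1, dtype=float)
    if abs(np.linalg.norm(e1) - 1.0) > 1e-6:
        raise ValueError("eps1 must be unit length")
    lam = np.asarray(eigenvalues, dtype=float)
    c = np.cross(e1, _Z)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        E = np.column_stack([_Z, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])])
    else:
        e3 = c / nc
        e2 = np.cross(e1, e3)
        E = np.column_stack([e1, e2, e3])
    return E @ np.diag(lam) @ E.T


def build_tensor_field(orient: OrientationField, spec: PhantomSpec) -> np.ndarray:
    """Vectorized tensor construction over every tissue voxel.

    Returns a (rows, cols, slices, 3, 3) array, NaN outside tissue.
    """
    e1 = orient.eps1
    valid = np.isfinite(e1[..., 0])
    D = np.full(e1.shape[:3] + (3, 3), np.nan)
    v = e1[valid]  # (n, 3)
    lam = np.asarray(spec.eigenvalues)
    c = np.cross(v, _Z)
    nc = np.linalg.norm(c, axis=1)
    degen = nc < 1e-12
    e3 = np.empty_like(v)
    e3[~degen] = c[~degen] / nc[~degen, None]
    e2 = np.cross(v, e3)
    E = np.stack([v, e2, e3], axis=-1)  # columns eps1, eps2, eps3
    if degen.any():
        E[degen] = np.column_stack(
            [_Z, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
        )
    D[valid] = np.einsum("nij,j,nkj->nik", E, lam, E)
    return D


def _repulsion_energy(p: np.ndarray) -> float:
    """Electrostatic energy with antipodal symmetry."""
    n = len(p)
    e = 0.0
    for i in range(n):
        d1 = np.linalg.norm(p[i + 1 :] - p[i], axis=1)
        d2 = np.linalg.norm(p[i + 1 :] + p[i], axis=1)
        e += np.sum(1.0 / d1 + 1.0 / d2)
    return e


def make_encoding(
    n_directions: int = 12, b_value: float = 475.0, rng_seed: int = 0
) -> EncodingScheme:
    """Diffusion directions from electrostatic repulsion on the sphere.

    Minimizes the antipodally symmetric Coulomb energy by projected gradient
    descent from a seeded random start (best of a few restarts), so the
    scheme is deterministic for a given seed.  A b = 0 entry is prepended.
    """
    if n_directions < 6:
        raise ValueError("at least 6 directions are required to determine the tensor")
    if b_value < 0:
        raise ValueError("b_value must be non-negative")
    rng = np.random.default_rng(rng_seed)
    best = None
    best_e = np.inf
    for _ in range(3):
        p = rng.standard_normal((n_directions, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        step = 0.02
        for _ in range(3000):
            # pairwise separations to every charge and its antipode
            diff = p[:, None, :] - p[None, :, :]  # p_i - p_j
            summ = p[:, None, :] + p[None, :, :]  # p_i - (-p_j)
            n1 = np.linalg.norm(diff, axis=-1)
            n2 = np.linalg.norm(summ, axis=-1)
            np.fill_diagonal(n1, np.inf)  # no self-interaction
            np.fill_diagonal(n2, np.inf)  # self-antipode force is radial
            force = (diff / n1[..., None] ** 3).sum(axis=1) + (
                summ / n2[..., None] ** 3
            ).sum(axis=1)
            # keep only the tangential component, step, reproject
            force -= (force * p).sum(axis=1, keepdims=True) * p
            p = p + step * force
            p /= np.linalg.norm(p, axis=1, keepdims=True)
        e = _repulsion_energy(p)
        if e < best_e:
            best_e, best = e, p
    dirs = np.vstack([np.zeros(3), best])
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    return EncodingScheme(directions=dirs, b_values=bvals)


def synthesize_dwi(
    tensors: np.ndarray, scheme: EncodingScheme, tissue_mask: np.ndarray, S0: float = 1.0
) -> DWIStack:
    """Noise-free signals S = S0 * exp(-b * r' D r) per voxel and image.

    ``tensors`` is a (rows, cols, slices, 3, 3) field (NaN outside tissue);
    the background is set to zero.
    """
    if np.any(scheme.b_values < 0):
        raise ValueError("negative b-value")
    shape = tensors.shape[:3]
    n_img = scheme.n_images
    signals = np.zeros(shape + (n_img,))
    D = tensors[tissue_mask]  # (n, 3, 3)
    r = scheme.directions  # (m, 3)
    quad = np.einsum("mi,nij,mj->nm", r, D, r)
    signals[tissue_mask] = S0 * np.exp(-scheme.b_values[None, :] * quad)
    return DWIStack(signals=signals, S0=S0, snr=np.inf)


def add_noise(
    stack: DWIStack, snr: float, rng_seed: int, trial_index: int = 0, rician: bool = False
) -> DWIStack:
    """Add zero-mean Gaussian noise with sigma = S0/snr to every voxel.

    Each (rng_seed, trial_index) pair defines an independent substream so
    Monte-Carlo trials are reproducible and order-independent.  An infinite
    SNR returns the input unchanged.  The default is additive real-channel
    Gaussian noise; ``rician=True`` instead corrupts two quadrature
    channels and takes the magnitude.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return stack
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(rng_seed), spawn_key=(int(trial_index),))
    )
    sigma = stack.S0 / snr
    if rician:
        re = stack.signals + rng.normal(0.0, sigma, size=stack.signals.shape)
        im = rng.normal(0.0, sigma, size=stack.signals.shape)
        noisy = np.hypot(re, im)
    else:
        noisy = stack.signals + rng.normal(0.0, sigma, size=stack.signals.shape)
    return DWIStack(signals=noisy, S0=stack.S0, snr=snr)
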