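"""Per-voxel diffusion tensor estimation by weighted linear least squares.

Fits the log-linear single-tensor model ln S = ln S0 - b * r' D r with the
standard two-pass scheme: an ordinary least-squares pass, then a weighted
pass with weights equal to the squared predicted signals.  The fitted tensor
is eigendecomposed (sorted descending, first eigenvector sign-normalized to
a non-negative slice component) and fractional anisotropy is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIStack, EncodingScheme

__all__ = ["TensorVolume", "wls_fit", "fractional_anisotropy", "design_matrix"]


@dataclass
class TensorVolume:
    """Fitted tensor field with eigen-system and FA; NaN outside the mask.

    ``evecs`` columns are (eps1, eps2, eps3); ``evals`` are sorted
    descending.  ``valid_mask`` marks voxels fitted without signal clamping.
    """

    D: np.ndarray  # (R, C, S, 3, 3) mm^2/s
    evecs: np.ndarray  # (R, C, S, 3, 3)
    evals: np.ndarray  # (R, C, S, 3)
    fa: np.ndarray  # (R, C, S)
    valid_mask: np.ndarray  # (R, C, S) bool

    @property
    def eps1(self) -> np.ndarray:
        return self.evecs[..., :, 0]


def design_matrix(scheme: EncodingScheme) -> np.ndarray:
    """Log-linear design: columns (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    b = scheme.b_values
    gx, gy, gz = scheme.directions.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _tensor_from_params(beta: np.ndarray) -> np.ndarray:
    """Assemble symmetric tensors from (n, 7) parameter rows."""
    D = np.empty(beta.shape[:-1] + (3, 3))
    D[..., 0, 0] = beta[..., 1]
    D[..., 1, 1] = beta[..., 2]
    D[..., 2, 2] = beta[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = beta[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = beta[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = beta[..., 6]
    return D


def wls_fit(
    stack: DWIStack,
    scheme: EncodingScheme,
    mask: np.ndarray,
    signal_floor: float = 1e-6,
) -> TensorVolume:
    """Fit D in every masked voxel; returns tensors, eigen-system, and FA.

    Non-positive signals are clamped to ``signal_floor * S0`` and the voxel
    is flagged in ``valid_mask`` (fit still performed).  Raises if the
    encoding cannot determine the tensor.
    """
    X = design_matrix(scheme)
    if stack.signals.shape[-1] != len(scheme.b_values):
        raise ValueError("signal volume count does not match the encoding scheme")
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise ValueError("singular design: encoding scheme cannot determine the tensor")

    S = stack.signals[mask]  # (n, m)
    clamped = S <= 0
    S = np.where(clamped, signal_floor * stack.S0, S)
    y = np.log(S)

    # pass 1: OLS
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (n, 7)
    # pass 2: WLS, weights = squared predicted signals
    w = np.exp(2.0 * (beta @ X.T))  # (n, m)
    A = np.einsum("ki,nk,kj->nij", X, w, X)
    rhs = np.einsum("ki,nk,nk->ni", X, w, y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]

    Dv = _tensor_from_params(beta)
    evals_a, evecs_a = np.linalg.eigh(Dv)  # ascending
    evals_v = evals_a[:, ::-1]
    evecs_v = evecs_a[:, :, ::-1]
    # sign convention: eps1 has non-negative slice (z) component
    flip = evecs_v[:, 2, 0] < 0
    evecs_v[flip, :, 0] *= -1.0

    shape = mask.shape
    D = np.full(shape + (3, 3), np.nan)
    evecs = np.full(shape + (3, 3), np.nan)
    evals = np.full(shape + (3,), np.nan)
    fa = np.full(shape, np.nan)
    D[mask] = Dv
    evecs[mask] = evecs_v
    evals[mask] = evals_v
    fa[mask] = fractional_anisotropy(evals_v)
    valid = np.zeros(shape, dtype=bool)
    valid[mask] = ~clamped.any(axis=1)
    return TensorVolume(D=D, evecs=evecs, evals=evals, fa=fa, valid_mask=valid)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA of eigenvalue triples (last axis of length 3).

    FA = sqrt(1/2 * ((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / (l1^2+l2^2+l3^2)).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    scalar_in = lam.ndim == 1
    lam = np.atleast_2d(lam)
    ssq = (lam**2).sum(axis=-1)
    if np.any(ssq == 0):
        raise ValueError("FA undefined for all-zero eigenvalues")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    fa = np.sqrt(0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2) / ssq)
    return float(fa[0]) if scalar_in else fa
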