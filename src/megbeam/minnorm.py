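"""Non-adaptive minimum-norm inverses: weighted MN, dSPM and sLORETA.

The standard minimum-norm inverse is L^T (L L^T)^-1 applied to the data
(stored here column-per-orientation as W_r = G^-1 L_r with the Gram matrix
G = sum_r L_r L_r^T).  G is rank-deficient in general and must be
regularized before inversion; two options are provided:

* add a (scaled) sensor covariance — from subject data or room noise;
* Tikhonov loading with a constant scaled from the strength of the Gram
  matrix's off-diagonal elements.

dSPM divides each voxel's estimate by the projected sensor-noise power
sqrt(diag(W^T R_nn W)); sLORETA instead normalizes by the model resolution
block (L^T G^-1 L)^(1/2), which gives exactly zero localization bias for a
single noiseless source.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .beamformer import SpatialFilter, _solve_spd
from .forward import LeadField

__all__ = [
    "GramMatrix",
    "gram",
    "regularize_gram",
    "mn_weights",
    "dspm_weights",
    "sloreta_weights",
    "sloreta_power",
]


@dataclass(frozen=True)
class GramMatrix:
    """G = sum over voxels of L_r L_r^T (channels x channels), with a record
    of any regularization applied before inversion."""

    matrix: np.ndarray
    regularization: str = "none"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Gram matrix must be square")
        scale = np.abs(m).max()
        if scale > 0 and np.abs(m - m.T).max() > 1e-10 * scale:
            raise ValueError("Gram matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def condition_number(self) -> float:
        w = np.linalg.eigvalsh(self.matrix)
        return float(w.max() / w.min()) if w.min() > 0 else np.inf


def gram(leadfield: LeadField) -> GramMatrix:
    """Accumulate G = sum_r L_r L_r^T over VOI voxels in float64."""
    voi = leadfield.grid.voi_mask
    L = leadfield.gain[voi]  # (v, c, k)
    G = np.einsum("vck,vdk->cd", L, L)
    return GramMatrix(matrix=0.5 * (G + G.T))


def regularize_gram(
    G: GramMatrix,
    method: str = "tikhonov_offdiag",
    sensor_cov: np.ndarray | None = None,
    weight: float = 1.0,
) -> GramMatrix:
    """Regularize the Gram matrix before inversion.

    ``sensor_cov`` adds ``weight`` times a sensor covariance matrix
    (subject data or room noise; must be symmetric PSD).
    ``tikhonov_offdiag`` adds lambda*I with lambda = mean absolute
    off-diagonal element of G, so a diagonal G is left untouched.
    """
    if method == "sensor_cov":
        if sensor_cov is None:
            raise ValueError("sensor_cov regularization requires a covariance matrix")
        C = np.asarray(sensor_cov, dtype=np.float64)
        if C.shape != G.matrix.shape:
            raise ValueError("sensor covariance shape mismatch")
        if np.abs(C - C.T).max() > 1e-10 * max(np.abs(C).max(), 1e-300):
            raise ValueError("sensor covariance must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10 * max(np.abs(C).max(), 1e-300):
            raise ValueError("sensor covariance must be positive semidefinite")
        if weight == 0.0:
            return G
        return GramMatrix(
            matrix=G.matrix + weight * C,
            regularization=f"sensor_cov(weight={weight})",
        )
    if method == "tikhonov_offdiag":
        off = G.matrix - np.diag(np.diag(G.matrix))
        n = G.n_channels
        lam = np.abs(off).sum() / (n * (n - 1)) if n > 1 else 0.0
        if lam == 0.0:
            return G
        return GramMatrix(
            matrix=G.matrix + lam * np.eye(n),
            regularization=f"tikhonov_offdiag(lambda={lam:.3e})",
        )
    raise ValueError(f"unknown Gram regularization {method!r}")


def _check_invertible(G: GramMatrix):
    w = np.linalg.eigvalsh(G.matrix)
    if w.min() <= 0 or w.max() / w.min() > 1e14:
        raise np.linalg.LinAlgError(
            "Gram matrix is (near-)singular; regularize it first "
            "(regularize_gram with 'sensor_cov' or 'tikhonov_offdiag')"
        )


def mn_weights(leadfield: LeadField, G_reg: GramMatrix) -> SpatialFilter:
    """Weighted minimum-norm weights W_r = G^-1 L_r per voxel."""
    _check_invertible(G_reg)
    n_vox, nc, ncomp = leadfield.gain.shape
    GinvL = _solve_spd(
        G_reg.matrix, leadfield.gain.transpose(1, 0, 2).reshape(nc, -1)
    ).reshape(nc, n_vox, ncomp)
    W = GinvL.transpose(1, 0, 2).copy()
    W[~leadfield.grid.voi_mask] = 0.0
    return SpatialFilter(
        weights=W,
        channel_names=leadfield.channel_names,
        method="minimum_norm",
        params={"gram_regularization": G_reg.regularization},
        orientations=leadfield.orientations,
    )


def dspm_weights(
    leadfield: LeadField, G_reg: GramMatrix, R_nn: np.ndarray | None = None
):
    """dSPM: minimum-norm estimate noise-normalized per orientation.

    Each weight column w is divided by sqrt(w^T R_nn w), the sensor noise
    projected through the inverse.  ``R_nn`` defaults to the identity
    (flagged in the parameters); the classic choice is a measured
    room-noise covariance.  Returns ``(filter, noise_power_map)`` where
    the map holds the per-voxel, per-orientation noise power used.
    """
    base = mn_weights(leadfield, G_reg)
    nc = len(leadfield.channel_names)
    if R_nn is None:
        R = np.eye(nc)
        noise_src = "identity"
    else:
        R = np.asarray(R_nn, dtype=np.float64)
        if R.shape != (nc, nc):
            raise ValueError("R_nn shape mismatch")
        if np.abs(R - R.T).max() > 1e-10 * max(np.abs(R).max(), 1e-300):
            raise ValueError("R_nn must be symmetric")
        if np.linalg.eigvalsh(R).min() < -1e-10 * max(np.abs(R).max(), 1e-300):
            raise ValueError("R_nn must be positive semidefinite")
        noise_src = "supplied"
    # noise power per voxel & orientation: diag(W^T R_nn W)
    npow = np.einsum("vck,cd,vdk->vk", base.weights, R, base.weights)
    flagged = [int(v) for v in np.nonzero(np.any(npow <= 0, axis=1))[0]
               if leadfield.grid.voi_mask[v]]
    scale = np.where(npow > 0, 1.0 / np.sqrt(np.where(npow > 0, npow, 1.0)), 0.0)
    W = base.weights * scale[:, None, :]
    filt = replace(
        base,
        weights=W,
        method="dspm",
        params={**base.params, "noise_covariance": noise_src},
        flagged=tuple(flagged),
    )
    return filt, npow


def sloreta_weights(leadfield: LeadField, G_reg: GramMatrix):
    """sLORETA: minimum-norm estimate normalized by its resolution block.

    Per voxel the normalization is S_r^(-1/2) with S_r = L_r^T G^-1 L_r
    (the source-noise covariance under identity source power and identity
    sensor noise).  Returns ``(filter, flagged_voxels)``; voxels whose
    resolution block is not positive definite are flagged and zeroed.
    The resulting power map sum_k (w_k^T y)^2 peaks exactly at the true
    source for a single noiseless dipole.
    """
    _check_invertible(G_reg)
    n_vox, nc, ncomp = leadfield.gain.shape
    GinvL = _solve_spd(
        G_reg.matrix, leadfield.gain.transpose(1, 0, 2).reshape(nc, -1)
    ).reshape(nc, n_vox, ncomp)
    W = np.zeros_like(leadfield.gain)
    flagged = []
    for v in range(n_vox):
        if not leadfield.grid.voi_mask[v]:
            continue
        A = GinvL[:, v, :]  # G^-1 L_v
        S = leadfield.gain[v].T @ A
        S = 0.5 * (S + S.T)
        evals, evecs = np.linalg.eigh(S)
        if evals[-1] <= 0:
            flagged.append(v)
            continue
        # pseudo inverse sqrt: silent orientations (rank-2 spherical MEG
        # lead fields) are excluded from the normalization
        keep = evals > 1e-10 * evals[-1]
        if np.any(evals[keep] < 0):
            flagged.append(v)
            continue
        S_inv_sqrt = (evecs[:, keep] / np.sqrt(evals[keep])) @ evecs[:, keep].T
        W[v] = A @ S_inv_sqrt
    filt = SpatialFilter(
        weights=W,
        channel_names=leadfield.channel_names,
        method="sloreta",
        params={"gram_regularization": G_reg.regularization},
        flagged=flagged,
        orientations=leadfield.orientations,
    )
    return filt, flagged


def sloreta_power(filt: SpatialFilter, y: np.ndarray) -> np.ndarray:
    """sLORETA pseudo-power map for a sensor vector or (channels, samples)
    array: per voxel, the squared norm of the normalized estimate summed
    over samples."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    s = np.einsum("vck,cs->vks", filt.weights, y)
    return np.sum(s**2, axis=(1, 2))
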