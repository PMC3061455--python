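"""Adaptive spatial filters (beamformers).

The linearly constrained minimum-variance (LCMV) beamformer passes a
source at location r with unit gain while minimizing output variance, so
activity from everywhere else is adaptively suppressed:

    W_r = R^-1 L_r (L_r^T R^-1 L_r)^-1

with L_r the lead field at r and R the sensor covariance.  Stored
column-per-orientation; algebraically identical to the usual row form
W_r^T = (L_r^T R^-1 L_r)^-1 L_r^T R^-1.

Variants implemented here:

* eigenspace projection of the weights onto the signal subspace of the
  averaged-data covariance (stabilizes evoked reconstructions);
* minimum-eigenvalue regularization for averaged-data covariances
  (regularize with the smallest eigenvalue of the unaveraged covariance);
* coherent source suppression — an extra zero-gain constraint over a zone
  containing a temporally correlated interfering source;
* the source stability index — split-half correlation mapping that is
  high only at genuine evoked sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla

from .forward import LeadField
from .session import SessionData, TimeWindow, average_trials

__all__ = [
    "Covariance",
    "SpatialFilter",
    "SourceEstimate",
    "SuppressionZone",
    "compute_covariance",
    "regularize",
    "lcmv_weights",
    "scalar_orientation",
    "eigenspace_project",
    "suppression_weights",
    "suppression_scan",
    "source_stability_index",
    "apply_weights",
    "output_power",
]


@dataclass(frozen=True)
class Covariance:
    """Sensor covariance with provenance.

    ``mode`` records how it was estimated: ``"averaged"`` (covariance of
    the trial-averaged data) or ``"trials"`` (mean of per-trial sample
    covariances).  Channel means are removed per trial within the window.
    """

    matrix: np.ndarray
    window: TimeWindow | None = None
    band: tuple | None = None
    mode: str = "trials"
    n_samples_effective: int = 0
    channel_names: tuple = ()
    regularization: str = "none"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        scale = np.abs(m).max()
        if scale > 0 and np.abs(m - m.T).max() > 1e-12 * scale:
            raise ValueError("covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def condition_number(self) -> float:
        w = np.linalg.eigvalsh(self.matrix)
        w_min = w.min()
        if w_min <= 0:
            return np.inf
        return float(w.max() / w_min)


@dataclass(frozen=True)
class SpatialFilter:
    """Per-voxel sensor weights; applying them yields virtual electrodes.

    ``weights`` has shape (n_voxels, n_channels, n_comp) with n_comp = 3
    (vector) or 1 (scalar).  ``flagged`` lists voxels whose weights could
    not be computed (zeroed).
    """

    weights: np.ndarray
    channel_names: tuple
    method: str
    params: dict = field(default_factory=dict)
    flagged: tuple = ()
    orientations: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "flagged", tuple(int(i) for i in self.flagged))
        if w.ndim != 3:
            raise ValueError("weights must be (n_voxels, n_channels, n_comp)")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_comp(self) -> int:
        return self.weights.shape[2]


@dataclass(frozen=True)
class SourceEstimate:
    """Virtual-electrode time series: (n_trials, n_voxels, n_comp, n_samples)."""

    data: np.ndarray
    time: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def power(self) -> np.ndarray:
        """Per-voxel mean power over trials, orientations and samples, (A·m)^2."""
        return np.mean(np.sum(self.data**2, axis=2), axis=(0, 2))

    def scalar(self) -> np.ndarray:
        """Collapse orientations: Euclidean norm across components."""
        return np.linalg.norm(self.data, axis=2)


@dataclass(frozen=True)
class SuppressionZone:
    """Grid voxel indices of the region containing the interfering source."""

    voxels: tuple

    def __post_init__(self):
        object.__setattr__(self, "voxels", tuple(int(v) for v in self.voxels))


# ---------------------------------------------------------------------------
# covariance estimation and regularization
# ---------------------------------------------------------------------------

def compute_covariance(
    session: SessionData, window: TimeWindow, mode: str = "trials"
) -> Covariance:
    """Sensor covariance over ``window``.

    ``mode="averaged"`` takes the covariance of the trial-averaged data
    (appropriate for phase-locked/evoked analyses, but rank-deficient when
    the window is short); ``mode="trials"`` averages per-trial sample
    covariances (full rank, the estimate used for induced activity).
    Channel means are removed per trial within the window; the normalizer
    is the per-trial sample count.
    """
    if mode not in ("averaged", "trials"):
        raise ValueError(f"mode must be 'averaged' or 'trials', got {mode!r}")
    idx = window.indices(session.time)
    nc = session.n_channels
    if mode == "averaged":
        x = average_trials(session).data[0][:, idx]
        x = x - x.mean(axis=1, keepdims=True)
        n = x.shape[1]
        cov = (x @ x.T) / n
        if n < nc:
            import warnings

            warnings.warn(
                f"averaged-data covariance from {n} samples < {nc} channels is "
                "rank-deficient; consider regularization",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        n = len(idx)
        cov = np.zeros((nc, nc))
        for t in range(session.n_trials):
            x = session.data[t][:, idx]
            x = x - x.mean(axis=1, keepdims=True)
            cov += x @ x.T / n
        cov /= session.n_trials
    cov = 0.5 * (cov + cov.T)
    return Covariance(
        matrix=cov,
        window=window,
        mode=mode,
        n_samples_effective=int(n),
        channel_names=session.sensors.names,
    )


def regularize(
    cov: Covariance,
    method: str = "none",
    param: float = 0.0,
    unaveraged: Covariance | None = None,
) -> Covariance:
    """Regularize a covariance prior to inversion.

    ``tikhonov`` adds ``param * mean(diag(R)) * I``; ``min_eig`` adds the
    smallest eigenvalue of the *unaveraged*-data covariance times I — the
    recommended loading when inverting the ill-conditioned covariance of
    averaged (evoked) data.
    """
    if method == "none":
        return cov
    if method == "tikhonov":
        if param < 0:
            raise ValueError("tikhonov parameter must be >= 0")
        if param == 0.0:
            return cov
        lam = param * float(np.mean(np.diag(cov.matrix)))
        mat = cov.matrix + lam * np.eye(cov.n_channels)
        return replace(cov, matrix=mat, regularization=f"tikhonov({param})")
    if method == "min_eig":
        if unaveraged is None:
            raise ValueError(
                "min_eig regularization requires the unaveraged-data covariance"
            )
        lam = float(np.linalg.eigvalsh(unaveraged.matrix).min())
        mat = cov.matrix + lam * np.eye(cov.n_channels)
        return replace(cov, matrix=mat, regularization=f"min_eig({lam:.3e})")
    raise ValueError(f"unknown regularization method {method!r}")


# ---------------------------------------------------------------------------
# LCMV weights and variants
# ---------------------------------------------------------------------------

_COND_MAX = 1e12

#: relative eigenvalue cutoff for the per-voxel normalization inverse.
#: Spherical-conductor MEG lead fields are rank 2 (radial moments are
#: silent); directions whose eigenvalue falls below this fraction of the
#: largest are treated as unobservable and excluded from the constraint.
_RANK_TOL = 1e-10


def _pinv_psd(M: np.ndarray, rel_tol: float = _RANK_TOL):
    """Pseudo-inverse of a small symmetric PSD matrix with rank truncation.

    Returns ``(pinv, rank)``; eigenvalues below ``rel_tol * max`` are
    treated as a silent subspace (zeroed), so the unit-gain constraint is
    enforced only over observable source directions.
    """
    M = 0.5 * (M + M.T)
    evals, evecs = np.linalg.eigh(M)
    top = evals[-1]
    if top <= 0:
        return None, 0
    keep = evals > rel_tol * top
    inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    return inv, int(keep.sum())


def _solve_spd(R: np.ndarray, B: np.ndarray) -> np.ndarray:
    """R^-1 B via Cholesky, falling back to a symmetric solve."""
    try:
        c, low = sla.cho_factor(R, check_finite=False)
        return sla.cho_solve((c, low), B, check_finite=False)
    except np.linalg.LinAlgError:
        return sla.solve(R, B, assume_a="sym", check_finite=False)
    except sla.LinAlgError:
        return sla.solve(R, B, assume_a="sym", check_finite=False)


def lcmv_weights(leadfield: LeadField, cov: Covariance) -> SpatialFilter:
    """LCMV weights W_r = R^-1 L_r (L_r^T R^-1 L_r)^-1 for every voxel.

    Implemented with linear solves (no explicit inverses).  Voxels where
    L^T R^-1 L is numerically singular (e.g. at a conductor centre) are
    flagged and their weights zeroed; voxels outside the VOI are skipped.
    """
    if cov.n_channels != leadfield.n_channels:
        raise ValueError("covariance and lead field channel counts differ")
    n_vox, nc, ncomp = leadfield.gain.shape
    W = np.zeros_like(leadfield.gain)
    flagged = []
    RinvL = _solve_spd(
        cov.matrix, leadfield.gain.transpose(1, 0, 2).reshape(nc, -1)
    ).reshape(nc, n_vox, ncomp)
    for v in range(n_vox):
        if not leadfield.grid.voi_mask[v]:
            continue
        L = leadfield.gain[v]
        A = RinvL[:, v, :]  # R^-1 L_v
        M = L.T @ A  # L^T R^-1 L, (ncomp, ncomp)
        Minv, rank = _pinv_psd(M)
        if rank == 0:
            flagged.append(v)
            continue
        W[v] = A @ Minv
    return SpatialFilter(
        weights=W,
        channel_names=leadfield.channel_names,
        method="lcmv",
        params={"cov_mode": cov.mode, "regularization": cov.regularization},
        flagged=flagged,
        orientations=leadfield.orientations,
    )


def scalar_orientation(
    leadfield: LeadField, cov: Covariance, degeneracy_tol: float = 1e-8
):
    """Orientation-optimized scalar lead field.

    For each voxel, picks the unit orientation maximizing the beamformer
    output SNR under the unit-gain constraint: the dominant generalized
    eigenvector of the pencil (L^T R^-1 L, L^T R^-2 L), which maximizes
    (eta^T L^T R^-1 L eta)/(eta^T L^T R^-2 L eta) — the ratio of source
    power to projected white-noise power.  The solution is invariant to
    rescaling of R (both matrices scale).  The pencil is solved in the
    observable subspace of L (silent directions of a spherical conductor
    are excluded).  Sign is fixed so the first nonzero component is
    positive.

    Returns ``(scalar_leadfield, degenerate_voxels)``; voxels whose top
    two generalized eigenvalues coincide within ``degeneracy_tol``
    (relative) — e.g. a perfectly isotropic L^T R^-1 L — are resolved
    deterministically (dominant eigenvector as returned by the symmetric
    solver) and flagged.
    """
    if leadfield.form != "vector":
        raise ValueError("scalar_orientation expects a vector lead field")
    n_vox, nc, _ = leadfield.gain.shape
    ori = np.zeros((n_vox, 3))
    degenerate = []
    Lflat = leadfield.gain.transpose(1, 0, 2).reshape(nc, -1)
    RinvL = _solve_spd(cov.matrix, Lflat).reshape(nc, n_vox, 3)
    Rinv2L = _solve_spd(cov.matrix, RinvL.reshape(nc, -1)).reshape(nc, n_vox, 3)
    for v in range(n_vox):
        if not leadfield.grid.voi_mask[v]:
            ori[v] = (1.0, 0.0, 0.0)
            continue
        L = leadfield.gain[v]
        # observable subspace of the lead field
        M0 = L.T @ L
        evals0, evecs0 = np.linalg.eigh(M0)
        keep = evals0 > _RANK_TOL * max(evals0[-1], 1e-300)
        B = evecs0[:, keep]
        if B.shape[1] == 0:
            ori[v] = (1.0, 0.0, 0.0)
            degenerate.append(v)
            continue
        M1 = B.T @ (L.T @ RinvL[:, v, :]) @ B
        M2 = B.T @ (L.T @ Rinv2L[:, v, :]) @ B
        M1 = 0.5 * (M1 + M1.T)
        M2 = 0.5 * (M2 + M2.T)
        try:
            gev, gvec = sla.eigh(M1, M2, check_finite=False)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            degenerate.append(v)
            ori[v] = (1.0, 0.0, 0.0)
            continue
        if gev.size > 1 and (gev[-1] - gev[-2]) <= degeneracy_tol * max(
            abs(gev[-1]), 1e-300
        ):
            degenerate.append(v)
        eta = B @ gvec[:, -1]
        eta = eta / np.linalg.norm(eta)
        nz = np.nonzero(np.abs(eta) > 1e-12)[0]
        if nz.size and eta[nz[0]] < 0:
            eta = -eta
        ori[v] = eta
    from .forward import to_scalar

    return to_scalar(leadfield, ori), degenerate


def eigenspace_project(
    filt: SpatialFilter, cov_avg: Covariance, signal_rank: int
) -> SpatialFilter:
    """Project beamformer weights onto the signal subspace.

    The signal space E_s is spanned by the eigenvectors of the
    averaged-data covariance belonging to its ``signal_rank`` largest
    eigenvalues; projected weights are w_es = E_s E_s^T w.  Keeps the
    original covariance in the weight denominator (the projection acts on
    the finished weights), which focuses evoked reconstructions on the
    signal subspace and rejects noise-space leakage.
    """
    nc = len(filt.channel_names)
    if not (1 <= signal_rank <= nc):
        raise ValueError(f"signal_rank must be in [1, {nc}], got {signal_rank}")
    if cov_avg.n_channels != nc:
        raise ValueError("covariance channel count does not match filter")
    evals, evecs = np.linalg.eigh(cov_avg.matrix)
    Es = evecs[:, ::-1][:, :signal_rank]  # top eigenvectors
    proj = Es @ Es.T
    W = np.einsum("ij,vjk->vik", proj, filt.weights)
    return replace(
        filt,
        weights=W,
        method="eigenspace",
        params={**filt.params, "signal_rank": signal_rank},
    )


def _zone_basis(
    leadfield: LeadField, zone: SuppressionZone, energy: float = 0.99
) -> np.ndarray:
    """Orthonormal basis capturing ``energy`` of the zone's lead-field
    singular-value energy (left singular vectors)."""
    cols = np.concatenate([leadfield.gain[v] for v in zone.voxels], axis=1)
    U, s, _ = np.linalg.svd(cols, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("suppression zone has an all-zero lead field")
    cum = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(cum, energy) + 1)
    k = min(k, s.size)
    return U[:, :k]


def suppression_weights(
    leadfield: LeadField,
    cov: Covariance,
    zone: SuppressionZone,
    target_voxel: int,
    energy: float = 0.99,
) -> SpatialFilter:
    """Minimum-variance weights with unit gain at the target voxel and an
    exact null over the suppression zone.

    The constraint matrix is C = [L_target, U_zone] with U_zone the
    leading left singular vectors of the concatenated zone lead fields
    (retaining ``energy`` of their energy); the weights solve
    min w^T R w subject to C^T w = [I; 0].  An empty zone degenerates to
    plain LCMV at the target.
    """
    if not zone.voxels:
        lf_single = _single_voxel_leadfield(leadfield, target_voxel)
        w = lcmv_weights(lf_single, cov)
        return replace(w, method="suppression", params={**w.params, "zone": ()})
    if target_voxel in zone.voxels:
        raise ValueError("target voxel lies inside the suppression zone")
    L = leadfield.gain[target_voxel]  # (nc, ncomp)
    # constrain only the observable orientations of the target (a spherical
    # conductor's radial direction is silent and cannot carry unit gain)
    evals0, evecs0 = np.linalg.eigh(L.T @ L)
    keep = evals0 > _RANK_TOL * max(evals0[-1], 1e-300)
    if not keep.any():
        raise ValueError("target voxel has an all-zero lead field")
    L = L @ evecs0[:, keep]
    ncomp = L.shape[1]
    U = _zone_basis(leadfield, zone, energy)
    while True:
        C = np.concatenate([L, U], axis=1)
        RinvC = _solve_spd(cov.matrix, C)
        M = C.T @ RinvC
        cond = np.linalg.cond(M)
        if np.isfinite(cond) and cond < _COND_MAX:
            break
        if U.shape[1] == 0:
            raise ValueError("constraint matrix is rank-deficient even without zone")
        import warnings

        warnings.warn(
            "rank-deficient suppression constraints; dropping weakest zone "
            "direction",
            RuntimeWarning,
            stacklevel=2,
        )
        U = U[:, :-1]
    E = np.zeros((C.shape[1], ncomp))
    E[:ncomp, :ncomp] = np.eye(ncomp)
    W = RinvC @ np.linalg.solve(0.5 * (M + M.T), E)  # (nc, ncomp)
    weights = np.zeros((1, L.shape[0], ncomp))
    weights[0] = W
    return SpatialFilter(
        weights=weights,
        channel_names=leadfield.channel_names,
        method="suppression",
        params={
            "target": int(target_voxel),
            "zone": zone.voxels,
            "zone_rank": U.shape[1],
            "cov_mode": cov.mode,
        },
        orientations=None,
    )


def _single_voxel_leadfield(leadfield: LeadField, voxel: int) -> LeadField:
    from .forward import VoxelGrid

    grid = VoxelGrid(
        positions=leadfield.grid.positions[voxel][None, :],
        shape=(1, 1, 1),
        spacing=leadfield.grid.spacing,
        origin=leadfield.grid.positions[voxel],
        voi_mask=np.array([True]),
    )
    return LeadField(
        gain=leadfield.gain[voxel][None],
        grid=grid,
        channel_names=leadfield.channel_names,
        form=leadfield.form,
        orientations=None
        if leadfield.orientations is None
        else leadfield.orientations[voxel][None],
    )


def suppression_scan(
    leadfield: LeadField,
    cov: Covariance,
    zone: SuppressionZone,
    energy: float = 0.99,
    normalize: bool = True,
) -> np.ndarray:
    """Localization map over all non-zone VOI voxels with the zone nulled.

    Per voxel: output power trace(W^T R W), by default normalized by the
    projected noise power trace(W^T W) (neural activity index) to remove
    depth bias.  Zone voxels and voxels outside the VOI are NaN.  Used to
    localize a source whose temporally correlated partner sits inside the
    zone.
    """
    power = np.full(leadfield.n_voxels, np.nan)
    zone_set = set(zone.voxels)
    for v in range(leadfield.n_voxels):
        if v in zone_set or not leadfield.grid.voi_mask[v]:
            continue
        filt = suppression_weights(leadfield, cov, zone, v, energy)
        W = filt.weights[0]
        p = float(np.trace(W.T @ cov.matrix @ W))
        if normalize:
            n = float(np.trace(W.T @ W))
            power[v] = p / n if n > 0 else np.nan
        else:
            power[v] = p
    return power


def source_stability_index(
    session: SessionData,
    leadfield: LeadField,
    cov_trials: Covariance,
    n_splits: int = 20,
    seed: int | np.random.Generator = 0,
    window: TimeWindow | None = None,
) -> np.ndarray:
    """Split-half stability map for evoked sources, in [-1, 1].

    Scalar LCMV weights are computed once from the unaveraged-trials
    covariance.  For each of ``n_splits`` random divisions of the trials
    into two halves (the first half taking the extra trial when the count
    is odd), both half-averages are passed through the same weights and
    the two per-voxel time series are correlated; the index is the mean
    correlation over splits.  True phase-locked sources reproduce across
    halves (index near 1); noise does not.
    """
    if session.n_trials < 4:
        raise ValueError("source stability index requires at least 4 trials")
    if cov_trials.mode != "trials":
        raise ValueError("weights must come from the unaveraged-trials covariance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lf_scalar, _ = scalar_orientation(leadfield, cov_trials)
    filt = lcmv_weights(lf_scalar, cov_trials)
    data = session.data
    if window is not None:
        idx = window.indices(session.time)
        data = data[:, :, idx]
    nt = data.shape[0]
    n_half = nt // 2
    W = filt.weights[:, :, 0]  # (n_vox, nc)
    ssi = np.zeros(leadfield.n_voxels)
    for _ in range(n_splits):
        perm = rng.permutation(nt)
        first, second = perm[: nt - n_half], perm[nt - n_half :]
        avg1 = data[first].mean(axis=0)
        avg2 = data[second].mean(axis=0)
        s1 = W @ avg1  # (n_vox, samples)
        s2 = W @ avg2
        s1 = s1 - s1.mean(axis=1, keepdims=True)
        s2 = s2 - s2.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(s1, axis=1) * np.linalg.norm(s2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("vs,vs->v", s1, s2) / denom
        ssi += np.where(np.isfinite(r), r, 0.0)
    return ssi / n_splits


def apply_weights(
    filt: SpatialFilter, session: SessionData, window: TimeWindow | None = None
) -> SourceEstimate:
    """Apply spatial-filter weights to sensor data (virtual electrodes).

    The session's channels must contain every filter channel (matched by
    name, in order).  Returns per-trial, per-voxel source time series with
    one trace per weight component.
    """
    try:
        ch_idx = session.sensors.index(list(filt.channel_names))
    except KeyError as err:
        raise ValueError(f"session lacks filter channels: {err}") from err
    data = session.data[:, ch_idx, :]
    time = session.time
    if window is not None:
        idx = window.indices(session.time)
        data = data[:, :, idx]
        time = time[idx]
    # (trials, vox, comp, samples)
    out = np.einsum("vck,tcs->tvks", filt.weights, data)
    return SourceEstimate(data=out, time=time)


def output_power(filt: SpatialFilter, cov: Covariance) -> np.ndarray:
    """Beamformer output power per voxel: trace(W^T R W), (A·m)^2."""
    if cov.n_channels != filt.weights.shape[1]:
        raise ValueError("covariance does not match filter channels")
    p = np.einsum("vck,cd,vdk->v", filt.weights, cov.matrix, filt.weights)
    return p


def neural_activity_index(
    filt: SpatialFilter,
    cov: Covariance,
    noise_cov: np.ndarray | None = None,
    noise_filter: SpatialFilter | None = None,
) -> np.ndarray:
    """Output power normalized by projected noise power, per voxel.

    The raw minimum-variance output power is biased towards locations
    with weak lead fields (large weights amplify noise there); the neural
    activity index trace(W^T R W) / trace(W^T C_n W) removes that depth
    bias and is the standard localization functional for LCMV scans.
    ``noise_cov`` defaults to the identity (white sensor noise).

    ``noise_filter`` supplies the weights used in the denominator
    (defaults to ``filt``).  Signal-subspace-projected weights annihilate
    their own noise estimate, so eigenspace scans should normalize by the
    *unprojected* weights.  Voxels with zero weights give NaN.
    """
    p = output_power(filt, cov)
    wn = filt.weights if noise_filter is None else noise_filter.weights
    if wn.shape != filt.weights.shape:
        raise ValueError("noise_filter weights must match the filter's shape")
    if noise_cov is None:
        n = np.einsum("vck,vck->v", wn, wn)
    else:
        C = np.asarray(noise_cov, dtype=np.float64)
        n = np.einsum("vck,cd,vdk->v", wn, C, wn)
    with np.errstate(invalid="ignore", divide="ignore"):
        nai = np.where(n > 0, p / np.where(n > 0, n, 1.0), np.nan)
    return nai
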