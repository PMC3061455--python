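"""Within-subject and group statistics for source maps.

Within subject: an empirical threshold from the distribution of baseline
activity across trials, and Wilcoxon signed-rank Z maps contrasting active
against baseline time-frequency power.

Across subjects: resampling of per-subject maps onto a common grid,
voxelwise t/ANOVA maps, and statistical nonparametric mapping (SnPM) —
a pseudo-t statistic (voxel mean over sqrt of spatially smoothed variance)
whose null distribution is built from sign-flip permutations of the
subject maps; the maximum statistic over voxels and time windows, kept
separately per frequency band, yields family-wise-error corrected
p-values.  With N subjects there are exactly 2^N sign patterns; when that
exceeds the permutation budget, unique patterns (always including the
identity) are sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sstats

from .forward import VoxelGrid

__all__ = [
    "StatMap",
    "SnPMResult",
    "baseline_threshold",
    "wilcoxon_z",
    "wilcoxon_z_map",
    "resample_common_grid",
    "group_ttest",
    "group_anova",
    "smooth_variance_map",
    "sign_flip_patterns",
    "snpm",
]


@dataclass(frozen=True)
class StatMap:
    """A per-voxel (x window x band) statistic with optional thresholds/p."""

    statistic: np.ndarray
    name: str
    threshold: np.ndarray | float | None = None
    p: np.ndarray | None = None
    df: tuple | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p is not None:
            p = np.asarray(self.p, dtype=float)
            ok = np.isfinite(p)
            if np.any((p[ok] < 0) | (p[ok] > 1)):
                raise ValueError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class SnPMResult:
    """SnPM output: pseudo-t maps and the permutation max-statistic null.

    ``max_null`` / ``min_null`` have shape (n_perm, n_bands): the largest
    and smallest pseudo-t over voxels and windows per band and
    permutation.  The identity permutation is always included, so the
    smallest attainable corrected p is 1/n_perm.
    """

    pseudo_t: np.ndarray  # (vox, windows, bands)
    corrected_p: np.ndarray
    max_null: np.ndarray
    min_null: np.ndarray
    fwhm_mm: float
    n_perm: int
    exhaustive: bool
    seed: int | None
    two_sided: bool

    def threshold(self, alpha: float = 0.05) -> np.ndarray:
        """Per-band pseudo-t threshold at corrected level ``alpha``."""
        null = np.maximum(self.max_null, -self.min_null) if self.two_sided else self.max_null
        return np.quantile(null, 1 - alpha, axis=0)


# ---------------------------------------------------------------------------
# within-subject
# ---------------------------------------------------------------------------

def baseline_threshold(
    source_data: np.ndarray,
    time: np.ndarray,
    baseline,
    alpha: float = 0.05,
) -> StatMap:
    """Empirical within-subject threshold from baseline activity.

    ``source_data`` is (n_trials, n_voxels, n_samples) of source
    amplitude/power; the per-voxel null pools the baseline samples of all
    trials, the threshold is its (1 - alpha) quantile, and post-stimulus
    samples of the trial-averaged series exceeding it are flagged.  The
    baseline window must lie entirely before t = 0.
    """
    from .session import TimeWindow

    if not isinstance(baseline, TimeWindow):
        baseline = TimeWindow(*baseline)
    if baseline.stop > 0:
        raise ValueError("baseline window must end at or before stimulus onset")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    data = np.asarray(source_data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("source_data must be trials x voxels x samples")
    bidx = baseline.indices(time)
    null = data[:, :, bidx]  # (trials, vox, base-samples)
    pooled = null.transpose(1, 0, 2).reshape(data.shape[1], -1)
    if alpha >= 1.0:  # degenerate request: flag every post-stimulus sample
        thresh = np.full(data.shape[1], -np.inf)
    else:
        thresh = np.quantile(pooled, 1 - alpha, axis=1)
    post = time >= 0
    flags = data[:, :, post] > thresh[None, :, None]
    return StatMap(
        statistic=data.mean(axis=0),
        name="baseline_threshold",
        threshold=thresh,
        extra={
            "alpha": alpha,
            "flags_post": flags,
            "post_mask": post,
            "flagged_fraction": float(flags.mean()),
        },
    )


def wilcoxon_z(diff: np.ndarray) -> float:
    """Signed-rank Z for one vector of paired differences.

    Zeros are dropped; ties get midranks with the matching variance
    Var(W+) = sum(r_i^2)/4 (the tie-corrected normal approximation).  The
    sign of Z follows the direction of the typical change.
    """
    d = np.asarray(diff, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0
    ranks = sstats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    if sigma == 0:
        return 0.0
    return float((w_plus - mu) / sigma)


def wilcoxon_z_map(active: np.ndarray, baseline: np.ndarray) -> StatMap:
    """Wilcoxon signed-rank Z per cell for paired active vs baseline power.

    ``active`` and ``baseline`` are (n_pairs, ...) arrays of per-trial (or
    per-subject) power per voxel/window/band cell.  Requires >= 5 pairs
    for the normal approximation.
    """
    a = np.asarray(active, dtype=np.float64)
    b = np.asarray(baseline, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("active and baseline must have identical shapes")
    if a.shape[0] < 5:
        raise ValueError("need at least 5 pairs for the normal approximation")
    diff = a - b
    flat = diff.reshape(diff.shape[0], -1)
    z = np.array([wilcoxon_z(flat[:, j]) for j in range(flat.shape[1])])
    z = z.reshape(diff.shape[1:])
    p = 2.0 * sstats.norm.sf(np.abs(z))
    return StatMap(statistic=z, name="wilcoxon_z", p=p, df=(a.shape[0],))


# ---------------------------------------------------------------------------
# group maps
# ---------------------------------------------------------------------------

def resample_common_grid(
    values: np.ndarray, source_grid: VoxelGrid, target_grid: VoxelGrid
) -> np.ndarray:
    """Trilinear resampling of a per-voxel map onto a target grid.

    Both grids must share one coordinate frame (spatial normalization is
    assumed done).  Target voxels outside the source volume are NaN; fully
    disjoint volumes are an error.
    """
    vol = source_grid.to_volume(np.asarray(values, dtype=np.float64))
    rel = (target_grid.positions - source_grid.origin) / source_grid.spacing
    coords = rel.T  # (3, n_target) in voxel index units
    nx, ny, nz = source_grid.shape
    inside = (
        (rel[:, 0] >= 0) & (rel[:, 0] <= nx - 1)
        & (rel[:, 1] >= 0) & (rel[:, 1] <= ny - 1)
        & (rel[:, 2] >= 0) & (rel[:, 2] <= nz - 1)
    )
    if not inside.any():
        raise ValueError("target grid does not intersect the source volume")
    out = np.full(target_grid.n_voxels, np.nan)
    out[inside] = ndimage.map_coordinates(
        vol, coords[:, inside], order=1, mode="nearest"
    )
    return out


def group_ttest(maps: np.ndarray) -> StatMap:
    """One-sample t (against 0) across subjects, per cell.

    ``maps`` is (n_subjects, ...).  Zero-variance cells give NaN and are
    counted in ``extra['n_degenerate']``.
    """
    x = np.asarray(maps, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0)
    t = np.where(degenerate, np.nan, t)
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    return StatMap(
        statistic=t, name="t", p=p, df=(n - 1,),
        extra={"n_degenerate": int(degenerate.sum())},
    )


def group_anova(maps_by_condition) -> StatMap:
    """One-way ANOVA F across conditions, per cell.

    ``maps_by_condition`` is a sequence of (n_subjects_c, ...) arrays, one
    per condition (subject counts may differ)."""
    groups = [np.asarray(g, dtype=np.float64) for g in maps_by_condition]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 conditions")
    k = len(groups)
    ns = [g.shape[0] for g in groups]
    n_tot = sum(ns)
    grand = np.sum([g.sum(axis=0) for g in groups], axis=0) / n_tot
    ss_between = np.sum(
        [g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups], axis=0
    )
    ss_within = np.sum([((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups], axis=0)
    df1, df2 = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    degenerate = ss_within == 0
    F = np.where(degenerate, np.nan, F)
    p = sstats.f.sf(F, df1, df2)
    return StatMap(
        statistic=F, name="F", p=p, df=(df1, df2),
        extra={"n_degenerate": int(np.sum(degenerate))},
    )


# ---------------------------------------------------------------------------
# SnPM
# ---------------------------------------------------------------------------

def smooth_variance_map(
    var: np.ndarray, grid: VoxelGrid, fwhm_mm: float
) -> np.ndarray:
    """3-D Gaussian smoothing of a per-voxel variance map.

    The kernel FWHM is in millimetres, truncated at 4 sigma; NaN voxels
    are excluded from the kernel normalization (masked convolution) and
    stay NaN on output.
    """
    if fwhm_mm <= 0:
        return var.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / (grid.spacing * 1e3)
    vol = grid.to_volume(var)
    mask = np.isfinite(vol)
    filled = np.where(mask, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox, truncate=4.0)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox, truncate=4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(mask, num / den, np.nan)
    nx, ny, nz = grid.shape
    return sm.transpose(2, 1, 0).reshape(-1)


def sign_flip_patterns(n_subjects: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip patterns (n_used, N): exhaustive 2^N when affordable,
    otherwise unique sampled patterns always containing the identity."""
    total = 2**n_subjects
    if total <= n_perm:
        pats = np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
        # put the identity (all +1) first
        identity = np.nonzero((pats == 1.0).all(axis=1))[0][0]
        order = np.concatenate([[identity], np.delete(np.arange(total), identity)])
        return pats[order], True
    seen = {(1,) * n_subjects}
    pats = [np.ones(n_subjects)]
    while len(pats) < n_perm:
        p = tuple(int(s) for s in rng.choice((1, -1), size=n_subjects))
        if p in seen:
            continue
        seen.add(p)
        pats.append(np.array(p, dtype=float))
    return np.array(pats), False


def snpm(
    maps: np.ndarray,
    grid: VoxelGrid,
    fwhm_mm: float = 20.0,
    n_perm: int = 2**14,
    seed: int | None = 0,
    two_sided: bool = True,
    smooth_mean: bool = False,
) -> SnPMResult:
    """Statistical nonparametric mapping with sign-flip permutations.

    ``maps`` holds per-subject power-change maps, shape (N, n_voxels) or
    (N, n_voxels, n_windows, n_bands), already on a common grid.  The
    pseudo-t at each cell is mean / sqrt(smoothed variance / N), with the
    variance map smoothed in 3-D space per window and band.  For each
    sign-flip permutation the maximum (and minimum) pseudo-t over voxels
    and windows is recorded separately per band; the corrected p of a cell
    is the fraction of permutations whose band max reaches its pseudo-t
    (identity included, so p >= 1/n_perm).  Requires N >= 5 subjects.
    """
    x = np.asarray(maps, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None, None]
    if x.ndim != 4:
        raise ValueError("maps must be (N, voxels[, windows, bands])")
    N, nv, nw, nb = x.shape
    if N < 5:
        raise ValueError(
            f"SnPM needs at least 5 subjects for a useful permutation "
            f"distribution (got {N})"
        )
    if nv != grid.n_voxels:
        raise ValueError("maps do not match the grid")
    if fwhm_mm < grid.spacing * 1e3:
        import warnings

        warnings.warn(
            "smoothing FWHM below grid spacing has little effect",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    patterns, exhaustive = sign_flip_patterns(N, n_perm, rng)
    n_used = patterns.shape[0]

    sum_sq = np.sum(x**2, axis=0)  # invariant under sign flips

    def pseudo_t_for(signs: np.ndarray) -> np.ndarray:
        mean = np.tensordot(signs, x, axes=(0, 0)) / N  # (nv, nw, nb)
        var = (sum_sq - N * mean**2) / (N - 1)
        var = np.maximum(var, 0.0)
        out = np.empty_like(mean)
        for w in range(nw):
            for b in range(nb):
                svar = smooth_variance_map(var[:, w, b], grid, fwhm_mm)
                m = mean[:, w, b]
                if smooth_mean:
                    m = smooth_variance_map(m, grid, fwhm_mm)
                with np.errstate(divide="ignore", invalid="ignore"):
                    out[:, w, b] = m / np.sqrt(svar / N)
        return out

    t_obs = pseudo_t_for(patterns[0])
    max_null = np.empty((n_used, nb))
    min_null = np.empty((n_used, nb))
    for i in range(n_used):
        t_perm = t_obs if i == 0 else pseudo_t_for(patterns[i])
        flat = t_perm.reshape(nv * nw, nb)
        with np.errstate(invalid="ignore"):
            max_null[i] = np.nanmax(flat, axis=0)
            min_null[i] = np.nanmin(flat, axis=0)

    if two_sided:
        null = np.maximum(max_null, -min_null)  # per-perm max |pseudo-t|
        comp = np.abs(t_obs)
    else:
        null = max_null
        comp = t_obs
    # corrected p: fraction of permutations whose band max reaches the cell
    corrected = np.empty_like(comp)
    for b in range(nb):
        srt = np.sort(null[:, b])
        counts = n_used - np.searchsorted(srt, comp[:, :, b] - 1e-12, side="left")
        corrected[:, :, b] = counts / n_used
    corrected = np.minimum(corrected, 1.0)
    return SnPMResult(
        pseudo_t=t_obs,
        corrected_p=corrected,
        max_null=max_null,
        min_null=min_null,
        fwhm_mm=fwhm_mm,
        n_perm=n_used,
        exhaustive=exhaustive,
        seed=seed,
        two_sided=two_sided,
    )
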