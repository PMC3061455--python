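"""Time-frequency beamformer (TFBF).

For each frequency band the trials are band-pass filtered; for each active
time window a trials-mode covariance is estimated, regularized, and turned
into orientation-optimized scalar LCMV weights.  The per-voxel active
power w^T R_active w is contrasted against the power of the *same* weights
in a common control window of that band, giving source power change per
voxel x time window x frequency band — a 5-D navigable result when
combined with the spatial grid.

Cells of the window x band plan are independent, so they can be computed
as separate batch jobs and merged bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import h5py

from .beamformer import compute_covariance, lcmv_weights, regularize, scalar_orientation
from .forward import LeadField
from .session import SessionData, TimeWindow, bandpass

__all__ = [
    "TFPlan",
    "TFBeam",
    "tfbf_run",
    "tfbf_run_cell",
    "tfbf_split",
    "tfbf_merge",
    "tfbf_contrast",
    "save_tfbeam",
    "load_tfbeam",
]


@dataclass(frozen=True)
class TFPlan:
    """Window x band plan for the time-frequency beamformer.

    ``bands`` is a list of (lo, hi) Hz pairs; ``windows`` the active
    windows shared by all bands; ``control`` one control window per band
    (or a single window reused for every band).  Covariance estimation is
    fixed to trials mode; ``reg`` / ``reg_param`` configure Tikhonov
    loading applied identically to active and control covariances.
    """

    bands: tuple
    windows: tuple
    control: tuple
    reg: str = "tikhonov"
    reg_param: float = 0.05
    cond_max: float = 1e12

    def __post_init__(self):
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        windows = tuple(self.windows)
        control = self.control
        if isinstance(control, TimeWindow):
            control = (control,) * len(bands)
        control = tuple(control)
        if len(control) != len(bands):
            raise ValueError("need one control window per band")
        for lo, hi in bands:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "windows", windows)
        object.__setattr__(self, "control", control)

    def validate_against(self, session: SessionData) -> None:
        epoch = session.epoch
        for w in list(self.windows) + list(self.control):
            if w.start < epoch.start - 1e-9 or w.stop > epoch.stop + 1e-9:
                raise ValueError(
                    f"window [{w.start}, {w.stop}) outside epoch "
                    f"[{epoch.start}, {epoch.stop})"
                )
        for lo, hi in self.bands:
            if hi >= session.fs / 2:
                raise ValueError(f"band ({lo}, {hi}) exceeds Nyquist")
            if lo > 0:
                min_len = 2.0 / lo
                for w in self.windows:
                    if w.duration < min_len - 1e-9:
                        warnings.warn(
                            f"window [{w.start}, {w.stop}) shorter than two "
                            f"periods of {lo} Hz; covariance may be unstable",
                            RuntimeWarning,
                            stacklevel=2,
                        )

    @property
    def n_cells(self) -> int:
        return len(self.bands) * len(self.windows)


@dataclass(frozen=True)
class TFBeam:
    """Active and control source power, voxels x windows x bands, (A·m)^2.

    Control power is estimated once per band (common control window) and
    broadcast across that band's windows.  Cells that could not be
    computed (ill-conditioned covariance) hold NaN; ``n_missing`` counts
    them.
    """

    active: np.ndarray
    control: np.ndarray
    plan: TFPlan
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.active, dtype=np.float64)
        c = np.asarray(self.control, dtype=np.float64)
        if a.shape != c.shape or a.ndim != 3:
            raise ValueError("active/control must both be voxels x windows x bands")
        with np.errstate(invalid="ignore"):
            if np.nanmin(a, initial=0.0) < -1e-20 or np.nanmin(c, initial=0.0) < -1e-20:
                raise ValueError("source power must be non-negative")
        object.__setattr__(self, "active", a)
        object.__setattr__(self, "control", c)

    @property
    def n_missing(self) -> int:
        """Number of (window, band) cells with no computed value at all."""
        return int(np.isnan(self.active).all(axis=0).sum())


def _cell_powers(
    band_session: SessionData,
    leadfield: LeadField,
    plan: TFPlan,
    window: TimeWindow,
    control: TimeWindow,
):
    """Active/control power per voxel for one (window, band) cell.

    Weights come from the active-window trials covariance; the control
    covariance is regularized by the same rule and probed with the same
    weights.
    """
    cov_a = compute_covariance(band_session, window, mode="trials")
    cov_c = compute_covariance(band_session, control, mode="trials")
    cov_a = regularize(cov_a, plan.reg, plan.reg_param)
    cov_c = regularize(cov_c, plan.reg, plan.reg_param)
    if cov_a.condition_number() > plan.cond_max:
        return None, None
    lf_scalar, _ = scalar_orientation(leadfield, cov_a)
    filt = lcmv_weights(lf_scalar, cov_a)
    W = filt.weights[:, :, 0]  # (vox, nc)
    p_act = np.einsum("vc,cd,vd->v", W, cov_a.matrix, W)
    p_ctl = np.einsum("vc,cd,vd->v", W, cov_c.matrix, W)
    mask = leadfield.grid.voi_mask.copy()
    for v in filt.flagged:
        mask[v] = False
    p_act = np.where(mask, p_act, np.nan)
    p_ctl = np.where(mask, p_ctl, np.nan)
    return np.maximum(p_act, 0.0), np.maximum(p_ctl, 0.0)


def tfbf_run_cell(
    session: SessionData, leadfield: LeadField, plan: TFPlan, band_idx: int, win_idx: int
):
    """Compute a single (window, band) cell; returns (active, control) per voxel."""
    lo, hi = plan.bands[band_idx]
    band_session = bandpass(session, lo, hi)
    return _cell_powers(
        band_session, leadfield, plan, plan.windows[win_idx], plan.control[band_idx]
    )


def tfbf_run(session: SessionData, leadfield: LeadField, plan: TFPlan) -> TFBeam:
    """Run the full plan (all windows x bands) in deterministic cell order."""
    if session.is_average:
        raise ValueError("TFBF requires unaveraged multi-trial data")
    plan.validate_against(session)
    n_vox = leadfield.n_voxels
    nw, nb = len(plan.windows), len(plan.bands)
    active = np.full((n_vox, nw, nb), np.nan)
    control = np.full((n_vox, nw, nb), np.nan)
    for b in range(nb):
        lo, hi = plan.bands[b]
        band_session = bandpass(session, lo, hi)
        for w in range(nw):
            p_act, p_ctl = _cell_powers(
                band_session, leadfield, plan, plan.windows[w], plan.control[b]
            )
            if p_act is None:
                continue
            active[:, w, b] = p_act
            control[:, w, b] = p_ctl
    return TFBeam(active=active, control=control, plan=plan)


def tfbf_split(plan: TFPlan) -> list:
    """Job specs covering the plan exactly once: [(band_idx, win_idx), ...]."""
    return [(b, w) for b in range(len(plan.bands)) for w in range(len(plan.windows))]


def tfbf_merge(plan: TFPlan, n_voxels: int, cells: dict) -> TFBeam:
    """Assemble independently computed cells into a TFBeam.

    ``cells`` maps (band_idx, win_idx) -> (active, control) arrays.  Every
    plan cell must be present exactly once; duplicates and omissions are
    errors naming the offending (window, band).
    """
    expected = tfbf_split(plan)
    seen = set()
    active = np.full((n_voxels, len(plan.windows), len(plan.bands)), np.nan)
    control = np.full_like(active, np.nan)
    for key, value in cells.items():
        if tuple(key) in seen:
            raise ValueError(f"duplicate cell (band={key[0]}, window={key[1]})")
        seen.add(tuple(key))
    for b, w in expected:
        if (b, w) not in cells:
            raise ValueError(f"missing cell (band={b}, window={w})")
        p_act, p_ctl = cells[(b, w)]
        if p_act is not None:
            active[:, w, b] = p_act
            control[:, w, b] = p_ctl
    extra = set(map(tuple, cells)) - set(expected)
    if extra:
        raise ValueError(f"cells outside the plan: {sorted(extra)}")
    return TFBeam(active=active, control=control, plan=plan)


def tfbf_contrast(beam: TFBeam, kind: str = "percent") -> np.ndarray:
    """Active-vs-control contrast per cell.

    ``difference`` = A - C; ``percent`` = 100 (A - C)/C;
    ``dB`` = 10 log10(A/C); ``pseudoF`` = A/C.  Cells with zero control
    power are NaN (counted in the return's companion via ``np.isnan``).
    """
    A, C = beam.active, beam.control
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "difference":
            out = A - C
        elif kind == "percent":
            out = 100.0 * (A - C) / C
        elif kind == "dB":
            out = 10.0 * np.log10(A / C)
        elif kind == "pseudoF":
            out = A / C
        else:
            raise ValueError(f"unknown contrast type {kind!r}")
    if kind != "difference":
        out = np.where(C == 0, np.nan, out)
    return out


def save_tfbeam(beam: TFBeam, path) -> None:
    """Write a TFBeam container (s_active/s_control + window/band tables)."""
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "megbeam-tfbeam"
        f.create_dataset("s_active", data=beam.active, dtype="f8")
        f.create_dataset("s_control", data=beam.control, dtype="f8")
        f.create_dataset("bands", data=np.asarray(beam.plan.bands, dtype="f8"))
        f.create_dataset(
            "windows",
            data=np.asarray([(w.start, w.stop) for w in beam.plan.windows], dtype="f8"),
        )
        f.create_dataset(
            "control_windows",
            data=np.asarray([(w.start, w.stop) for w in beam.plan.control], dtype="f8"),
        )
        f.attrs["reg"] = beam.plan.reg
        f.attrs["reg_param"] = beam.plan.reg_param


def load_tfbeam(path) -> TFBeam:
    from .session import SchemaError

    with h5py.File(path, "r") as f:
        for ds in ("s_active", "s_control", "bands", "windows"):
            if ds not in f:
                raise SchemaError(f"TFBeam container missing '/{ds}'")
        plan = TFPlan(
            bands=[tuple(b) for b in f["bands"][()]],
            windows=[TimeWindow(*w) for w in f["windows"][()]],
            control=[TimeWindow(*w) for w in f["control_windows"][()]],
            reg=f.attrs.get("reg", "tikhonov"),
            reg_param=float(f.attrs.get("reg_param", 0.05)),
        )
        return TFBeam(active=f["s_active"][()], control=f["s_control"][()], plan=plan)
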