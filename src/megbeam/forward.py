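"""Forward models: volumetric source grids and lead fields.

MEG lead fields use the analytic field of a current dipole in a homogeneous
spherical conductor (Sarvas' formula): the external magnetic field depends
only on the sphere *centre*, not its radius, and radial dipoles are
externally silent.  An overlapping-spheres variant assigns each MEG channel
its own locally fitted sphere centre.  Scalp/intracranial EEG uses the
potential of a dipole in a semi-infinite homogeneous conductor (image
construction), average-referenced across electrodes.

A lead field stores, per source voxel, the sensor gain matrix for unit
dipoles along the coordinate axes (vector form, channels x 3) or along one
fixed orientation (scalar form, channels x 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py
import nibabel as nib
from scipy.optimize import least_squares

from .session import SensorArray

__all__ = [
    "MU0",
    "VoxelGrid",
    "SphereModel",
    "LocalSpheres",
    "LeadField",
    "fit_sphere",
    "fit_local_spheres",
    "dipole_field_sphere",
    "leadfield_meg_sphere",
    "dipole_potential_halfspace",
    "leadfield_eeg_halfspace",
    "to_scalar",
    "save_leadfield",
    "load_leadfield",
    "export_voi_mask_nifti",
    "read_coil_table",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A


@dataclass(frozen=True)
class VoxelGrid:
    """Regular volumetric grid of candidate source locations.

    ``positions`` are voxel centres in metres (head frame), ordered
    x-fastest, then y, then z.  ``voi_mask`` flags voxels inside the
    volume of interest; excluded voxels keep their slot so that maps stay
    addressable on the full lattice.
    """

    positions: np.ndarray
    shape: tuple
    spacing: float
    origin: np.ndarray
    voi_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "voi_mask", np.asarray(self.voi_mask, dtype=bool))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        n = int(np.prod(self.shape))
        if self.positions.shape != (n, 3):
            raise ValueError("positions must match grid shape (x-fastest order)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.voi_mask.shape != (n,):
            raise ValueError("voi_mask must have one flag per voxel")

    @classmethod
    def from_box(cls, bbox, spacing: float) -> "VoxelGrid":
        """Build a grid from a bounding box ((x0,x1),(y0,y1),(z0,z1)) in metres."""
        axes = [np.arange(lo, hi + spacing / 2, spacing) for lo, hi in bbox]
        nx, ny, nz = (len(a) for a in axes)
        # x-fastest ordering: index = ix + nx*(iy + ny*iz)
        zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
        return cls(
            positions=pos,
            shape=(nx, ny, nz),
            spacing=float(spacing),
            origin=origin,
            voi_mask=np.ones(pos.shape[0], dtype=bool),
        )

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def nearest(self, point) -> int:
        """Index of the voxel centre nearest to ``point`` (metres)."""
        d = np.linalg.norm(self.positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))

    def with_mask(self, mask) -> "VoxelGrid":
        mask = np.asarray(mask, dtype=bool)
        return VoxelGrid(self.positions, self.shape, self.spacing, self.origin, mask)

    def to_volume(self, values, fill=np.nan) -> np.ndarray:
        """Reshape a per-voxel vector into the (nx, ny, nz) volume."""
        values = np.asarray(values, dtype=float)
        vol = np.full(self.n_voxels, fill, dtype=float)
        vol[: values.size] = values
        nx, ny, nz = self.shape
        return vol.reshape(nz, ny, nx).transpose(2, 1, 0)

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to head-frame millimetres."""
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing * 1e3
        aff[:3, 3] = self.origin * 1e3
        return aff


@dataclass(frozen=True)
class SphereModel:
    """Single-sphere conductor: centre (metres) and radius (metres).

    The MEG field of a dipole inside a spherical conductor is independent
    of the radius; the radius is kept for VOI construction and EEG-style
    scaling.
    """

    centre: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=np.float64))
        if self.centre.shape != (3,):
            raise ValueError("centre must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class LocalSpheres:
    """Overlapping-spheres model: one sphere centre per MEG channel."""

    centres: dict  # channel name -> 3-vector (metres)

    def centre_for(self, name: str) -> np.ndarray:
        if name not in self.centres:
            raise KeyError(f"no local sphere for channel {name!r}")
        return np.asarray(self.centres[name], dtype=np.float64)


@dataclass(frozen=True)
class LeadField:
    """Per-voxel forward gain matrices.

    ``gain`` has shape (n_voxels, n_channels, 3) for the vector form or
    (n_voxels, n_channels, 1) for the scalar (orientation-constrained)
    form; scalar lead fields carry their per-voxel unit ``orientations``.
    Units: T per A·m (MEG) or V per A·m (EEG).
    """

    gain: np.ndarray
    grid: VoxelGrid
    channel_names: tuple
    form: str  # "vector" | "scalar"
    orientations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gain", np.asarray(self.gain, dtype=np.float64))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.form not in ("vector", "scalar"):
            raise ValueError("form must be 'vector' or 'scalar'")
        ncomp = 3 if self.form == "vector" else 1
        expected = (self.grid.n_voxels, len(self.channel_names), ncomp)
        if self.gain.shape != expected:
            raise ValueError(f"gain must have shape {expected}, got {self.gain.shape}")
        if self.form == "scalar":
            if self.orientations is None:
                raise ValueError("scalar lead field requires orientation vectors")
            object.__setattr__(
                self, "orientations", np.asarray(self.orientations, dtype=np.float64)
            )
            if self.orientations.shape != (self.grid.n_voxels, 3):
                raise ValueError("orientations must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite gains")

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]

    @property
    def n_comp(self) -> int:
        return self.gain.shape[2]


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

def fit_sphere(points) -> SphereModel:
    """Least-squares sphere through digitized headshape points.

    Minimizes sum((|p - c| - R)^2) with a linear (algebraic) initial fit
    refined by Gauss-Newton.  Requires >= 4 points spanning 3 dimensions.
    """
    p = np.asarray(points, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need at least 4 headshape points of dimension 3")
    centred = p - p.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-12 * max(1.0, np.abs(p).max())) < 3:
        raise ValueError("headshape points are coplanar or degenerate")
    # algebraic init: |p|^2 = 2 p.c + (R^2 - |c|^2)
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = np.sum(p**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = np.sqrt(max(sol[3] + c0 @ c0, 1e-12))

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    fit = least_squares(resid, np.concatenate([c0, [r0]]), method="lm")
    centre, radius = fit.x[:3], float(fit.x[3])
    return SphereModel(centre=centre, radius=abs(radius))


def fit_local_spheres(
    headshape_points, sensors: SensorArray, radius_m: float = 0.08
) -> LocalSpheres:
    """Fit one sphere per MEG channel from nearby headshape points.

    Each channel's sphere uses the headshape points within ``radius_m`` of
    the channel position (falling back to the global fit when too few
    points are close).
    """
    p = np.asarray(headshape_points, dtype=np.float64)
    global_fit = fit_sphere(p)
    centres = {}
    for name, pos, kind in zip(sensors.names, sensors.positions, sensors.kinds):
        if not kind.startswith("meg"):
            continue
        near = p[np.linalg.norm(p - pos, axis=1) <= radius_m]
        if near.shape[0] >= 10:
            try:
                centres[name] = fit_sphere(near).centre
                continue
            except ValueError:
                pass
        centres[name] = global_fit.centre
    return LocalSpheres(centres=centres)


# ---------------------------------------------------------------------------
# MEG: dipole in a homogeneous sphere
# ---------------------------------------------------------------------------

def dipole_field_sphere(r_sensor, r_dipole, q, centre=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Magnetic field (Tesla) at ``r_sensor`` of a current dipole ``q`` (A·m)
    at ``r_dipole`` inside a homogeneous spherical conductor.

    Analytic solution for the field outside a conducting sphere; the result
    is independent of the sphere radius and vanishes for radial dipole
    moments.  All positions in metres.
    """
    c = np.asarray(centre, dtype=np.float64)
    r = np.asarray(r_sensor, dtype=np.float64) - c
    r0 = np.asarray(r_dipole, dtype=np.float64) - c
    q = np.asarray(q, dtype=np.float64)
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    rn = np.linalg.norm(r)
    if a < 1e-12 or rn < 1e-12:
        raise ValueError("sensor coincides with dipole or sphere centre")
    F = a * (rn * a + rn**2 - r0 @ r)
    if abs(F) < 1e-300:
        raise ValueError("degenerate geometry (F = 0)")
    grad_F = (a**2 / rn + (a_vec @ r) / a + 2.0 * a + 2.0 * rn) * r - (
        a + 2.0 * rn + (a_vec @ r) / a
    ) * r0
    q_x_r0 = np.cross(q, r0)
    return MU0 / (4.0 * np.pi * F**2) * (F * q_x_r0 - (q_x_r0 @ r) * grad_F)


def _sarvas_gain_rows(sensor_pos, sensor_ori, voxels, centre) -> np.ndarray:
    """Gain (projected field per unit dipole along x, y, z) at one point
    sensor for many source voxels inside a sphere.  Returns (n_vox, 3)."""
    r = np.asarray(sensor_pos, float) - centre  # (3,)
    o = np.asarray(sensor_ori, float)
    r0 = np.asarray(voxels, float) - centre  # (V, 3)
    a_vec = r[None, :] - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r)
    ar = a_vec @ r
    F = a * (rn * a + rn**2 - r0 @ r)
    grad_F = (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r[None, :] - (
        a + 2.0 * rn + ar / a
    )[:, None] * r0
    # field for unit dipole e_k: B_k = c (F (e_k x r0) - ((e_k x r0).r) grad_F)
    # triple products: (e_k x r0).o = (r0 x o)_k and (e_k x r0).r = (r0 x r)_k
    ek_x_r0_dot_o = np.cross(r0, np.broadcast_to(o, r0.shape))  # (V, 3)
    r0_x_r = np.cross(r0, np.broadcast_to(r, r0.shape))  # (V, 3)
    coeff = MU0 / (4.0 * np.pi * F**2)
    gain = coeff[:, None] * (F[:, None] * ek_x_r0_dot_o - r0_x_r * (grad_F @ o)[:, None])
    return gain


def _channel_coils(sensors: SensorArray, name: str, pos, ori):
    """Integration points (positions, orientations, weights) for a channel."""
    if name in sensors.coil_weights:
        cpos, cori, w = sensors.coil_weights[name]
        return (
            np.atleast_2d(np.asarray(cpos, float)),
            np.atleast_2d(np.asarray(cori, float)),
            np.asarray(w, float),
        )
    return pos[None, :], ori[None, :], np.array([1.0])


def leadfield_meg_sphere(model, grid: VoxelGrid, sensors: SensorArray) -> LeadField:
    """Vector MEG lead field on ``grid`` for a sphere conductor model.

    ``model`` is a :class:`SphereModel` or :class:`LocalSpheres`; with
    local spheres, each channel's row is evaluated with that channel's own
    centre.  Gradiometers declared through ``sensors.coil_weights`` are
    summed over their weighted integration points.

    Voxels at a sphere centre (silent and unlocalizable) or outside a
    single-sphere conductor are excluded from the returned grid's
    ``voi_mask`` and get zero gain.
    """
    meg_names = sensors.pick("meg")
    if not meg_names:
        raise ValueError("sensor array has no MEG channels")
    idx = sensors.index(meg_names)
    n_vox = grid.n_voxels
    gain = np.zeros((n_vox, len(meg_names), 3))
    mask = grid.voi_mask.copy()

    if isinstance(model, SphereModel):
        centres = {n: model.centre for n in meg_names}
        rel = grid.positions - model.centre
        outside = np.linalg.norm(rel, axis=1) >= model.radius
        mask &= ~outside
    elif isinstance(model, LocalSpheres):
        centres = {n: model.centre_for(n) for n in meg_names}
    else:
        raise TypeError("model must be SphereModel or LocalSpheres")

    # voxels too close to any used sphere centre are silent -> excluded
    unique_centres = np.unique(np.array([centres[n] for n in meg_names]), axis=0)
    for c in unique_centres:
        at_centre = np.linalg.norm(grid.positions - c, axis=1) < 1e-6
        mask &= ~at_centre

    active = np.nonzero(mask)[0]
    for j, (name, ch_i) in enumerate(zip(meg_names, idx)):
        pos = sensors.positions[ch_i]
        ori = sensors.orientations[ch_i]
        cpos, cori, w = _channel_coils(sensors, name, pos, ori)
        centre = centres[name]
        for cp, co, cw in zip(cpos, cori, w):
            gain[active, j, :] += cw * _sarvas_gain_rows(
                cp, co, grid.positions[active], centre
            )

    return LeadField(
        gain=gain,
        grid=grid.with_mask(mask),
        channel_names=meg_names,
        form="vector",
        meta={"model": type(model).__name__},
    )


# ---------------------------------------------------------------------------
# EEG: dipole in a semi-infinite homogeneous conductor
# ---------------------------------------------------------------------------

def dipole_potential_halfspace(
    r_electrode, r_dipole, q, conductivity: float, boundary_z: float = 0.0
) -> float:
    """Potential (Volts) of a dipole in a semi-infinite conductor.

    The conductor occupies z < ``boundary_z`` with an insulating boundary
    at the plane; the boundary condition is satisfied by adding a mirror
    dipole whose normal moment component is flipped.
    """
    r = np.asarray(r_electrode, dtype=np.float64)
    s = np.asarray(r_dipole, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if s[2] >= boundary_z - 1e-12:
        raise ValueError("dipole must lie strictly below the boundary plane")
    mirror = np.array([1.0, 1.0, -1.0])
    s_img = s.copy()
    s_img[2] = 2 * boundary_z - s[2]
    q_img = q * mirror
    out = 0.0
    for src, mom in ((s, q), (s_img, q_img)):
        d = r - src
        dist = np.linalg.norm(d)
        if dist < 1e-12:
            raise ValueError("electrode coincides with (image) dipole")
        out += (mom @ d) / dist**3
    return out / (4.0 * np.pi * conductivity)


def leadfield_eeg_halfspace(
    grid: VoxelGrid,
    sensors: SensorArray,
    conductivity: float = 0.33,
    boundary_z: float = 0.0,
) -> LeadField:
    """Vector EEG lead field for the semi-infinite homogeneous conductor.

    Electrodes must lie on or above the boundary plane, sources strictly
    below it.  Columns are average-referenced across electrodes, matching
    the automatic average referencing applied to EEG data.  Conductivity in
    S/m (default 0.33, brain-like tissue).
    """
    eeg_names = [n for n, k in zip(sensors.names, sensors.kinds) if k == "eeg"]
    if not eeg_names:
        raise ValueError("sensor array has no EEG channels")
    idx = sensors.index(eeg_names)
    epos = sensors.positions[idx]
    if np.any(epos[:, 2] < boundary_z - 1e-9):
        raise ValueError("electrodes must lie on or above the boundary plane")
    below = grid.positions[:, 2] < boundary_z - 1e-12
    mask = grid.voi_mask & below

    gain = np.zeros((grid.n_voxels, len(eeg_names), 3))
    eye = np.eye(3)
    for v in range(grid.n_voxels):
        if not mask[v]:
            continue
        for k in range(3):
            for j in range(len(eeg_names)):
                gain[v, j, k] = dipole_potential_halfspace(
                    epos[j], grid.positions[v], eye[k], conductivity, boundary_z
                )
    # average reference: each column sums to zero over electrodes
    gain[mask] -= gain[mask].mean(axis=1, keepdims=True)
    return LeadField(
        gain=gain,
        grid=grid.with_mask(mask),
        channel_names=eeg_names,
        form="vector",
        meta={"model": "halfspace", "conductivity": conductivity},
    )


# ---------------------------------------------------------------------------
# form conversion and I/O
# ---------------------------------------------------------------------------

def to_scalar(lf: LeadField, orientations) -> LeadField:
    """Constrain a vector lead field to fixed per-voxel unit orientations."""
    if lf.form != "vector":
        raise ValueError("to_scalar expects a vector lead field")
    ori = np.asarray(orientations, dtype=np.float64)
    if ori.shape == (3,):
        ori = np.tile(ori, (lf.n_voxels, 1))
    norms = np.linalg.norm(ori, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("orientations must be nonzero")
    ori = ori / norms
    gain = np.einsum("vck,vk->vc", lf.gain, ori)[:, :, None]
    return LeadField(
        gain=gain,
        grid=lf.grid,
        channel_names=lf.channel_names,
        form="scalar",
        orientations=ori,
        meta=dict(lf.meta),
    )


def save_leadfield(lf: LeadField, path) -> None:
    """Write a lead field to HDF5 (groups /grid and /L)."""
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "megbeam-leadfield"
        f.attrs["schema_version"] = 1
        g = f.create_group("grid")
        g.create_dataset("positions", data=lf.grid.positions, dtype="f8")
        g.create_dataset("voi_mask", data=lf.grid.voi_mask.astype(np.uint8))
        g.attrs["shape"] = lf.grid.shape
        g.attrs["spacing"] = lf.grid.spacing
        g.attrs["origin"] = lf.grid.origin
        L = f.create_group("L")
        L.create_dataset("gain", data=lf.gain, dtype="f8")
        L.attrs["form"] = lf.form
        L.create_dataset(
            "channel_names",
            data=np.array(lf.channel_names, dtype=h5py.string_dtype()),
        )
        if lf.orientations is not None:
            L.create_dataset("orientations", data=lf.orientations, dtype="f8")


def load_leadfield(path, form: str | None = None) -> LeadField:
    """Read a lead field container; ``form`` asserts the expected form.

    Raises a ``ValueError`` when the declared form does not match the file
    contents, and :class:`~megbeam.session.SchemaError` for missing groups.
    """
    from .session import SchemaError

    with h5py.File(path, "r") as f:
        for group in ("grid", "L"):
            if group not in f:
                raise SchemaError(f"lead-field container missing group '/{group}'")
        g = f["grid"]
        grid = VoxelGrid(
            positions=g["positions"][()],
            shape=tuple(int(s) for s in g.attrs["shape"]),
            spacing=float(g.attrs["spacing"]),
            origin=np.asarray(g.attrs["origin"], dtype=float),
            voi_mask=g["voi_mask"][()].astype(bool),
        )
        L = f["L"]
        file_form = L.attrs["form"]
        if isinstance(file_form, bytes):
            file_form = file_form.decode()
        if form is not None and form != file_form:
            raise ValueError(
                f"lead field stored in {file_form!r} form, but {form!r} requested"
            )
        names = [
            n.decode() if isinstance(n, bytes) else n for n in L["channel_names"][()]
        ]
        gain = L["gain"][()]
        if gain.shape[0] != grid.n_voxels:
            raise ValueError("voxel count of gain does not match grid")
        return LeadField(
            gain=gain,
            grid=grid,
            channel_names=names,
            form=file_form,
            orientations=L["orientations"][()] if "orientations" in L else None,
        )


def export_voi_mask_nifti(grid: VoxelGrid, path) -> None:
    """Write the VOI mask as a NIfTI-1 volume (mm head frame) for inspection."""
    vol = grid.to_volume(grid.voi_mask.astype(np.float64), fill=0.0)
    nib.save(nib.Nifti1Image(vol, grid.affine()), str(path))


def read_coil_table(path) -> dict:
    """Read a plain-text gradiometer coil table.

    Each line: ``name px py pz ox oy oz weight`` (metres, unit orientation,
    signed weight); repeated names accumulate integration points.
    """
    coils: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(f"malformed coil-table line: {line!r}")
            name = parts[0]
            vals = [float(x) for x in parts[1:]]
            pos, ori, w = vals[0:3], vals[3:6], vals[6]
            coils.setdefault(name, ([], [], []))
            coils[name][0].append(pos)
            coils[name][1].append(ori)
            coils[name][2].append(w)
    return {
        name: (np.array(p), np.array(o), np.array(w))
        for name, (p, o, w) in coils.items()
    }
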