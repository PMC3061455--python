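"""Sensor-space data model and preprocessing primitives.

A recording session is a stack of epoched trials (trials x channels x
samples) together with the sampling rate, an epoch time axis referenced to
the stimulus trigger (t = 0 at stimulus onset), and the sensor geometry.
All quantities are SI internally: Tesla for MEG, Volts for EEG, metres for
positions, seconds for time.

Sessions round-trip losslessly through an HDF5 container (groups ``/data``,
``/sensors``, ``/meta``) and can be imported from MAT-file structures
exported by other analysis environments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import h5py
from scipy import signal as sps
from scipy.io import loadmat, savemat

__all__ = [
    "SensorArray",
    "SessionData",
    "TimeWindow",
    "SchemaError",
    "save_session",
    "load_session",
    "import_mat_session",
    "export_mat_session",
    "sensor_rms",
    "select_channels",
    "bandpass",
    "remove_baseline",
    "average_trials",
]

SCHEMA_VERSION = 1

#: channel kinds understood by the toolbox. ``ref`` marks auxiliary
#: reference channels (e.g. EMG for corticomuscular coherence) that carry
#: no forward model.
CHANNEL_KINDS = ("meg_mag", "meg_grad", "eeg", "ref")


class SchemaError(IOError):
    """Raised when an on-disk container is missing required groups."""


def _as_f64(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass(frozen=True)
class SensorArray:
    """Channel labels, positions and (for MEG) coil orientations.

    Parameters
    ----------
    names : list of str
        Unique channel labels.
    positions : (n, 3) array
        Channel positions in metres, head frame.
    orientations : (n, 3) array or None
        Unit coil normals for MEG channels; ignored (may be NaN) for EEG
        and reference channels.  ``None`` for a pure-EEG array.
    kinds : list of str
        Per-channel kind, each one of ``meg_mag``, ``meg_grad``, ``eeg``,
        ``ref``.
    coil_weights : dict, optional
        For gradiometers modelled as weighted sets of point magnetometers:
        maps channel name -> (positions (k,3), orientations (k,3),
        weights (k,)).  Channels absent from the dict are treated as single
        point sensors at ``positions``/``orientations``.
    """

    names: tuple
    positions: np.ndarray
    orientations: np.ndarray | None
    kinds: tuple
    coil_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "positions", _as_f64(self.positions))
        object.__setattr__(self, "kinds", tuple(str(k) for k in self.kinds))
        if self.orientations is not None:
            object.__setattr__(self, "orientations", _as_f64(self.orientations))
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("channel names must be unique")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        if len(self.kinds) != n:
            raise ValueError("one kind per channel required")
        for k in self.kinds:
            if k not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")
        if self.orientations is not None:
            if self.orientations.shape != (n, 3):
                raise ValueError("orientations must match channel count")
            for i, k in enumerate(self.kinds):
                if k.startswith("meg"):
                    nrm = np.linalg.norm(self.orientations[i])
                    if abs(nrm - 1.0) > 1e-9:
                        raise ValueError(
                            f"MEG orientation of {self.names[i]!r} not unit-norm "
                            f"(|o| = {nrm})"
                        )
        elif any(k.startswith("meg") for k in self.kinds):
            raise ValueError("MEG channels require coil orientations")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, names) -> np.ndarray:
        """Indices of ``names`` in this array; unknown names raise."""
        lookup = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"unknown channel name(s): {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset(self, keep) -> "SensorArray":
        idx = self.index(keep)
        return SensorArray(
            names=[self.names[i] for i in idx],
            positions=self.positions[idx],
            orientations=None if self.orientations is None else self.orientations[idx],
            kinds=[self.kinds[i] for i in idx],
            coil_weights={n: self.coil_weights[n] for n in keep if n in self.coil_weights},
        )

    def pick(self, kind_prefix: str) -> list:
        """Channel names whose kind starts with ``kind_prefix`` (e.g. 'meg')."""
        return [n for n, k in zip(self.names, self.kinds) if k.startswith(kind_prefix)]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval [start, stop) in seconds relative to trigger."""

    start: float
    stop: float

    def __post_init__(self):
        if not (self.start < self.stop):
            raise ValueError(f"need start < stop, got [{self.start}, {self.stop})")

    def mask(self, time: np.ndarray) -> np.ndarray:
        return (time >= self.start) & (time < self.stop)

    def indices(self, time: np.ndarray) -> np.ndarray:
        idx = np.nonzero(self.mask(time))[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{self.start}, {self.stop}) contains no samples of the epoch"
            )
        return idx

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class SessionData:
    """Multi-trial sensor recording.

    ``data`` has shape (n_trials, n_channels, n_samples); ``time`` is the
    shared epoch time axis with t = 0 at stimulus onset and uniform step
    1/fs.  ``is_average`` marks a session whose single "trial" is a trial
    average.
    """

    data: np.ndarray
    fs: float
    time: np.ndarray
    sensors: SensorArray
    is_average: bool = False

    def __post_init__(self):
        object.__setattr__(self, "data", _as_f64(self.data))
        object.__setattr__(self, "time", _as_f64(self.time))
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        nt, nc, ns = self.data.shape
        if nc != self.sensors.n_channels:
            raise ValueError(
                f"data has {nc} channels but sensor array has "
                f"{self.sensors.n_channels}"
            )
        if self.time.shape != (ns,):
            raise ValueError("time axis length must match sample count")
        if ns >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(steps * self.fs - 1.0)) > 1e-9 * max(1.0, self.fs):
                raise ValueError("time step must equal 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch(self) -> TimeWindow:
        return TimeWindow(float(self.time[0]), float(self.time[-1]) + 1.0 / self.fs)

    def replace(self, **kw) -> "SessionData":
        return dataclasses.replace(self, **kw)

    def crop(self, window: TimeWindow) -> "SessionData":
        idx = window.indices(self.time)
        return self.replace(data=self.data[:, :, idx], time=self.time[idx])


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_session(session: SessionData, path) -> None:
    """Write a session to the HDF5 container (float64, lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["container"] = "megbeam-session"
        g = f.create_group("data")
        g.create_dataset("y", data=session.data, dtype="f8")
        g.create_dataset("time", data=session.time, dtype="f8")
        s = f.create_group("sensors")
        s.create_dataset(
            "names", data=np.array(session.sensors.names, dtype=h5py.string_dtype())
        )
        s.create_dataset("positions", data=session.sensors.positions, dtype="f8")
        if session.sensors.orientations is not None:
            s.create_dataset(
                "orientations", data=session.sensors.orientations, dtype="f8"
            )
        s.create_dataset(
            "kinds", data=np.array(session.sensors.kinds, dtype=h5py.string_dtype())
        )
        if session.sensors.coil_weights:
            cg = s.create_group("coils")
            for name, (pos, ori, w) in session.sensors.coil_weights.items():
                sub = cg.create_group(name)
                sub.create_dataset("positions", data=_as_f64(pos), dtype="f8")
                sub.create_dataset("orientations", data=_as_f64(ori), dtype="f8")
                sub.create_dataset("weights", data=_as_f64(w), dtype="f8")
        m = f.create_group("meta")
        m.attrs["fs"] = float(session.fs)
        m.attrs["is_average"] = bool(session.is_average)


def load_session(path) -> SessionData:
    """Read a session written by :func:`save_session`.

    Raises
    ------
    SchemaError
        If a required group (``/data``, ``/sensors``, ``/meta``) is absent
        or the schema version is unsupported.
    """
    with h5py.File(path, "r") as f:
        for group in ("data", "sensors", "meta"):
            if group not in f:
                raise SchemaError(f"container missing required group '/{group}'")
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported session schema version {version}")
        s = f["sensors"]
        coils = {}
        if "coils" in s:
            for name, sub in s["coils"].items():
                coils[name] = (
                    sub["positions"][()],
                    sub["orientations"][()],
                    sub["weights"][()],
                )
        sensors = SensorArray(
            names=[n.decode() if isinstance(n, bytes) else n for n in s["names"][()]],
            positions=s["positions"][()],
            orientations=s["orientations"][()] if "orientations" in s else None,
            kinds=[k.decode() if isinstance(k, bytes) else k for k in s["kinds"][()]],
            coil_weights=coils,
        )
        return SessionData(
            data=f["data/y"][()],
            fs=float(f["meta"].attrs["fs"]),
            time=f["data/time"][()],
            sensors=sensors,
            is_average=bool(f["meta"].attrs["is_average"]),
        )


def export_mat_session(session: SessionData, path) -> None:
    """Write the session as a MAT-file struct (``session`` variable)."""
    struct = {
        "data": session.data,
        "fs": float(session.fs),
        "time": session.time,
        "names": np.array(session.sensors.names, dtype=object),
        "positions": session.sensors.positions,
        "kinds": np.array(session.sensors.kinds, dtype=object),
        "is_average": float(session.is_average),
    }
    if session.sensors.orientations is not None:
        struct["orientations"] = session.sensors.orientations
    savemat(path, {"session": struct})


def _mat_cellstr(v) -> list:
    out = []
    for item in np.asarray(v).ravel():
        while isinstance(item, np.ndarray):
            item = item.item() if item.size == 1 else str(item)
        if isinstance(item, bytes):
            item = item.decode()
        out.append(str(item))
    return out


def import_mat_session(path) -> SessionData:
    """Import a MAT-file session struct (trials x channels x samples).

    The struct must provide ``data``, ``fs``, ``time``, ``names``,
    ``positions`` and ``kinds``; ``orientations`` is required when MEG
    channels are present.
    """
    mat = loadmat(path, squeeze_me=False, struct_as_record=True)
    if "session" not in mat:
        raise SchemaError("MAT file lacks a 'session' struct")
    st = mat["session"][0, 0]
    fields = st.dtype.names or ()
    for required in ("data", "fs", "time", "names", "positions", "kinds"):
        if required not in fields:
            raise SchemaError(f"MAT session struct missing field '{required}'")
    sensors = SensorArray(
        names=_mat_cellstr(st["names"]),
        positions=np.atleast_2d(st["positions"]),
        orientations=np.atleast_2d(st["orientations"]) if "orientations" in fields else None,
        kinds=_mat_cellstr(st["kinds"]),
    )
    data = np.asarray(st["data"], dtype=np.float64)
    if data.ndim == 2:  # single trial stored as channels x samples
        data = data[None]
    return SessionData(
        data=data,
        fs=float(np.squeeze(st["fs"])),
        time=np.squeeze(np.asarray(st["time"], dtype=np.float64)),
        sensors=sensors,
        is_average=bool(np.squeeze(st["is_average"])) if "is_average" in fields else False,
    )


# ---------------------------------------------------------------------------
# channel utilities and preprocessing
# ---------------------------------------------------------------------------

def sensor_rms(session: SessionData, window: TimeWindow) -> np.ndarray:
    """Per-channel RMS over the samples of ``window``, averaged over trials.

    Used to inspect channel quality before (de-)selecting channels.
    """
    idx = window.indices(session.time)
    x = session.data[:, :, idx]
    return np.sqrt(np.mean(x**2, axis=2)).mean(axis=0)


def select_channels(session: SessionData, keep) -> SessionData:
    """Restrict the session to the channels named in ``keep`` (order kept)."""
    keep = list(keep)
    if len(keep) == 0:
        raise ValueError("cannot select an empty channel set")
    idx = session.sensors.index(keep)
    return session.replace(
        data=session.data[:, idx, :], sensors=session.sensors.subset(keep)
    )


def _butter_sos(lo_hz: float, hi_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0.0 <= lo_hz < hi_hz):
        raise ValueError(f"need 0 <= lo < hi, got ({lo_hz}, {hi_hz})")
    if hi_hz >= nyq:
        raise ValueError(f"upper edge {hi_hz} Hz at or above Nyquist ({nyq} Hz)")
    if lo_hz == 0.0:
        return sps.butter(order, hi_hz / nyq, btype="lowpass", output="sos")
    return sps.butter(order, [lo_hz / nyq, hi_hz / nyq], btype="bandpass", output="sos")


def bandpass(
    session: SessionData, lo_hz: float, hi_hz: float, order: int = 4
) -> SessionData:
    """Zero-phase Butterworth band-pass, applied per trial and channel.

    A 4th-order IIR Butterworth is run forward and backward
    (``sosfiltfilt``) so the passband sees no phase distortion; edges are
    reflect-padded.  ``lo_hz = 0`` degenerates to a low-pass.
    """
    sos = _butter_sos(lo_hz, hi_hz, session.fs, order=order)
    filtered = sps.sosfiltfilt(sos, session.data, axis=-1, padtype="even")
    return session.replace(data=np.ascontiguousarray(filtered))


def remove_baseline(session: SessionData, window: TimeWindow) -> SessionData:
    """Subtract the per-trial, per-channel mean over ``window`` (baseline)."""
    idx = window.indices(session.time)
    base = session.data[:, :, idx].mean(axis=2, keepdims=True)
    return session.replace(data=session.data - base)


def average_trials(session: SessionData) -> SessionData:
    """Arithmetic mean across trials; result is a single-trial session."""
    if session.n_trials < 1:
        raise ValueError("no trials to average")
    avg = session.data.mean(axis=0, keepdims=True)
    return session.replace(data=avg, is_average=True)
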