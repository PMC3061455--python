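"""Dipole simulator: sensor recordings with known ground truth.

Generates multi-trial MEG/EEG sessions by driving grid-node dipoles
through a lead field and adding brain-like background noise (random
tangential dipoles with 1/f-shaped spectra) plus white sensor noise,
scaled to a requested signal-to-noise ratio.  Three waveform families are
supported:

* ``evoked`` — a phase-locked Gaussian-windowed pulse (same in every
  trial, up to optional latency jitter);
* ``induced`` — an oscillatory burst whose phase is randomized per trial,
  so it vanishes from the trial average but raises band power;
* ``am_modulated`` — a carrier with a slow stochastic amplitude envelope,
  optionally shared across dipoles to a target envelope correlation.

Every draw flows from one explicit seed, so simulations replay bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .session import SensorArray, SessionData, TimeWindow

__all__ = [
    "EvokedWaveform",
    "InducedWaveform",
    "AMWaveform",
    "DipoleSpec",
    "NoiseSpec",
    "simulate_session",
    "simulate_correlated_pair",
    "simulate_group",
]


@dataclass(frozen=True)
class EvokedWaveform:
    """Gaussian-windowed pulse: amplitude * gabor(latency, width) in A·m."""

    latency: float  # s, pulse centre
    width: float  # s, Gaussian sigma
    amplitude: float  # A·m, peak moment
    freq: float = 0.0  # optional carrier; 0 = pure Gaussian pulse
    phase: float = 0.0

    def sample(self, time: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        env = np.exp(-0.5 * ((time - self.latency) / self.width) ** 2)
        if self.freq > 0:
            env = env * np.cos(2 * np.pi * self.freq * (time - self.latency) + self.phase)
        return self.amplitude * env


@dataclass(frozen=True)
class InducedWaveform:
    """Oscillatory burst with per-trial random phase (non-phase-locked)."""

    freq: float  # Hz
    window: TimeWindow  # burst support
    amplitude: float  # A·m
    rise: float = 0.02  # s, cosine taper at the burst edges

    def sample(self, time: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        phase = rng.uniform(0, 2 * np.pi)
        x = self.amplitude * np.cos(2 * np.pi * self.freq * time + phase)
        env = np.zeros_like(time)
        inside = self.window.mask(time)
        env[inside] = 1.0
        # smooth edges to limit spectral splatter
        for edge, sign in ((self.window.start, 1.0), (self.window.stop, -1.0)):
            ramp = (time - edge) * sign
            sel = (ramp >= 0) & (ramp < self.rise) & inside
            env[sel] = 0.5 - 0.5 * np.cos(np.pi * ramp[sel] / self.rise)
        return x * env


@dataclass(frozen=True)
class AMWaveform:
    """Carrier with stochastic low-pass amplitude modulation.

    ``envelope`` may be supplied per trial by :func:`simulate_session` when
    dipoles share modulation; otherwise it is drawn independently.
    """

    carrier: float  # Hz
    amplitude: float  # A·m
    mod_depth: float = 0.4
    mod_cutoff: float = 3.0  # Hz, envelope bandwidth

    def envelope(self, time: np.ndarray, fs: float, rng: np.random.Generator) -> np.ndarray:
        z = lowpass_noise(len(time), fs, self.mod_cutoff, rng)
        return np.clip(1.0 + self.mod_depth * z, 0.05, None)

    def sample_with_envelope(
        self, time: np.ndarray, env: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        phase = rng.uniform(0, 2 * np.pi)
        return self.amplitude * env * np.cos(2 * np.pi * self.carrier * time + phase)

    def sample(self, time, rng, fs=None):
        if fs is None:
            fs = 1.0 / float(time[1] - time[0])
        return self.sample_with_envelope(time, self.envelope(time, fs, rng), rng)


@dataclass(frozen=True)
class DipoleSpec:
    """One simulated source: a grid voxel, a unit moment orientation, a
    waveform, and optional per-trial latency jitter (seconds)."""

    voxel: int
    orientation: np.ndarray
    waveform: object
    jitter: float = 0.0

    def __post_init__(self):
        ori = np.asarray(self.orientation, dtype=np.float64)
        n = np.linalg.norm(ori)
        if n < 1e-12:
            raise ValueError("dipole orientation must be nonzero")
        object.__setattr__(self, "orientation", ori / n)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: white sensor noise plus dipolar background activity.

    ``snr`` (if given) rescales the total noise so that the ratio of
    signal RMS to noise RMS — measured at the sensors over ``snr_window``,
    pooled over channels — equals the requested value.  ``sensor_sigma``
    is in sensor units (T or V); brain-noise dipole amplitudes in A·m.
    """

    sensor_sigma: float = 1e-14
    n_brain_dipoles: int = 200
    brain_amplitude: float = 1e-9
    snr: float | None = None
    snr_window: TimeWindow | None = None

    def __post_init__(self):
        if self.sensor_sigma < 0:
            raise ValueError("sensor_sigma must be >= 0")


def lowpass_noise(n: int, fs: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to [0, cutoff] Hz."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[f > cutoff] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with 1/f amplitude spectrum (brain-like)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _radial_check(lf: LeadField, dip: DipoleSpec) -> None:
    """Reject dipoles that are externally silent (e.g. radial in a sphere)."""
    g = lf.gain[dip.voxel] @ dip.orientation  # (channels,)
    scale = np.abs(lf.gain[dip.voxel]).max()
    if scale > 0 and np.abs(g).max() < 1e-10 * scale:
        raise ValueError(
            f"dipole at voxel {dip.voxel} is (near-)radial: externally silent "
            "and unlocalizable"
        )


def _time_axis(fs: float, epoch) -> np.ndarray:
    t0, t1 = epoch
    n = int(round((t1 - t0) * fs))
    return t0 + np.arange(n) / fs


def simulate_session(
    dipoles,
    noise: NoiseSpec,
    leadfield: LeadField,
    sensors: SensorArray,
    n_trials: int,
    fs: float,
    epoch=(-0.5, 0.5),
    seed: int | np.random.Generator = 0,
    shared_envelope_corr: float | None = None,
) -> tuple[SessionData, dict]:
    """Simulate a multi-trial session; returns (session, ground_truth).

    ``dipoles`` is a sequence of :class:`DipoleSpec` whose voxels index
    ``leadfield``.  ``shared_envelope_corr`` couples the amplitude
    envelopes of AM dipoles to the given target correlation.  Ground truth
    records voxel indices, orientations, per-trial source waveforms and
    the realized sensor-level SNR.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dipoles = list(dipoles)
    ch_idx = sensors.index(list(leadfield.channel_names))
    time = _time_axis(fs, epoch)
    ns = len(time)
    nc = sensors.n_channels
    for d in dipoles:
        if not (0 <= d.voxel < leadfield.n_voxels):
            raise ValueError(f"dipole voxel {d.voxel} outside the lead field grid")
        _radial_check(leadfield, d)

    gains = [leadfield.gain[d.voxel] @ d.orientation for d in dipoles]  # (channels,)

    signal = np.zeros((n_trials, nc, ns))
    waveforms = np.zeros((n_trials, len(dipoles), ns))
    shared_env = None
    for t in range(n_trials):
        if shared_envelope_corr is not None:
            am = [d for d in dipoles if isinstance(d.waveform, AMWaveform)]
            if am:
                shared_env = lowpass_noise(ns, fs, am[0].waveform.mod_cutoff, rng)
        for i, d in enumerate(dipoles):
            t_axis = time
            if d.jitter > 0:
                t_axis = time - rng.normal(0.0, d.jitter)
            if isinstance(d.waveform, AMWaveform) and shared_env is not None:
                c = float(shared_envelope_corr)
                own = lowpass_noise(ns, fs, d.waveform.mod_cutoff, rng)
                z = np.sqrt(c) * shared_env + np.sqrt(1 - c) * own
                env = np.clip(1.0 + d.waveform.mod_depth * z, 0.05, None)
                q = d.waveform.sample_with_envelope(t_axis, env, rng)
            else:
                q = d.waveform.sample(t_axis, rng)
            waveforms[t, i] = q
            signal[t, ch_idx, :] += gains[i][:, None] * q[None, :]

    # --- noise -------------------------------------------------------------
    noise_data = np.zeros_like(signal)
    if noise.n_brain_dipoles > 0:
        voi = np.nonzero(leadfield.grid.voi_mask)[0]
        vox = rng.choice(voi, size=noise.n_brain_dipoles, replace=True)
        for v in vox:
            # tangential-ish random orientation: random unit vector with the
            # radial component (w.r.t. grid centroid) removed
            ori = rng.standard_normal(3)
            radial = leadfield.grid.positions[v] - leadfield.grid.positions[voi].mean(0)
            nr = np.linalg.norm(radial)
            if nr > 1e-9:
                ori -= (ori @ radial) / nr**2 * radial
            nn = np.linalg.norm(ori)
            if nn < 1e-9:
                continue
            ori /= nn
            g = leadfield.gain[v] @ ori
            for t in range(n_trials):
                noise_data[t, ch_idx, :] += (
                    noise.brain_amplitude * g[:, None] * pink_noise(ns, fs, rng)[None, :]
                )
    if noise.sensor_sigma > 0:
        noise_data += noise.sensor_sigma * rng.standard_normal(signal.shape)

    realized_snr = None
    if noise.snr is not None:
        win = noise.snr_window or TimeWindow(time[0], time[-1] + 1.0 / fs)
        idx = win.indices(time)
        sig_rms = np.sqrt(np.mean(signal[:, :, idx] ** 2))
        noi_rms = np.sqrt(np.mean(noise_data[:, :, idx] ** 2))
        if noi_rms == 0:
            raise ValueError("cannot scale SNR of a zero noise model")
        noise_data *= sig_rms / (noise.snr * noi_rms)
        noi_rms = np.sqrt(np.mean(noise_data[:, :, idx] ** 2))
        realized_snr = float(sig_rms / noi_rms) if noi_rms > 0 else np.inf

    session = SessionData(
        data=signal + noise_data, fs=fs, time=time, sensors=sensors, is_average=False
    )
    truth = {
        "voxels": [d.voxel for d in dipoles],
        "orientations": np.array([d.orientation for d in dipoles]),
        "waveforms": waveforms,
        "realized_snr": realized_snr,
    }
    return session, truth


def dataclasses_replace_noise(noise: NoiseSpec) -> NoiseSpec:
    """Copy of ``noise`` with SNR scaling disabled (raw noise draw)."""
    import dataclasses

    return dataclasses.replace(noise, snr=None, snr_window=None)


def correlated_waveform_pair(
    base: EvokedWaveform, time: np.ndarray, c: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two waveforms with sample correlation ~= ``c`` in [0, 1].

    Built from a Gabor atom and its (orthogonal, equal-norm) quadrature:
    w2 = c*w1 + sqrt(1-c^2)*w1_quadrature, so corr(w1, w2) = c up to the
    small non-orthogonality of the finite-length atoms.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError("correlation must lie in [0, 1]")
    freq = base.freq if base.freq > 0 else 1.0 / (4 * base.width)
    env = np.exp(-0.5 * ((time - base.latency) / base.width) ** 2)
    w1 = env * np.cos(2 * np.pi * freq * (time - base.latency))
    w_quad = env * np.sin(2 * np.pi * freq * (time - base.latency))
    # demean & normalize so the mixture correlation is exactly controlled
    for w in (w1, w_quad):
        w -= w.mean()
    w1 /= np.linalg.norm(w1)
    w_quad -= (w_quad @ w1) * w1  # exact orthogonalization
    w_quad /= np.linalg.norm(w_quad)
    w2 = c * w1 + np.sqrt(1.0 - c * c) * w_quad
    scale = base.amplitude / np.abs(w1).max()
    return scale * w1, scale * w2


def simulate_correlated_pair(
    voxels,
    orientations,
    correlation: float,
    noise: NoiseSpec,
    leadfield: LeadField,
    sensors: SensorArray,
    n_trials: int,
    fs: float,
    epoch=(-0.5, 0.5),
    base: EvokedWaveform | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[SessionData, dict]:
    """Two evoked dipoles with a controlled waveform correlation.

    ``correlation`` = 1 reproduces the classic beamformer failure mode of
    fully correlated bilateral sources; 0 gives orthogonal waveforms.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if base is None:
        base = EvokedWaveform(latency=0.15, width=0.04, amplitude=10e-9, freq=10.0)
    time = _time_axis(fs, epoch)
    w1, w2 = correlated_waveform_pair(base, time, correlation, rng)

    dips = [
        DipoleSpec(voxel=int(voxels[0]), orientation=orientations[0], waveform=base),
        DipoleSpec(voxel=int(voxels[1]), orientation=orientations[1], waveform=base),
    ]
    for d in dips:
        _radial_check(leadfield, d)
    gains = [leadfield.gain[d.voxel] @ d.orientation for d in dips]
    ch_idx = sensors.index(list(leadfield.channel_names))
    nc = sensors.n_channels
    signal = np.zeros((n_trials, nc, len(time)))
    for t in range(n_trials):
        signal[t, ch_idx, :] = gains[0][:, None] * w1[None, :] + gains[1][:, None] * w2[
            None, :
        ]

    # draw the noise unscaled, then match the requested SNR against the
    # actual two-dipole signal
    noise_unscaled = dataclasses_replace_noise(noise)
    sess, _ = simulate_session(
        [], noise_unscaled, leadfield, sensors, n_trials, fs, epoch, seed=rng
    )
    data = signal + sess.data
    if noise.snr is not None:
        win = noise.snr_window or TimeWindow(time[0], time[-1] + 1.0 / fs)
        idx = win.indices(time)
        sig_rms = np.sqrt(np.mean(signal[:, :, idx] ** 2))
        noi_rms = np.sqrt(np.mean(sess.data[:, :, idx] ** 2))
        if noi_rms == 0:
            raise ValueError("cannot scale SNR of a zero noise model")
        data = signal + sess.data * (sig_rms / (noise.snr * noi_rms))
    session = SessionData(data=data, fs=fs, time=time, sensors=sensors)
    truth = {
        "voxels": [d.voxel for d in dips],
        "orientations": np.array([d.orientation for d in dips]),
        "waveforms": np.stack([w1, w2]),
        "realized_correlation": float(np.corrcoef(w1, w2)[0, 1]),
    }
    return session, truth


def simulate_group(
    effect_map: np.ndarray,
    n_subjects: int,
    between_subject_sd: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-subject source-power-change maps for group statistics.

    Each subject's map is ``effect_map`` plus a Gaussian between-subject
    deviation (per voxel, sd ``between_subject_sd``) plus measurement
    noise (sd ``noise_sd``).  A zero effect map yields an exact
    sign-symmetric null, suitable for family-wise-error calibration.
    Returns (n_subjects, *effect_map.shape).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effect = np.asarray(effect_map, dtype=np.float64)
    shape = (n_subjects,) + effect.shape
    maps = effect[None] + between_subject_sd * rng.standard_normal(shape)
    if noise_sd > 0:
        maps = maps + noise_sd * rng.standard_normal(shape)
    return maps
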