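"""Source-space functional connectivity.

Virtual-electrode time series (spatial-filter weights applied to the
sensor data, optionally joined by reference channels such as EMG) are
turned into trial-wise cross-spectra by Welch-style windowed FFTs, from
which the complex coherency C_xy = S_xy / sqrt(S_xx S_yy) gives

* magnitude coherence |C_xy| in [0, 1];
* imaginary coherence Im(C_xy) in [-1, 1] — insensitive to instantaneous
  (zero-lag) mixing such as sensor cross-talk and volume conduction, which
  produces purely real coherency;

and, as an alternative metric, the Pearson correlation of Hilbert
envelopes of band-passed source series.  Maps can be seed-based (one row)
or whole-brain (all pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beamformer import SpatialFilter
from .session import SessionData

__all__ = [
    "CrossSpectrum",
    "ConnectivityMap",
    "project_sources",
    "cross_spectra",
    "coherence",
    "envelope_correlation",
    "seed_map",
    "pair_permutation_null",
]


@dataclass(frozen=True)
class CrossSpectrum:
    """Averaged cross-spectral matrices: (n_freqs, n_signals, n_signals).

    Hermitian per frequency bin with real non-negative diagonal.
    ``n_average`` counts the trial x segment units averaged.
    """

    S: np.ndarray
    freqs: np.ndarray
    n_trials: int
    n_average: int
    window: str = "hann"
    segment_len: int = 0

    def __post_init__(self):
        S = np.asarray(self.S, dtype=np.complex128)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=np.float64))
        if S.ndim != 3 or S.shape[1] != S.shape[2]:
            raise ValueError("S must be (n_freqs, p, p)")
        scale = np.abs(S).max()
        if scale > 0:
            if np.abs(S - S.conj().transpose(0, 2, 1)).max() > 1e-10 * scale:
                raise ValueError("cross-spectrum must be Hermitian per bin")
        if np.any(np.diagonal(S, axis1=1, axis2=2).real < -1e-12 * max(scale, 1e-300)):
            raise ValueError("auto-spectra must be non-negative")

    def band_indices(self, band) -> np.ndarray:
        lo, hi = band
        idx = np.nonzero((self.freqs >= lo) & (self.freqs <= hi))[0]
        if idx.size == 0:
            raise ValueError(f"band ({lo}, {hi}) Hz contains no frequency bins")
        return idx


@dataclass(frozen=True)
class ConnectivityMap:
    """Pairwise connectivity values for one metric and band.

    ``values`` is (n_seeds, n_targets); ``seed_indices`` / ``target_indices``
    name the signals.  Self-pairs follow the metric conventions
    (coherence 1, imaginary coherence 0, envelope correlation 1).
    """

    metric: str
    values: np.ndarray
    band: tuple | None = None
    seed_indices: tuple = ()
    target_indices: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        finite = v[np.isfinite(v)]
        if self.metric == "coh_magnitude" and finite.size:
            if finite.min() < -1e-9 or finite.max() > 1 + 1e-9:
                raise ValueError("magnitude coherence must lie in [0, 1]")
        if self.metric in ("imag_coh", "env_corr") and finite.size:
            if np.abs(finite).max() > 1 + 1e-9:
                raise ValueError(f"{self.metric} must lie in [-1, 1]")


def project_sources(
    session: SessionData, filt: SpatialFilter, voxel_subset=None
) -> np.ndarray:
    """Per-trial scalar source time series for the requested voxels.

    Requires a scalar (orientation-constrained) filter; returns
    (n_trials, n_voxels_subset, n_samples).
    """
    if filt.n_comp != 1:
        raise ValueError("project_sources expects a scalar spatial filter")
    if voxel_subset is None:
        voxel_subset = np.arange(filt.n_voxels)
    voxel_subset = np.asarray(voxel_subset, dtype=int)
    if voxel_subset.size and (
        voxel_subset.min() < 0 or voxel_subset.max() >= filt.n_voxels
    ):
        raise ValueError("voxel subset outside the filter's grid")
    ch_idx = session.sensors.index(list(filt.channel_names))
    W = filt.weights[voxel_subset, :, 0]  # (v, nc)
    return np.einsum("vc,tcs->tvs", W, session.data[:, ch_idx, :])


def cross_spectra(
    signals: np.ndarray,
    fs: float,
    segment_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
) -> CrossSpectrum:
    """Welch cross-spectral matrices from per-trial signals.

    ``signals`` is (n_trials, n_signals, n_samples).  Each trial is cut
    into windowed segments of ``segment_len`` samples (default: half a
    second) overlapping by ``overlap``; cross-spectra are averaged over
    segments and trials.  At least two averaging units are required for a
    defined coherence.
    """
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("signals must be (n_trials, n_signals, n_samples)")
    nt, p, ns = x.shape
    if segment_len is None:
        segment_len = min(ns, int(round(0.5 * fs)))
    if segment_len > ns:
        raise ValueError("segment length exceeds samples per trial")
    step = max(1, int(round(segment_len * (1.0 - overlap))))
    starts = list(range(0, ns - segment_len + 1, step))
    n_units = nt * len(starts)
    if n_units < 2:
        raise ValueError(
            "need at least 2 trial x segment units to average a cross-spectrum"
        )
    taper = sps.get_window(window, segment_len)
    nf = segment_len // 2 + 1
    S = np.zeros((nf, p, p), dtype=np.complex128)
    for t in range(nt):
        for s0 in starts:
            seg = x[t, :, s0 : s0 + segment_len]
            seg = (seg - seg.mean(axis=1, keepdims=True)) * taper[None, :]
            X = np.fft.rfft(seg, axis=1)  # (p, nf)
            S += np.einsum("af,bf->fab", X, X.conj())
    S /= n_units
    freqs = np.fft.rfftfreq(segment_len, 1.0 / fs)
    return CrossSpectrum(
        S=S,
        freqs=freqs,
        n_trials=nt,
        n_average=n_units,
        window=window,
        segment_len=segment_len,
    )


def coherence(cs: CrossSpectrum, band=None):
    """Magnitude and imaginary coherence maps from a cross-spectrum.

    The complex coherency per bin is C_xy = S_xy / sqrt(S_xx S_yy); band
    values are the mean over the band's bins of |C_xy| and Im(C_xy)
    respectively (whole spectrum when ``band`` is None).  Pairs with a
    zero auto-spectrum are NaN.  Returns ``(magnitude_map, imaginary_map)``.
    """
    idx = cs.band_indices(band) if band is not None else np.arange(len(cs.freqs))
    S = cs.S[idx]
    auto = np.diagonal(S, axis1=1, axis2=2).real  # (nf, p)
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = S / denom
    bad = (auto[:, :, None] == 0) | (auto[:, None, :] == 0)
    C = np.where(bad, np.nan, C)
    mag = np.nanmean(np.abs(C), axis=0)
    imag = np.nanmean(C.imag, axis=0)
    invalid = np.all(bad, axis=0)
    mag = np.where(invalid, np.nan, mag)
    imag = np.where(invalid, np.nan, imag)
    p = S.shape[1]
    # self-pair conventions, exact
    di = np.arange(p)
    mag[di, di] = np.where(np.isnan(mag[di, di]), np.nan, 1.0)
    imag[di, di] = np.where(np.isnan(imag[di, di]), np.nan, 0.0)
    mag = np.clip(mag, 0.0, 1.0)
    imag = np.clip(imag, -1.0, 1.0)
    targets = tuple(range(p))
    m_map = ConnectivityMap("coh_magnitude", mag, band, targets, targets)
    i_map = ConnectivityMap("imag_coh", imag, band, targets, targets)
    return m_map, i_map


def envelope_correlation(
    signals: np.ndarray,
    fs: float,
    band,
    filter_order: int = 4,
    trim: int | None = None,
) -> ConnectivityMap:
    """Pairwise Pearson correlation of Hilbert envelopes in a band.

    Signals are band-passed (zero-phase Butterworth), the analytic-signal
    amplitude is taken per trial, ``trim`` samples are dropped at each
    epoch edge (default: one cycle of the band's low edge) to remove
    filter and Hilbert edge transients, and the per-trial correlations
    are averaged.  Pairs with a constant envelope are NaN.
    """
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("signals must be (n_trials, n_signals, n_samples)")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) for fs={fs}")
    nt, p, ns = x.shape
    sos = sps.butter(filter_order, [lo / (fs / 2), hi / (fs / 2)], "bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, x, axis=-1, padtype="even")
    env = np.abs(sps.hilbert(filtered, axis=-1))
    if trim is None:
        trim = int(round(fs / lo))
    if 2 * trim >= ns:
        raise ValueError("epoch too short for the requested edge trim")
    if trim > 0:
        env = env[:, :, trim:-trim]
    env = env - env.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(env, axis=2)  # (nt, p)
    corr_sum = np.zeros((p, p))
    count = np.zeros((p, p))
    for t in range(nt):
        denom = norms[t][:, None] * norms[t][None, :]
        ok = denom > 0
        r = np.zeros((p, p))
        r[ok] = (env[t] @ env[t].T)[ok] / denom[ok]
        corr_sum += np.where(ok, r, 0.0)
        count += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = corr_sum / count
    vals = np.where(count == 0, np.nan, vals)
    vals = np.clip(vals, -1.0, 1.0)
    targets = tuple(range(p))
    return ConnectivityMap("env_corr", vals, band, targets, targets, {"trim": trim})


def seed_map(
    session: SessionData,
    filt: SpatialFilter,
    metric: str,
    band,
    seed_voxel: int | None = None,
    reference: np.ndarray | None = None,
    voxel_subset=None,
    segment_len: int | None = None,
    chunk: int = 256,
) -> ConnectivityMap:
    """Seed-based or whole-brain connectivity map.

    ``metric`` is one of ``coh``, ``imcoh``, ``envcorr``.  With
    ``seed_voxel`` the result is 1 x V against all (subset) voxels; with
    ``reference`` (n_trials, n_samples), the external channel — e.g.
    rectified EMG for corticomuscular coherence — is the seed instead.
    Without either, the full V x V matrix is computed in deterministic
    chunks of ``chunk`` voxels.
    """
    if metric not in ("coh", "imcoh", "envcorr"):
        raise ValueError(f"unknown metric {metric!r}")
    if voxel_subset is None:
        voxel_subset = np.nonzero(np.any(filt.weights != 0, axis=(1, 2)))[0]
    voxel_subset = np.asarray(voxel_subset, dtype=int)
    if seed_voxel is not None and seed_voxel not in set(voxel_subset.tolist()):
        raise ValueError("seed voxel outside the available volume of interest")
    src = project_sources(session, filt, voxel_subset)  # (nt, V, ns)

    def metric_values(sig: np.ndarray) -> np.ndarray:
        if metric == "envcorr":
            return envelope_correlation(sig, session.fs, band).values
        cs = cross_spectra(sig, session.fs, segment_len=segment_len)
        mag, imag = coherence(cs, band)
        return mag.values if metric == "coh" else imag.values

    if reference is not None:
        ref = np.asarray(reference, dtype=np.float64)
        if ref.shape != (src.shape[0], src.shape[2]):
            raise ValueError("reference must be (n_trials, n_samples)")
        sig = np.concatenate([ref[:, None, :], src], axis=1)
        row = metric_values(sig)[0, 1:]
        return ConnectivityMap(
            _metric_name(metric), row[None, :], band, ("reference",),
            tuple(int(v) for v in voxel_subset),
        )
    if seed_voxel is not None:
        seed_pos = int(np.nonzero(voxel_subset == seed_voxel)[0][0])
        vals = np.empty((1, len(voxel_subset)))
        for s0 in range(0, len(voxel_subset), chunk):
            sel = np.arange(s0, min(s0 + chunk, len(voxel_subset)))
            if seed_pos in sel:
                block = src[:, sel, :]
                local = np.nonzero(sel == seed_pos)[0][0]
            else:
                block = np.concatenate([src[:, [seed_pos], :], src[:, sel, :]], axis=1)
                local = 0
            m = metric_values(block)
            vals[0, sel] = m[local, 1:] if seed_pos not in sel else m[local]
        return ConnectivityMap(
            _metric_name(metric), vals, band, (int(seed_voxel),),
            tuple(int(v) for v in voxel_subset),
        )
    # whole-brain: all pairs at once (chunking the FFT stage is cheap since
    # cross_spectra is O(V^2) memory anyway at map assembly)
    vals = metric_values(src)
    return ConnectivityMap(
        _metric_name(metric), vals, band,
        tuple(int(v) for v in voxel_subset), tuple(int(v) for v in voxel_subset),
    )


def _metric_name(metric: str) -> str:
    return {"coh": "coh_magnitude", "imcoh": "imag_coh", "envcorr": "env_corr"}[metric]


def pair_permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    metric: str,
    band,
    n_perm: int = 1000,
    seed: int = 0,
    segment_len: int | None = None,
):
    """Trial-shuffle null for one signal pair.

    Breaks the trial pairing between ``x`` and ``y`` (each (n_trials,
    n_samples)) by permuting the trials of ``y``; returns (observed,
    null_values).  This is a generic exchangeability null, not a
    calibrated test of any specific coupling model.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x and y must be matching (n_trials, n_samples) arrays")

    def value(ypair):
        sig = np.stack([x, ypair], axis=1)
        if metric == "envcorr":
            return envelope_correlation(sig, fs, band).values[0, 1]
        cs = cross_spectra(sig, fs, segment_len=segment_len)
        mag, imag = coherence(cs, band)
        return (mag if metric == "coh" else imag).values[0, 1]

    observed = value(y)
    null = np.array([value(y[rng.permutation(x.shape[0])]) for _ in range(n_perm)])
    return observed, null
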