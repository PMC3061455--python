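"""Source-space connectivity: cross-spectra, coherence, envelopes, maps."""

import numpy as np
import pytest

from conftest import make_session, tangential
from megbeam import beamformer as bf
from megbeam import connectivity as conn
from megbeam import simulate as sim


FS = 200.0
NS = 400  # 2 s epochs


def tone_trials(n_trials, freq, rng, phase_fn=None, noise=0.05):
    t = np.arange(NS) / FS
    out = []
    for _ in range(n_trials):
        ph = rng.uniform(0, 2 * np.pi) if phase_fn is None else phase_fn()
        out.append(np.sin(2 * np.pi * freq * t + ph))
    return np.array(out) + noise * rng.standard_normal((n_trials, NS))


class TestProjectSources:
    def test_one_hot_weights_copy_channel(self, rng):
        sess = make_session(rng.standard_normal((3, 4, 60)))
        W = np.zeros((2, 4, 1))
        W[0, 1, 0] = 1.0
        W[1, 3, 0] = 1.0
        filt = bf.SpatialFilter(weights=W, channel_names=sess.sensors.names, method="t")
        src = conn.project_sources(sess, filt)
        assert np.array_equal(src[:, 0, :], sess.data[:, 1, :])
        assert np.array_equal(src[:, 1, :], sess.data[:, 3, :])

    def test_linear_in_data(self, rng):
        x = rng.standard_normal((2, 3, 50))
        W = rng.standard_normal((2, 3, 1))
        filt_names = make_session(x).sensors.names
        filt = bf.SpatialFilter(weights=W, channel_names=filt_names, method="t")
        a = conn.project_sources(make_session(x), filt)
        b = conn.project_sources(make_session(2.0 * x), filt)
        assert np.allclose(b, 2.0 * a, rtol=1e-12)

    def test_matches_naive_loop(self, rng):
        sess = make_session(rng.standard_normal((2, 4, 30)))
        W = rng.standard_normal((3, 4, 1))
        filt = bf.SpatialFilter(weights=W, channel_names=sess.sensors.names, method="t")
        src = conn.project_sources(sess, filt, [0, 2])
        for t in range(2):
            for j, v in enumerate([0, 2]):
                expected = np.array(
                    [W[v, :, 0] @ sess.data[t, :, s] for s in range(30)]
                )
                assert np.allclose(src[t, j], expected, rtol=1e-12)

    def test_vector_filter_rejected(self, rng):
        sess = make_session(rng.standard_normal((2, 4, 30)))
        W = rng.standard_normal((3, 4, 3))
        filt = bf.SpatialFilter(weights=W, channel_names=sess.sensors.names, method="t")
        with pytest.raises(ValueError, match="scalar"):
            conn.project_sources(sess, filt)


class TestCrossSpectra:
    def test_identical_signals_give_unit_coherence(self, rng):
        x = tone_trials(20, 10.0, rng)
        sig = np.stack([x, x], axis=1)
        cs = conn.cross_spectra(sig, FS, segment_len=100)
        mag, imag = conn.coherence(cs)
        assert mag.values[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert imag.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_hermitian_symmetry(self, rng):
        sig = rng.standard_normal((10, 3, NS))
        cs = conn.cross_spectra(sig, FS, segment_len=100)
        assert np.allclose(cs.S, cs.S.conj().transpose(0, 2, 1))
        assert np.all(np.diagonal(cs.S, axis1=1, axis2=2).real >= 0)

    def test_independent_noise_coherence_is_small(self, rng):
        sig = rng.standard_normal((200, 2, NS))
        cs = conn.cross_spectra(sig, FS, segment_len=100)
        mag, _ = conn.coherence(cs)
        assert mag.values[0, 1] < 0.1

    def test_fewer_than_two_units_rejected(self, rng):
        sig = rng.standard_normal((1, 2, 100))
        with pytest.raises(ValueError, match="2 trial"):
            conn.cross_spectra(sig, FS, segment_len=100)

    def test_segment_longer_than_trial_rejected(self, rng):
        sig = rng.standard_normal((5, 2, 100))
        with pytest.raises(ValueError, match="segment"):
            conn.cross_spectra(sig, FS, segment_len=200)


class TestCoherence:
    def test_zero_lag_mixture_has_tiny_imaginary_part(self, rng):
        # instantaneous mixing of one source: the volume-conduction
        # surrogate that imaginary coherence is designed to reject
        s = tone_trials(200, 10.0, rng, noise=0.3)
        x1 = 1.0 * s + 0.05 * rng.standard_normal(s.shape)
        x2 = 0.7 * s + 0.05 * rng.standard_normal(s.shape)
        cs = conn.cross_spectra(np.stack([x1, x2], axis=1), FS, segment_len=100)
        mag, imag = conn.coherence(cs, band=(8, 12))
        assert mag.values[0, 1] > 0.9
        assert abs(imag.values[0, 1]) < 0.05

    def test_quadrature_pair_has_unit_imaginary_coherence(self, rng):
        t = np.arange(NS) / FS
        ph = rng.uniform(0, 2 * np.pi, 200)
        xa = np.array([np.sin(2 * np.pi * 10 * t + p) for p in ph])
        xb = np.array([np.sin(2 * np.pi * 10 * t + p + np.pi / 2) for p in ph])
        xa += 0.05 * rng.standard_normal(xa.shape)
        xb += 0.05 * rng.standard_normal(xb.shape)
        cs = conn.cross_spectra(np.stack([xa, xb], axis=1), FS, segment_len=100)
        _, imag = conn.coherence(cs, band=(8, 12))
        assert abs(imag.values[0, 1]) > 0.8

    def test_bounds_and_self_pairs(self, rng):
        sig = rng.standard_normal((20, 4, NS))
        cs = conn.cross_spectra(sig, FS, segment_len=100)
        mag, imag = conn.coherence(cs)
        assert np.all(mag.values >= 0) and np.all(mag.values <= 1)
        assert np.all(np.abs(imag.values) <= 1)
        assert np.allclose(np.diag(mag.values), 1.0)
        assert np.allclose(np.diag(imag.values), 0.0)
        # |Im C| <= |C| bin-wise implies it for band means of one bin
        one_bin, one_imag = conn.coherence(cs, band=(9.9, 10.1))
        assert np.all(np.abs(one_imag.values) <= one_bin.values + 1e-12)

    def test_invariant_to_positive_rescaling(self, rng):
        sig = rng.standard_normal((20, 2, NS))
        scaled = sig.copy()
        scaled[:, 1, :] *= 37.5
        m1, i1 = conn.coherence(conn.cross_spectra(sig, FS, segment_len=100))
        m2, i2 = conn.coherence(conn.cross_spectra(scaled, FS, segment_len=100))
        assert np.allclose(m1.values, m2.values, atol=1e-9)
        assert np.allclose(i1.values, i2.values, atol=1e-9)


class TestEnvelopeCorrelation:
    def make_am_pair(self, c, rng, n_trials=100, carrier=20.0, depth=0.4):
        t = np.arange(NS) / FS
        s1, s2 = [], []
        for _ in range(n_trials):
            shared = sim.lowpass_noise(NS, FS, 3.0, rng)
            o1 = sim.lowpass_noise(NS, FS, 3.0, rng)
            o2 = sim.lowpass_noise(NS, FS, 3.0, rng)
            z1 = np.sqrt(c) * shared + np.sqrt(1 - c) * o1
            z2 = np.sqrt(c) * shared + np.sqrt(1 - c) * o2
            e1 = np.clip(1 + depth * z1, 0.05, None)
            e2 = np.clip(1 + depth * z2, 0.05, None)
            s1.append(e1 * np.cos(2 * np.pi * carrier * t + rng.uniform(0, 2 * np.pi)))
            s2.append(e2 * np.cos(2 * np.pi * carrier * t + rng.uniform(0, 2 * np.pi)))
        return np.stack([np.array(s1), np.array(s2)], axis=1)

    def test_pure_tone_envelope_is_flat(self, rng):
        t = np.arange(NS) / FS
        sig = (2.5 * np.sin(2 * np.pi * 20 * t))[None, None, :].repeat(2, axis=1)
        from scipy.signal import hilbert

        env = np.abs(hilbert(sig[0, 0]))
        interior = env[NS // 4 : -NS // 4]
        assert np.max(np.abs(interior - 2.5)) < 0.025

    def test_recovers_generated_correlation(self, rng):
        sig = self.make_am_pair(0.8, rng)
        m = conn.envelope_correlation(sig, FS, (16, 24))
        assert m.values[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_independent_envelopes_near_zero(self, rng):
        sig = self.make_am_pair(0.0, rng)
        m = conn.envelope_correlation(sig, FS, (16, 24))
        assert abs(m.values[0, 1]) < 0.1

    def test_constant_envelope_pair_is_missing(self):
        t = np.arange(NS) / FS
        tone = np.sin(2 * np.pi * 20 * t)
        sig = np.stack([np.tile(tone, (3, 1)), np.tile(tone, (3, 1))], axis=1)
        sig[:, 1, :] = 0.0  # zero signal -> constant (zero) envelope
        m = conn.envelope_correlation(sig, FS, (16, 24))
        assert np.isnan(m.values[0, 1])

    def test_invalid_band_rejected(self, rng):
        sig = rng.standard_normal((3, 2, NS))
        with pytest.raises(ValueError, match="band"):
            conn.envelope_correlation(sig, FS, (50, 120))


class TestSeedMap:
    @pytest.fixture()
    def projected_setup(self, leadfield, grid, sensors):
        v1 = grid.nearest([0.01, -0.01, 0.05])
        v2 = grid.nearest([-0.01, 0.01, 0.04])
        dips = [
            sim.DipoleSpec(v1, tangential(grid.positions[v1]),
                           sim.InducedWaveform(20.0, conn_window(), 10e-9)),
        ]
        noise = sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=20, brain_amplitude=1.0,
                              snr=3.0, snr_window=conn_window())
        sess, _ = sim.simulate_session(dips, noise, leadfield, sensors, 40, FS,
                                       (-1.0, 1.0), seed=21)
        cov = bf.regularize(
            bf.compute_covariance(sess, conn_window()), "tikhonov", 0.001
        )
        lf_scalar, _ = bf.scalar_orientation(leadfield, cov)
        filt = bf.lcmv_weights(lf_scalar, cov)
        return sess, filt, v1, v2

    def test_seed_row_contains_self_pair_convention(self, projected_setup):
        sess, filt, v1, _ = projected_setup
        cmap = conn.seed_map(sess, filt, "coh", (16, 24), seed_voxel=v1)
        j = cmap.target_indices.index(v1)
        assert cmap.values[0, j] == pytest.approx(1.0, abs=1e-9)

    def test_whole_brain_symmetric_for_symmetric_metric(self, projected_setup):
        sess, filt, _, _ = projected_setup
        sub = list(range(0, filt.n_voxels, 12))
        cmap = conn.seed_map(sess, filt, "coh", (16, 24), voxel_subset=sub)
        assert np.allclose(cmap.values, cmap.values.T, atol=1e-12)

    def test_reference_channel_seed_finds_coherent_voxel(
        self, leadfield, grid, sensors
    ):
        # external reference (EMG-like): a copy of the source rhythm; the
        # most coherent voxel should be at the simulated source
        v1 = grid.nearest([0.01, -0.01, 0.05])
        dip = sim.DipoleSpec(v1, tangential(grid.positions[v1]),
                             sim.InducedWaveform(20.0, conn_window(), 10e-9))
        noise = sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=20, brain_amplitude=1.0,
                              snr=3.0, snr_window=conn_window())
        sess, truth = sim.simulate_session([dip], noise, leadfield, sensors, 40, FS,
                                           (-1.0, 1.0), seed=22)
        cov = bf.regularize(bf.compute_covariance(sess, conn_window()), "tikhonov", 0.001)
        lf_scalar, _ = bf.scalar_orientation(leadfield, cov)
        filt = bf.lcmv_weights(lf_scalar, cov)
        ref = truth["waveforms"][:, 0, :]  # the true source rhythm per trial
        cmap = conn.seed_map(sess, filt, "coh", (16, 24), reference=ref)
        best = cmap.target_indices[int(np.nanargmax(cmap.values[0]))]
        err = np.linalg.norm(grid.positions[best] - grid.positions[v1])
        assert err <= grid.spacing * np.sqrt(3) + 1e-9

    def test_seed_outside_voi_rejected(self, projected_setup):
        sess, filt, _, _ = projected_setup
        with pytest.raises(ValueError, match="seed voxel"):
            conn.seed_map(sess, filt, "coh", (16, 24), seed_voxel=10**6)

    def test_unknown_metric_rejected(self, projected_setup):
        sess, filt, v1, _ = projected_setup
        with pytest.raises(ValueError, match="metric"):
            conn.seed_map(sess, filt, "granger", (16, 24), seed_voxel=v1)


def conn_window():
    from megbeam.session import TimeWindow

    return TimeWindow(-0.5, 0.5)


def test_pair_permutation_null_brackets_observed(rng):
    x = tone_trials(30, 10.0, rng)
    y = x + 0.1 * rng.standard_normal(x.shape)
    obs, null = conn.pair_permutation_null(x, y, FS, "coh", (8, 12), n_perm=20, seed=0)
    assert obs > np.percentile(null, 95)
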