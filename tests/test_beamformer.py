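"""Adaptive spatial filters: covariance estimation, LCMV and its variants."""

import warnings

import numpy as np
import pytest

import oracles
from conftest import make_session, tangential
from megbeam import beamformer as bf
from megbeam import forward as fwd
from megbeam import simulate as sim
from megbeam.session import TimeWindow


def random_spd(nc, rng, cond=50.0):
    Q, _ = np.linalg.qr(rng.standard_normal((nc, nc)))
    evals = np.geomspace(1.0, cond, nc)
    return Q @ np.diag(evals) @ Q.T


def single_voxel_lf(L):
    """Wrap one gain matrix as a 1-voxel lead field."""
    L = np.asarray(L, float)
    grid = fwd.VoxelGrid(
        positions=np.zeros((1, 3)), shape=(1, 1, 1), spacing=0.01,
        origin=np.zeros(3), voi_mask=np.array([True]),
    )
    ncomp = L.shape[1]
    return fwd.LeadField(
        gain=L[None], grid=grid, channel_names=[f"c{i}" for i in range(L.shape[0])],
        form="vector" if ncomp == 3 else "scalar",
        orientations=np.array([[0.0, 0.0, 1.0]]) if ncomp == 1 else None,
    )


class TestComputeCovariance:
    def test_white_noise_trials_mode_near_identity(self, rng):
        sigma = 2.0
        sess = make_session(sigma * rng.standard_normal((20, 6, 1000)))
        cov = bf.compute_covariance(sess, TimeWindow(-0.2, 3.7), mode="trials")
        off = cov.matrix - np.diag(np.diag(cov.matrix))
        assert np.allclose(np.diag(cov.matrix), sigma**2, rtol=0.15)
        assert np.abs(off).max() < 0.05 * sigma**2

    def test_single_trial_modes_agree(self, rng):
        sess = make_session(rng.standard_normal((1, 4, 200)))
        win = TimeWindow(-0.1, 0.5)
        a = bf.compute_covariance(sess, win, mode="averaged")
        b = bf.compute_covariance(sess, win, mode="trials")
        assert np.allclose(a.matrix, b.matrix, rtol=1e-12)

    def test_opposite_trials_averaged_mode_zero(self, rng):
        x = rng.standard_normal((1, 4, 100))
        sess = make_session(np.concatenate([x, -x], axis=0))
        cov = bf.compute_covariance(sess, TimeWindow(-0.1, 0.1), mode="averaged")
        assert np.allclose(cov.matrix, 0.0, atol=1e-30)

    def test_trials_mode_matches_naive_loop(self, rng):
        sess = make_session(rng.standard_normal((5, 4, 120)))
        win = TimeWindow(-0.1, 0.2)
        cov = bf.compute_covariance(sess, win, mode="trials")
        expected = oracles.naive_trial_covariance(sess.data, win.indices(sess.time))
        assert np.allclose(cov.matrix, expected, rtol=1e-12)

    def test_rank_deficiency_warns(self, rng):
        sess = make_session(rng.standard_normal((6, 8, 200)))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            bf.compute_covariance(sess, TimeWindow(-0.2, -0.18), mode="averaged")


class TestRegularize:
    def test_zero_tikhonov_is_identity(self, rng):
        cov = bf.Covariance(matrix=random_spd(5, rng))
        out = bf.regularize(cov, "tikhonov", 0.0)
        assert np.array_equal(out.matrix, cov.matrix)

    def test_min_eig_adds_smallest_eigenvalue(self, rng):
        cov = bf.Covariance(matrix=random_spd(4, rng))
        unavg = bf.Covariance(matrix=3.0 * np.eye(4))
        out = bf.regularize(cov, "min_eig", unaveraged=unavg)
        assert np.allclose(out.matrix, cov.matrix + 3.0 * np.eye(4), rtol=1e-12)

    def test_min_eig_requires_unaveraged(self, rng):
        cov = bf.Covariance(matrix=random_spd(4, rng))
        with pytest.raises(ValueError, match="unaveraged"):
            bf.regularize(cov, "min_eig")

    def test_tikhonov_improves_conditioning(self, rng):
        x = rng.standard_normal((6, 2))
        cov = bf.Covariance(matrix=x @ x.T)  # rank 2 of 6
        out = bf.regularize(cov, "tikhonov", 0.01)
        assert out.condition_number() < cov.condition_number()


class TestLCMVWeights:
    def test_identity_cov_basis_leadfield(self):
        L = np.zeros((5, 1))
        L[0, 0] = 1.0
        filt = bf.lcmv_weights(single_voxel_lf(L), bf.Covariance(matrix=np.eye(5)))
        assert np.allclose(filt.weights[0], L)
        assert filt.weights[0, :, 0] @ L[:, 0] == pytest.approx(1.0)

    def test_unit_gain_identity(self, rng):
        # Eq-1 constraint: W^T L = I for any SPD covariance
        for _ in range(10):
            nc = int(rng.integers(6, 21))
            L = rng.standard_normal((nc, 3))
            R = random_spd(nc, rng, cond=1e3)
            filt = bf.lcmv_weights(single_voxel_lf(L), bf.Covariance(matrix=R))
            gain = filt.weights[0].T @ L
            assert np.abs(gain - np.eye(3)).max() < 1e-8

    def test_matches_naive_inverse_oracle(self, rng):
        L = rng.standard_normal((6, 3))
        R = random_spd(6, rng)
        filt = bf.lcmv_weights(single_voxel_lf(L), bf.Covariance(matrix=R))
        W_ref = oracles.naive_lcmv(L, R)
        assert np.abs(filt.weights[0] - W_ref).max() < 1e-10 * np.abs(W_ref).max()

    def test_scale_equivariance(self, rng):
        L = rng.standard_normal((8, 3))
        R = random_spd(8, rng)
        lf = single_voxel_lf(L)
        w1 = bf.lcmv_weights(lf, bf.Covariance(matrix=R)).weights
        w2 = bf.lcmv_weights(lf, bf.Covariance(matrix=7.5 * R)).weights
        assert np.abs(w1 - w2).max() < 1e-10 * np.abs(w1).max()

    def test_zero_leadfield_voxel_flagged(self):
        filt = bf.lcmv_weights(
            single_voxel_lf(np.zeros((4, 3))), bf.Covariance(matrix=np.eye(4))
        )
        assert filt.flagged == (0,)
        assert np.all(filt.weights == 0)


class TestScalarOrientation:
    def test_recovers_dipole_orientation(self, leadfield, grid, sensors):
        true_vox = grid.nearest([0.01, -0.01, 0.05])
        tang = tangential(grid.positions[true_vox])
        dip = sim.DipoleSpec(true_vox, tang, sim.EvokedWaveform(0.15, 0.04, 10e-9, freq=10.0))
        noise = sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=0, snr=10.0,
                              snr_window=TimeWindow(0.05, 0.25))
        sess, _ = sim.simulate_session(
            [dip], noise, leadfield, sensors, 50, 250.0, (-0.3, 0.5), seed=11
        )
        cov = bf.regularize(
            bf.compute_covariance(sess, TimeWindow(0.05, 0.25)), "tikhonov", 0.001
        )
        lf_scalar, _ = bf.scalar_orientation(leadfield, cov)
        ori = lf_scalar.orientations[true_vox]
        angle = np.degrees(np.arccos(min(1.0, abs(ori @ tang))))
        assert angle < 5.0

    def test_isotropic_voxel_flagged_degenerate(self, rng):
        L, _ = np.linalg.qr(rng.standard_normal((6, 3)))  # L^T L = I
        lf = single_voxel_lf(L)
        _, degen = bf.scalar_orientation(lf, bf.Covariance(matrix=np.eye(6)))
        assert degen == [0]

    def test_invariant_to_covariance_scaling(self, rng):
        L = rng.standard_normal((8, 3))
        R = random_spd(8, rng)
        lf = single_voxel_lf(L)
        a, _ = bf.scalar_orientation(lf, bf.Covariance(matrix=R))
        b, _ = bf.scalar_orientation(lf, bf.Covariance(matrix=4.2 * R))
        assert np.allclose(a.orientations, b.orientations, atol=1e-9)


class TestEigenspace:
    def test_full_rank_projection_is_identity(self, rng):
        nc = 8
        L = rng.standard_normal((nc, 3))
        R = random_spd(nc, rng)
        filt = bf.lcmv_weights(single_voxel_lf(L), bf.Covariance(matrix=R))
        out = bf.eigenspace_project(filt, bf.Covariance(matrix=random_spd(nc, rng)), nc)
        assert np.abs(out.weights - filt.weights).max() < 1e-10 * np.abs(filt.weights).max()

    def test_invalid_rank_rejected(self, rng):
        filt = bf.lcmv_weights(
            single_voxel_lf(rng.standard_normal((5, 3))), bf.Covariance(matrix=np.eye(5))
        )
        cov = bf.Covariance(matrix=np.eye(5))
        with pytest.raises(ValueError):
            bf.eigenspace_project(filt, cov, 0)
        with pytest.raises(ValueError):
            bf.eigenspace_project(filt, cov, 6)

    def test_projection_improves_evoked_snr(self, leadfield, grid, sensors):
        # rank-1 evoked source: the signal-subspace-projected virtual
        # electrode has at least the SNR of the unprojected one
        true_vox = grid.nearest([0.01, -0.01, 0.05])
        tang = tangential(grid.positions[true_vox])
        dip = sim.DipoleSpec(true_vox, tang, sim.EvokedWaveform(0.15, 0.04, 10e-9, freq=10.0))
        win = TimeWindow(0.05, 0.25)
        noise = sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=20, brain_amplitude=1.0,
                              snr=2.0, snr_window=win)
        sess, truth = sim.simulate_session(
            [dip], noise, leadfield, sensors, 60, 250.0, (-0.3, 0.5), seed=5
        )
        cov = bf.regularize(bf.compute_covariance(sess, win), "tikhonov", 0.001)
        cov_avg = bf.compute_covariance(sess, win, mode="averaged")
        lf_scalar, _ = bf.scalar_orientation(leadfield, cov)
        filt = bf.lcmv_weights(lf_scalar, cov)
        filt_es = bf.eigenspace_project(filt, cov_avg, 1)
        from megbeam.session import average_trials

        avg = average_trials(sess)
        base = TimeWindow(-0.3, -0.05)

        def voxel_snr(f):
            est = bf.apply_weights(f, avg)
            trace = est.data[0, true_vox, 0]
            sig = np.sqrt(np.mean(trace[win.mask(est.time)] ** 2))
            noi = np.sqrt(np.mean(trace[base.mask(est.time)] ** 2))
            return sig / noi

        assert voxel_snr(filt_es) >= voxel_snr(filt)


class TestSuppression:
    def test_zone_response_nulled(self, leadfield, rng):
        cov = bf.Covariance(matrix=random_spd(leadfield.n_channels, rng))
        zone = bf.SuppressionZone((3,))
        filt = bf.suppression_weights(leadfield, cov, zone, target_voxel=40)
        W = filt.weights[0]
        resp = W.T @ leadfield.gain[3]
        assert np.abs(resp).max() < 1e-10 * np.abs(W).max() * np.abs(leadfield.gain[3]).max()

    def test_empty_zone_equals_plain_lcmv(self, leadfield, rng):
        cov = bf.Covariance(matrix=random_spd(leadfield.n_channels, rng))
        filt_z = bf.suppression_weights(leadfield, cov, bf.SuppressionZone(()), 40)
        filt_p = bf.lcmv_weights(leadfield, cov)
        # the suppression solver works in the observable subspace of the
        # target; compare reconstructed weight spans via output power
        p_z = filt_z.weights[0] @ filt_z.weights[0].T
        p_p = filt_p.weights[40] @ filt_p.weights[40].T
        assert np.allclose(p_z, p_p, atol=1e-8 * np.abs(p_p).max())

    def test_target_inside_zone_rejected(self, leadfield, rng):
        cov = bf.Covariance(matrix=random_spd(leadfield.n_channels, rng))
        with pytest.raises(ValueError, match="inside"):
            bf.suppression_weights(leadfield, cov, bf.SuppressionZone((7,)), 7)

    def test_correlated_pair_recovered_with_zone(self, sensors):
        # the classic failure mode: fully correlated bilateral sources
        sphere = fwd.SphereModel(centre=np.zeros(3), radius=0.09)
        g = fwd.VoxelGrid.from_box([(-0.045, 0.045), (-0.015, 0.015), (0.035, 0.065)], 0.005)
        lf = fwd.leadfield_meg_sphere(sphere, g, sensors)
        vA = g.nearest([-0.035, 0, 0.05])
        vB = g.nearest([0.035, 0, 0.05])
        win = TimeWindow(0.05, 0.25)
        noise = sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=30, brain_amplitude=1.0,
                              snr=10.0, snr_window=win)
        sess, _ = sim.simulate_correlated_pair(
            [vA, vB], [tangential(g.positions[vA]), tangential(g.positions[vB])],
            1.0, noise, lf, sensors, 100, 250.0, (-0.3, 0.5), seed=2,
        )
        cov = bf.regularize(bf.compute_covariance(sess, win), "tikhonov", 0.001)
        zone_vox = np.nonzero(np.linalg.norm(g.positions - g.positions[vB], axis=1) <= 0.0121)[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smap = bf.suppression_scan(lf, cov, bf.SuppressionZone(tuple(int(v) for v in zone_vox)))
        err = np.linalg.norm(g.positions[int(np.nanargmax(smap))] - g.positions[vA])
        assert err <= g.spacing + 1e-9


class TestSourceStability:
    def test_deterministic_given_seed(self, leadfield, sensors, rng):
        sess, _ = sim.simulate_session(
            [], sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=0), leadfield, sensors,
            8, 250.0, (-0.2, 0.3), seed=1,
        )
        cov = bf.regularize(bf.compute_covariance(sess, TimeWindow(0.0, 0.3)), "tikhonov", 0.01)
        a = bf.source_stability_index(sess, leadfield, cov, n_splits=1, seed=9)
        b = bf.source_stability_index(sess, leadfield, cov, n_splits=1, seed=9)
        assert np.array_equal(a, b)

    def test_too_few_trials_rejected(self, leadfield, sensors):
        sess, _ = sim.simulate_session(
            [], sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=0), leadfield, sensors,
            3, 250.0, (-0.2, 0.3), seed=1,
        )
        cov = bf.compute_covariance(sess, TimeWindow(0.0, 0.3))
        with pytest.raises(ValueError, match="4 trials"):
            bf.source_stability_index(sess, leadfield, cov)

    def test_requires_trials_covariance(self, leadfield, sensors):
        sess, _ = sim.simulate_session(
            [], sim.NoiseSpec(sensor_sigma=1.0, n_brain_dipoles=0), leadfield, sensors,
            6, 250.0, (-0.2, 0.3), seed=1,
        )
        cov = bf.compute_covariance(sess, TimeWindow(0.0, 0.3), mode="averaged")
        with pytest.raises(ValueError, match="unaveraged"):
            bf.source_stability_index(sess, leadfield, cov)


class TestApplyWeights:
    def test_one_hot_weights_copy_channel(self, rng):
        sess = make_session(rng.standard_normal((2, 4, 50)))
        W = np.zeros((1, 4, 1))
        W[0, 2, 0] = 1.0
        filt = bf.SpatialFilter(weights=W, channel_names=sess.sensors.names, method="test")
        est = bf.apply_weights(filt, sess)
        assert np.array_equal(est.data[:, 0, 0, :], sess.data[:, 2, :])

    def test_zero_data_gives_zero_sources(self, leadfield):
        sess = make_session(np.zeros((1, leadfield.n_channels, 20)),
                            sensors_=None)
        filt = bf.lcmv_weights(leadfield, bf.Covariance(matrix=np.eye(leadfield.n_channels)))
        filt = bf.SpatialFilter(weights=filt.weights, channel_names=sess.sensors.names,
                                method="lcmv")
        assert np.all(bf.apply_weights(filt, sess).data == 0)

    def test_matches_naive_dot_product_loop(self, rng):
        sess = make_session(rng.standard_normal((2, 5, 30)))
        W = rng.standard_normal((3, 5, 3))
        filt = bf.SpatialFilter(weights=W, channel_names=sess.sensors.names, method="test")
        est = bf.apply_weights(filt, sess)
        for t in range(2):
            for v in range(3):
                for k in range(3):
                    for s in range(0, 30, 7):
                        expected = float(W[v, :, k] @ sess.data[t, :, s])
                        assert est.data[t, v, k, s] == pytest.approx(expected, rel=1e-12)

    def test_channel_mismatch_reported(self, rng):
        sess = make_session(rng.standard_normal((1, 3, 20)))
        W = np.zeros((1, 2, 1))
        filt = bf.SpatialFilter(weights=W, channel_names=("X1", "X2"), method="test")
        with pytest.raises(ValueError, match="X1"):
            bf.apply_weights(filt, sess)
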