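import numpy as np
import pytest

from tectal import (
    SynthSpec,
    Track,
    TrackSet,
    ValidationError,
    convergence,
    discrete_frechet,
    displacement_field,
    fit_msd_powerlaw,
    frechet_null,
    gen_tracks,
    linearise,
    msd,
    normalise_polar,
    track_summary,
)
from conftest import frechet_brute_force, random_walk_set


class TestMsd:
    def test_ballistic_closed_form(self, ballistic_track):
        ts = TrackSet([ballistic_track], frame_interval=1.0)
        res = msd(ts)
        speed2 = 1.0**2 + 0.5**2
        np.testing.assert_allclose(res.msd, speed2 * res.lags**2, rtol=1e-12)
        alpha, d_eff, r2 = fit_msd_powerlaw(res)
        assert alpha == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_stationary_track_zero_msd_and_fit_refused(self, stationary_track):
        ts = TrackSet([stationary_track], frame_interval=1.0)
        res = msd(ts)
        np.testing.assert_array_equal(res.msd, 0.0)
        with pytest.raises(ValidationError, match="refused"):
            fit_msd_powerlaw(res)

    def test_random_walk_recovers_diffusion(self):
        # per-axis step variance 2 D dt => MSD = 4 D tau
        D, dt = 0.5, 1.0
        ts = random_walk_set(1000, 64, np.sqrt(2 * D * dt), seed=7, dt=dt)
        res = msd(ts)
        alpha, d_eff, _ = fit_msd_powerlaw(res)
        assert 0.9 < alpha < 1.1
        assert abs(d_eff - D) / D < 0.10

    def test_non_uniform_sampling_rejected(self):
        tr = Track("x", t=[0.0, 1.0, 3.0], xy=np.zeros((3, 2)) + [[0], [1], [2]])
        with pytest.raises(ValidationError, match="non-uniform"):
            msd(TrackSet([tr]))

    def test_rigid_transform_invariance(self):
        ts = random_walk_set(20, 32, 1.0, seed=3)
        base_alpha, base_d, _ = fit_msd_powerlaw(msd(ts))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = TrackSet(
            [Track(tr.track_id, tr.t, tr.xy @ R.T + [37.0, -11.0])
             for tr in ts],
            frame_interval=ts.frame_interval,
        )
        alpha, d_eff, _ = fit_msd_powerlaw(msd(moved))
        assert alpha == pytest.approx(base_alpha, abs=1e-9)
        assert d_eff == pytest.approx(base_d, rel=1e-9)

    def test_powerlaw_fit_on_noisy_superdiffusive_series(self):
        from tectal.tracks import MSDResult

        rng = np.random.default_rng(5)
        lags = np.arange(1.0, 40.0)
        curve = lags**1.5 * (1 + rng.normal(0, 0.01, len(lags)))
        res = MSDResult(lags=lags, msd=curve, n_tracks=1)
        alpha, _, _ = fit_msd_powerlaw(res)
        assert alpha == pytest.approx(1.50, abs=0.02)

    def test_exact_powerlaw_conventions(self):
        from tectal.tracks import MSDResult

        lags = np.arange(1.0, 20.0)
        alpha, d_eff, _ = fit_msd_powerlaw(
            MSDResult(lags=lags, msd=4.0 * lags, n_tracks=1)
        )
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert d_eff == pytest.approx(1.0, rel=1e-12)
        alpha2, _, _ = fit_msd_powerlaw(
            MSDResult(lags=lags, msd=lags**2, n_tracks=1)
        )
        assert alpha2 == pytest.approx(2.0, abs=1e-12)


class TestTrackSummary:
    def test_collinear_track_straightness_one(self):
        tr = Track("c", t=[0.0, 1, 2], xy=[[0, 0], [1, 0], [2, 0]])
        assert track_summary(tr).straightness == pytest.approx(1.0)

    def test_closed_loop_straightness_zero(self):
        tr = Track("loop", t=np.arange(5.0),
                   xy=[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        assert track_summary(tr).straightness == pytest.approx(0.0)

    def test_right_angle_value(self):
        tr = Track("L", t=[0.0, 1, 2], xy=[[0, 0], [1, 0], [1, 1]])
        s = track_summary(tr)
        assert s.straightness == pytest.approx(np.sqrt(2) / 2)
        assert s.path_length == pytest.approx(2.0)
        assert s.net_displacement == pytest.approx(np.sqrt(2))

    def test_z_displacement_3d_only(self):
        tr3 = Track("z", t=[0.0, 1], xy=[[0, 0, 0], [0, 0, 5]])
        assert track_summary(tr3).z_displacement == pytest.approx(5.0)
        tr2 = Track("p", t=[0.0, 1], xy=[[0, 0], [1, 1]])
        assert track_summary(tr2).z_displacement is None

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            track_summary(Track("s", t=[0.0], xy=[[0, 0]]))


class TestLinearise:
    def test_parallel_motion_has_no_normal_component(self):
        curve = np.array([[0, 0], [100, 0]], float)
        tr = Track("p", t=[0.0, 1], xy=[[10, 5], [20, 5]])
        lin = linearise(tr, curve)
        assert lin.d_normal == pytest.approx(0.0, abs=1e-12)
        assert lin.d_tangential == pytest.approx(10.0)

    def test_perpendicular_motion_has_no_tangential_component(self):
        curve = np.array([[0, 0], [100, 0]], float)
        tr = Track("p", t=[0.0, 1], xy=[[10, 5], [10, 15]])
        lin = linearise(tr, curve)
        assert lin.d_tangential == pytest.approx(0.0, abs=1e-12)
        assert lin.d_normal == pytest.approx(10.0)  # +90 deg CCW from +x is +y

    def test_quarter_circle_arc_length(self):
        # dense polyline on a quarter circle radius 50; the probe point sits
        # radially above a polyline vertex (30 deg) so its projection foot is
        # exact and s0 converges to R*theta at the vertex density used
        theta = np.linspace(0, np.pi / 2, 3001)
        curve = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        ang = theta[1000]
        assert ang == pytest.approx(np.deg2rad(30.0), abs=1e-12)
        start = 55.0 * np.array([np.cos(ang), np.sin(ang)])
        tr = Track("arc", t=[0.0, 1], xy=[start, start + [1.0, 0]])
        lin = linearise(tr, curve)
        assert lin.s0 == pytest.approx(50.0 * ang, rel=1e-6)
        assert abs(lin.lateral0) == pytest.approx(5.0, rel=1e-6)

    def test_decomposition_preserves_net_displacement(self):
        rng = np.random.default_rng(2)
        curve = np.cumsum(rng.uniform(0.5, 2.0, size=(10, 2)), axis=0)
        for _ in range(20):
            a, b = rng.normal(0, 10, 2), rng.normal(0, 10, 2)
            tr = Track("r", t=[0.0, 1], xy=[a, a + b])
            lin = linearise(tr, curve)
            assert lin.d_tangential**2 + lin.d_normal**2 == pytest.approx(
                float(b @ b), rel=1e-6
            )


class TestDisplacementField:
    def test_vectors_and_zero_flags(self):
        tr1 = Track("a", t=[0.0, 1], xy=[[0, 0], [3, 4]])
        tr2 = Track("b", t=[0.0, 1], xy=[[5, 5], [5, 5]])
        field = displacement_field(TrackSet([tr1, tr2]))
        np.testing.assert_allclose(field[0].vector, [3, 4])
        assert not field[0].is_zero
        assert field[1].is_zero


class TestConvergence:
    def rays_to(self, target, starts):
        tracks = []
        for i, s in enumerate(starts):
            s = np.asarray(s, float)
            end = s + 0.5 * (np.asarray(target) - s)
            tracks.append(Track(f"r{i}", t=[0.0, 1], xy=[s, end]))
        return TrackSet(tracks)

    def test_two_rays_hit_planted_point(self, geometry):
        target = np.array(geometry.injury_center)
        ts = self.rays_to(target, [target + [-30, 5], target + [10, 25]])
        res = convergence(displacement_field(ts), geometry)
        assert res.defined
        np.testing.assert_allclose(res.centroid, target, atol=1e-9)

    def test_parallel_rays_undefined(self, geometry):
        c = np.array(geometry.origin)
        tracks = [
            Track("p1", t=[0.0, 1], xy=[c + [0, 5], c + [5, 5]]),
            Track("p2", t=[0.0, 1], xy=[c + [0, 15], c + [5, 15]]),
        ]
        res = convergence(displacement_field(TrackSet(tracks)), geometry)
        assert not res.defined

    def test_noisy_radial_tracks_recover_centre(self, geometry):
        rng = np.random.default_rng(19)
        target = np.array(geometry.injury_center)
        tracks = []
        for i in range(20):
            ang = rng.uniform(0, 2 * np.pi)
            s = target + rng.uniform(25, 45) * np.array([np.cos(ang), np.sin(ang)])
            end = s + 0.4 * (target - s) + rng.normal(0, 1.0, 2)
            tracks.append(Track(f"n{i}", t=[0.0, 1], xy=[s, end]))
        res = convergence(displacement_field(TrackSet(tracks)), geometry)
        assert res.defined
        assert np.linalg.norm(np.array(res.centroid) - target) < 5.0

    def test_translation_equivariance(self, geometry):
        target = np.array(geometry.injury_center)
        starts = [target + [-30, 5], target + [10, 25], target + [5, -20]]
        ts = self.rays_to(target, starts)
        res = convergence(displacement_field(ts), geometry)
        shift = np.array([3.0, -2.0])
        moved = TrackSet(
            [Track(tr.track_id, tr.t, tr.xy + shift) for tr in ts]
        )
        res2 = convergence(displacement_field(moved), geometry)
        np.testing.assert_allclose(
            np.array(res2.centroid), np.array(res.centroid) + shift, atol=1e-9
        )


class TestNormalisePolar:
    def circle_geometry(self):
        from tectal import TectumGeometry

        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        outline = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        inner = 0.5 * outline
        band = np.vstack([0.9 * outline, 0.6 * outline[::-1]])
        return TectumGeometry(
            tectum_outline=outline, pvz_band=band, neuropil_region=inner,
            rostrocaudal_curve=0.75 * outline[:128], injury_center=(75.0, 0.0),
            injury_radius=10.0, origin=(0.0, 0.0), rostral_axis=(1.0, 0.0),
        )

    def test_point_on_outline_r_is_one(self):
        g = self.circle_geometry()
        r, th = normalise_polar((100.0, 0.0), g)
        assert r == pytest.approx(1.0, rel=1e-3)
        assert th == pytest.approx(0.0, abs=1e-9)

    def test_origin_maps_to_zero(self):
        g = self.circle_geometry()
        assert normalise_polar((0.0, 0.0), g) == (0.0, 0.0)

    def test_half_radius_on_axis(self):
        g = self.circle_geometry()
        r, th = normalise_polar((50.0, 0.0), g)
        assert r == pytest.approx(0.5, rel=1e-3)
        assert th == pytest.approx(0.0, abs=1e-9)

    def test_angle_sign_and_magnitude(self):
        g = self.circle_geometry()
        _, th = normalise_polar((0.0, 60.0), g)
        assert th == pytest.approx(90.0)


class TestDiscreteFrechet:
    def test_identical_sequences_zero(self):
        P = np.array([[0, 0], [1, 1], [2, 0]], float)
        assert discrete_frechet(P, P) == 0.0

    def test_parallel_offset_segments(self):
        P = np.array([[0, 0], [1, 0], [2, 0]], float)
        Q = P + [0, 1]
        assert discrete_frechet(P, Q) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n, m = rng.integers(1, 7, size=2)
            P = rng.normal(0, 5, size=(n, 2))
            Q = rng.normal(0, 5, size=(m, 2))
            assert discrete_frechet(P, Q) == pytest.approx(
                frechet_brute_force(P, Q), rel=1e-12
            )

    def test_metric_properties(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            P = rng.normal(0, 3, size=(rng.integers(2, 6), 2))
            Q = rng.normal(0, 3, size=(rng.integers(2, 6), 2))
            d = discrete_frechet(P, Q)
            assert d >= 0
            assert d == pytest.approx(discrete_frechet(Q, P), rel=1e-12)
            assert d >= np.linalg.norm(P[0] - Q[0]) - 1e-12
            assert d >= np.linalg.norm(P[-1] - Q[-1]) - 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            discrete_frechet(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestFrechetNull:
    def make_pair(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 1.0, size=(30, 2)) + [0.5, 0.2]
        mg = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        t = np.arange(31.0)
        # neuron track: smoothed copy of the microglial track
        kernel = np.ones(5) / 5
        neuron = np.column_stack(
            [np.convolve(mg[:, 0], kernel, mode="same"),
             np.convolve(mg[:, 1], kernel, mode="same")]
        )
        return (Track("mg", t=t, xy=mg, cell_type="microglia"),
                Track("nn", t=t, xy=neuron, cell_type="neuron"))

    def test_identical_tracks_minimal_p(self):
        mg, _ = self.make_pair(0)
        res = frechet_null(mg, mg, n_perm=99, seed=1)
        assert res.distance == 0.0
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_matched_pair_beats_null(self):
        hits = 0
        for seed in range(20):
            mg, nn = self.make_pair(seed)
            res = frechet_null(mg, nn, n_perm=99, seed=seed)
            if res.distance < np.percentile(res.null_distances, 5):
                hits += 1
        assert hits >= 19

    def test_zero_permutations_rejected(self):
        mg, nn = self.make_pair(1)
        with pytest.raises(ValidationError):
            frechet_null(mg, nn, n_perm=0)


class TestInjuredVsUninjuredContrast:
    def test_directed_tracks_straighter_and_more_superdiffusive(self, geometry):
        inj = gen_tracks(SynthSpec(seed=4, motion_model="directed_oscillator",
                                   n_tracks=30, geometry=geometry))
        unin = gen_tracks(SynthSpec(seed=4, motion_model="jitter",
                                    n_tracks=30, geometry=geometry))
        s_inj = np.mean([track_summary(tr).straightness for tr in inj])
        s_unin = np.mean([track_summary(tr).straightness for tr in unin])
        assert s_inj > s_unin
        a_inj, _, _ = fit_msd_powerlaw(msd(inj))
        a_unin, _, _ = fit_msd_powerlaw(msd(unin))
        assert a_inj > a_unin
        assert a_inj > 1.5
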