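"""Ground-truth scene generator: paths, placement, evolution, rendering."""

import numpy as np
import pytest

import boutondyn as bd
from boutondyn.synthetic import (
    GroundTruthBouton,
    SceneConsistencyError,
    _classify_fate,
)


class TestGenerateAxonPath:
    def test_zero_tortuosity_is_straight(self):
        path = bd.generate_axon_path(10.0, tortuosity=0.0, step_um=0.5,
                                     seed=0)
        end_dist = np.linalg.norm(path.points[-1] - path.points[0])
        assert end_dist == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("tort", [0.0, 0.2, 0.5])
    def test_arc_length_within_one_step(self, tort):
        path = bd.generate_axon_path(200.0, tortuosity=tort, step_um=0.5,
                                     seed=1, field_um=(39.6, 39.6))
        assert 199.5 <= path.total_length <= 200.5

    def test_stays_inside_field(self):
        for seed in range(5):
            path = bd.generate_axon_path(
                200.0, tortuosity=0.3, seed=seed, field_um=(39.6, 39.6))
            assert path.points[:, 0].min() >= 0
            assert path.points[:, 0].max() <= 39.6
            assert path.points[:, 1].min() >= 0
            assert path.points[:, 1].max() <= 39.6

    def test_self_clearance_in_field(self):
        from scipy.spatial import cKDTree

        for seed in range(5):
            path = bd.generate_axon_path(
                200.0, tortuosity=0.3, seed=seed, field_um=(39.6, 39.6))
            rp = bd.resample_path(path, 0.1)
            tree = cKDTree(rp.samples)
            pairs = tree.query_pairs(1.8, output_type="ndarray")
            # only distant-in-arc pairs count as self-approach
            far = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 30]
            assert len(far) == 0

    def test_field_length_sampling_distribution(self):
        # lengths drawn as mean 213.4, SEM 13.4 over n=31 fields
        # (sd = SEM * sqrt(n)); the sample mean must sit within 3 SEM
        rng = np.random.default_rng(0)
        sd = 13.4 * np.sqrt(31)
        lengths = np.clip(rng.normal(213.4, sd, size=31), 30.0, None)
        paths = [
            bd.generate_axon_path(L, tortuosity=0.2, seed=i,
                                  field_um=(80.0, 80.0))
            for i, L in enumerate(lengths)
        ]
        realized = np.array([p.total_length for p in paths])
        assert abs(realized.mean() - 213.4) < 3 * 13.4 + 1.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            bd.generate_axon_path(-5.0)
        with pytest.raises(ValueError):
            bd.generate_axon_path(10.0, step_um=0.0)


class TestPlaceBoutons:
    def test_zero_density_empty(self, straight_path):
        params = bd.DynamicsParams(density=0.0)
        assert bd.place_boutons(straight_path, params, seed=0) == []

    def test_poisson_mean_count(self):
        # E[count] = density * L; 400 replicates of a 200 um axon
        pts = np.column_stack([np.linspace(0, 200, 401),
                               np.zeros(401), np.zeros(401)])
        path = bd.AxonPath(points=pts)
        params = bd.DynamicsParams(density=0.12)
        counts = [len(bd.place_boutons(path, params, seed=s))
                  for s in range(400)]
        expected = 0.12 * 200
        tol = 3 * np.sqrt(expected / 400)
        assert abs(np.mean(counts) - expected) < tol

    def test_min_spacing_enforced(self, straight_path):
        params = bd.DynamicsParams(density=0.3, min_spacing_um=2.0)
        for seed in range(5):
            pos = sorted(b.position_s for b in
                         bd.place_boutons(straight_path, params, seed=seed))
            gaps = np.diff(pos)
            assert np.all(gaps >= 2.0 - 1e-9)

    def test_weights_above_definitional_floor(self, straight_path):
        params = bd.DynamicsParams(density=0.3)
        boutons = bd.place_boutons(straight_path, params, seed=3)
        assert all(b.amplitude_by_session[0] > params.size_min
                   for b in boutons)


def _manual_population(n, amp=4.0, spacing=3.0):
    return [
        GroundTruthBouton(bouton_id=i, position_s=1.0 + i * spacing,
                          amplitude_by_session={0: amp})
        for i in range(n)
    ]


class TestEvolveSessions:
    def test_static_population_when_all_probabilities_zero(self):
        params = bd.DynamicsParams(
            formation_prob_per_interval=0.0,
            elimination_prob_per_interval=0.0, size_drift_sd=0.0)
        boutons = _manual_population(20)
        bd.evolve_sessions(boutons, params, 100.0, seed=0)
        for b in boutons:
            assert b.fate == "preexisting_persistent"
            amps = set(b.amplitude_by_session.values())
            assert amps == {4.0}

    def test_cumulative_survival_matches_binomial(self):
        # (1 - e)^3 = 0.85 over three intervals, N0 = 1000
        e = 1.0 - 0.85 ** (1.0 / 3.0)
        params = bd.DynamicsParams(
            formation_prob_per_interval=0.0,
            elimination_prob_per_interval=e, size_drift_sd=0.0)
        boutons = _manual_population(1000, spacing=2.0)
        bd.evolve_sessions(boutons, params, 2200.0, seed=1)
        frac = np.mean([b.present(7) for b in boutons])
        assert abs(frac - 0.85) < 3 * np.sqrt(0.85 * 0.15 / 1000)

    def test_formation_expectation(self):
        # E[new per interval] = formation_prob * N_prev
        params = bd.DynamicsParams(
            formation_prob_per_interval=0.1,
            elimination_prob_per_interval=0.0, size_drift_sd=0.0,
            session_days=(0, 2))
        n_new = []
        for seed in range(200):
            boutons = _manual_population(200, spacing=3.0)
            bd.evolve_sessions(boutons, params, 700.0, seed=seed)
            n_new.append(sum(1 for b in boutons if b.fate == "formed"))
        se = np.sqrt(200 * 0.1 * 0.9 / 200)
        assert abs(np.mean(n_new) - 20.0) < 3 * se

    def test_fates_consistent_with_amplitudes(self):
        params = bd.DynamicsParams(
            formation_prob_per_interval=0.15,
            elimination_prob_per_interval=0.15, reappear_prob=0.3)
        boutons = _manual_population(50, spacing=2.5)
        bd.evolve_sessions(boutons, params, 150.0, seed=5)
        days = params.session_days
        for b in boutons:
            amps = [b.amplitude_by_session.get(d, 0.0) for d in days]
            assert b.fate == _classify_fate(amps)
            if b.fate == "formed":
                assert amps[0] == 0.0


class TestRender:
    def test_shaft_only_normalization(self, straight_path, desk_imaging):
        # voxel max approaches the tube amplitude (a little below it:
        # voxel centres sample slightly off the centreline) and never
        # exceeds it
        stack = bd.render_stack(straight_path, [], 0, desk_imaging)
        assert stack.voxels.max() == pytest.approx(
            desk_imaging.shaft_amplitude, rel=0.10)
        assert stack.voxels.max() <= desk_imaging.shaft_amplitude * (1 + 1e-5)

    @pytest.mark.parametrize("w", [2.0, 3.0, 5.0, 8.0])
    def test_calibration_contract(self, straight_path, desk_imaging, w):
        """Noise-free render + detection recovers the true weight +-10%."""
        L = straight_path.total_length
        b = bd.GroundTruthBouton(bouton_id=0, position_s=L / 2,
                                 amplitude_by_session={0: w})
        stack = bd.render_stack(straight_path, [b], 0, desk_imaging)
        obs = bd.detect_stack(stack, bd.resample_path(straight_path, 0.1))
        assert len(obs) == 1
        assert obs[0].size == pytest.approx(w, rel=0.10)
        assert abs(obs[0].position_s - L / 2) < 0.2

    def test_superposition_bound(self, straight_path, desk_imaging):
        boutons = [
            bd.GroundTruthBouton(bouton_id=i, position_s=5.0 + 4 * i,
                                 amplitude_by_session={0: 4.0 + i})
            for i in range(4)
        ]
        stack = bd.render_stack(straight_path, boutons, 0, desk_imaging)
        assert stack.voxels.max() <= desk_imaging.shaft_amplitude * 7.0 * 1.01

    def test_off_path_bouton_rejected(self, straight_path, desk_imaging):
        b = bd.GroundTruthBouton(
            bouton_id=0, position_s=straight_path.total_length + 5.0,
            amplitude_by_session={0: 4.0})
        with pytest.raises(SceneConsistencyError):
            bd.render_stack(straight_path, [b], 0, desk_imaging)

    def test_determinism_identical_seeds(self):
        a = bd.generate_scene(11, length_um=60.0)
        b = bd.generate_scene(11, length_um=60.0)
        np.testing.assert_array_equal(a.path.points, b.path.points)
        assert len(a.boutons) == len(b.boutons)
        for ba, bb in zip(a.boutons, b.boutons):
            assert ba.amplitude_by_session == bb.amplitude_by_session
        sa = bd.render_scene(a)
        sb = bd.render_scene(b)
        for day in sa:
            np.testing.assert_array_equal(sa[day].voxels, sb[day].voxels)

    def test_poisson_noise_changes_voxels(self, straight_path):
        img = bd.ImagingParams.desk(noise_model="poisson")
        s1 = bd.render_stack(straight_path, [], 0, img, seed=1)
        s2 = bd.render_stack(straight_path, [], 0, img, seed=2)
        assert not np.array_equal(s1.voxels, s2.voxels)
        assert np.all(s1.voxels >= 0)


class TestWriteScene:
    def test_roundtrip_and_row_counts(self, tmp_path):
        scene = bd.generate_scene(5, length_um=60.0)
        files = bd.write_scene(scene, tmp_path / "s")
        # SWC round trip
        (path,) = bd.read_swc(files["trace"])
        np.testing.assert_allclose(path.points, scene.path.points, atol=1e-6)
        # TIFF round trip (bit exact)
        for day, tif in files["stacks"].items():
            stack = bd.read_stack(tif)
            np.testing.assert_array_equal(
                stack.voxels, files["rendered"][day].voxels)
        # ground-truth CSV: sessions x boutons rows
        import pandas as pd

        gt = pd.read_csv(files["ground_truth"])
        assert len(gt) == len(scene.boutons) * len(
            scene.dynamics.session_days)

    def test_empty_scene_valid_files(self, tmp_path):
        scene = bd.generate_scene(
            6, dynamics=bd.DynamicsParams(density=0.0), length_um=60.0)
        files = bd.write_scene(scene, tmp_path / "empty")
        import pandas as pd

        gt = pd.read_csv(files["ground_truth"])
        assert len(gt) == 0
        (path,) = bd.read_swc(files["trace"])
        assert path.total_length > 0
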