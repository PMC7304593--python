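"""Landmark alignment, cross-session matching and track building."""

import numpy as np
import pytest

import boutondyn as bd
from boutondyn.tracking import IDENTITY_TOL_UM

from conftest import make_obs


class TestSelectLandmarks:
    def test_identical_sessions_zero_offset(self):
        obs = make_obs(0, [(10, 4.0), (30, 5.0), (55, 3.5)])
        obs_b = make_obs(2, [(10, 4.0), (30, 5.0), (55, 3.5)])
        lset = bd.select_landmarks(obs, obs_b, axon_length=60.0)
        assert len(lset.landmarks) == 3
        assert not lset.fallback
        assert lset.offset_at(20.0) == pytest.approx(0.0)

    def test_constant_shift_recovered(self):
        obs_a = make_obs(0, [(10, 4.0), (30, 5.0), (55, 3.5)])
        obs_b = make_obs(2, [(10.5, 4.0), (30.5, 5.0), (55.5, 3.5)])
        lset = bd.select_landmarks(obs_a, obs_b, axon_length=60.0)
        assert lset.offset_at(32.0) == pytest.approx(0.5)

    def test_spurious_extra_bouton_ignored(self):
        """Mutual-nearest filtering: an unpaired extra bouton in session b
        does not perturb the landmark set (brute-force expectation: the
        three true pairs)."""
        obs_a = make_obs(0, [(10, 4.0), (30, 5.0), (55, 3.5)])
        obs_b = make_obs(2, [(10, 4.0), (28.4, 3.2), (30, 5.0), (55, 3.5)])
        lset = bd.select_landmarks(obs_a, obs_b, axon_length=60.0)
        pairs = {(lm.s_a, lm.s_b) for lm in lset.landmarks}
        assert pairs == {(10.0, 10.0), (30.0, 30.0), (55.0, 55.0)}

    def test_no_observations_flagged(self):
        lset = bd.select_landmarks([], make_obs(2, [(5, 4.0)]),
                                   axon_length=60.0)
        assert lset.fallback
        assert lset.offset_at(10.0) == 0.0

    def test_sparse_landmarks_fall_back(self):
        # one landmark on a 200 um axon is below one per 50 um
        obs_a = make_obs(0, [(100, 4.0)])
        obs_b = make_obs(2, [(100.3, 4.0)])
        lset = bd.select_landmarks(obs_a, obs_b, axon_length=200.0)
        assert lset.fallback


class TestMatchPair:
    def test_identical_positions_all_matched(self):
        obs = make_obs(0, [(5, 4.0), (12, 3.0), (20, 2.5)])
        obs_b = make_obs(2, [(5, 4.1), (12, 3.1), (20, 2.6)])
        res = bd.match_pair(obs, obs_b)
        assert len(res.pairs) == 3
        assert all(d == pytest.approx(0.0) for _, _, d in res.pairs)
        assert res.unmatched_a == [] and res.unmatched_b == []

    def test_displacement_at_tolerance_excluded(self):
        # 1.0 um displacement exceeds the strict 0.7 um tolerance
        obs_a = make_obs(0, [(10, 4.0)])
        obs_b = make_obs(2, [(11.0, 4.0)])
        res = bd.match_pair(obs_a, obs_b)
        assert res.pairs == []
        assert res.unmatched_a == [0] and res.unmatched_b == [0]

    def test_tolerance_is_strict(self):
        obs_a = make_obs(0, [(10, 4.0)])
        assert bd.match_pair(obs_a, make_obs(2, [(10.75, 4.0)])).pairs == []
        assert len(bd.match_pair(obs_a, make_obs(2, [(10.65, 4.0)])).pairs) == 1

    def test_nearest_of_two_candidates_wins(self):
        obs_a = make_obs(0, [(10, 4.0)])
        obs_b = make_obs(2, [(10.3, 4.0), (10.6, 4.0)])
        res = bd.match_pair(obs_a, obs_b)
        assert len(res.pairs) == 1
        assert res.pairs[0][1] == 0  # the 0.3 um candidate
        assert res.unmatched_b == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_under_session_swap(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.uniform(2.0, 5.0, size=8))
        obs_a = make_obs(0, [(p, 4.0) for p in pos])
        keep = rng.random(8) > 0.2
        obs_b = make_obs(2, [
            (p + rng.uniform(-0.4, 0.4), 4.0)
            for p, k in zip(pos, keep) if k
        ])
        fwd = bd.match_pair(obs_a, obs_b)
        rev = bd.match_pair(obs_b, obs_a)
        assert {(i, j) for i, j, _ in fwd.pairs} == \
            {(j, i) for i, j, _ in rev.pairs}

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_equals_optimal_assignment(self, seed):
        """Greedy matching agrees with brute-force optimal one-to-one
        assignment (max cardinality, then min total discrepancy) on
        instances with <= 10 boutons per session."""
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(1000 + seed)
        n = rng.integers(1, 11)
        pos = np.cumsum(rng.uniform(2.0, 6.0, size=n))
        keep = rng.random(n) > 0.15
        pos_b = pos[keep] + rng.uniform(-0.5, 0.5, size=keep.sum())
        obs_a = make_obs(0, [(p, 4.0) for p in pos])
        obs_b = make_obs(2, [(p, 4.0) for p in sorted(pos_b)])
        res = bd.match_pair(obs_a, obs_b)

        # oracle: rectangular assignment with forbidden pairs at high cost
        sa = np.array([o.position_s for o in obs_a])
        sb = np.array([o.position_s for o in obs_b])
        if sb.size:
            cost = np.abs(sa[:, None] - sb[None, :])
            big = 1e6
            cost = np.where(cost < IDENTITY_TOL_UM, cost, big)
            ri, ci = linear_sum_assignment(cost)
            oracle = {(i, j) for i, j in zip(ri, ci) if cost[i, j] < big}
        else:
            oracle = set()
        assert {(i, j) for i, j, _ in res.pairs} == oracle


class TestBuildTracks:
    days = (0, 2, 4, 7)

    def _tracks_from_sizes(self, sizes_by_day, pos=10.0, extra=None):
        obs_by_day = {}
        for d, size in zip(self.days, sizes_by_day):
            obs_by_day[d] = []
            if size is not None:
                obs_by_day[d] = make_obs(d, [(pos, size)])
            if extra:
                obs_by_day[d] += make_obs(d, extra.get(d, []))
        return bd.build_tracks(obs_by_day, axon_length=60.0)

    def test_persistent_track(self):
        (track,) = self._tracks_from_sizes([3.5, 3.4, 3.6, 3.3])
        assert track.preexisting
        assert all(track.status_by_session[d] == "present"
                   for d in self.days)
        assert track.included_in_analysis
        assert not track.ever_eliminated

    def test_elimination_and_reappearance_keep_identity(self):
        """Weight sequence 3.5, 1.0, 3.2, 3.3 at a fixed position: present,
        eliminated (below 1.3), reappeared, present — one identity."""
        tracks = self._tracks_from_sizes([3.5, 1.0, 3.2, 3.3])
        assert len(tracks) == 1
        t = tracks[0]
        assert [t.status_by_session[d] for d in self.days] == \
            ["present", "eliminated", "reappeared", "present"]
        assert t.preexisting

    def test_newly_formed_on_day_two(self):
        tracks = self._tracks_from_sizes([None, 3.4, 3.4, 3.4])
        assert len(tracks) == 1
        t = tracks[0]
        assert not t.preexisting
        assert t.formed_day == 2
        assert t.status_by_session[0] == "absent"
        assert t.status_by_session[2] == "present"

    def test_subthreshold_cannot_be_born_but_sustains(self):
        # a 1.6-weight detection cannot open a track...
        tracks = self._tracks_from_sizes([None, 1.6, 1.6, 1.6])
        assert tracks == []
        # ...but sustains an existing one (hysteresis)
        (t,) = self._tracks_from_sizes([3.5, 1.6, 1.6, 3.4])
        assert [t.status_by_session[d] for d in self.days] == \
            ["present"] * 4

    def test_vanished_track_marked_eliminated(self):
        (t,) = self._tracks_from_sizes([3.5, None, None, None])
        assert [t.status_by_session[d] for d in self.days] == \
            ["present", "eliminated", "eliminated", "eliminated"]

    def test_mismatched_day_raises(self):
        obs = {0: make_obs(2, [(5, 4.0)])}
        with pytest.raises(bd.tracking.ScheduleError):
            bd.build_tracks(obs)


class TestTracksToEvents:
    def test_hand_enumerated_toy(self):
        days = (0, 2, 4, 7)
        obs_by_day = {d: [] for d in days}
        # persistent bouton at 10
        for d, s in zip(days, [3.5, 3.4, 3.6, 3.3]):
            obs_by_day[d] += make_obs(d, [(10.0, s)])
        # eliminated during 0-2 at 20 (falls below 1.3)
        for d, s in zip(days, [3.5, 1.0, None, None]):
            if s is not None:
                obs_by_day[d] += make_obs(d, [(20.0, s)])
        # newly formed during 0-2 at 30
        for d, s in zip(days, [None, 3.4, 3.5, 3.4]):
            if s is not None:
                obs_by_day[d] += make_obs(d, [(30.0, s)])
        tracks = bd.build_tracks(obs_by_day, axon_length=40.0)
        ev = bd.tracks_to_events(tracks, days).set_index("day_start")
        assert ev.loc[0, "n_prev"] == 2       # both pre-existing boutons
        assert ev.loc[0, "n_formed"] == 1
        assert ev.loc[0, "n_eliminated"] == 1
        assert ev.loc[0, "n_next"] == 2

    def test_empty_tracks_zero_table(self):
        ev = bd.tracks_to_events([], (0, 2, 4, 7))
        assert (ev[["n_prev", "n_formed", "n_eliminated"]].values == 0).all()

    def test_conservation_on_synthetic_scenes(self):
        """n(later) = n(prev) + formed - eliminated on every scene
        without reappearances."""
        for seed in (21, 22, 23):
            scene = bd.generate_scene(seed, length_um=120.0)
            res = bd.analyze_scene(scene)
            ev = res.events
            assert (ev.n_next ==
                    ev.n_prev + ev.n_formed - ev.n_eliminated).all()
            assert (ev.n_reappeared == 0).all()


class TestFateRecovery:
    def test_fates_match_ground_truth_with_session_offsets(self):
        """With rigid per-session arc offsets <= 0.5 um the pipeline's
        track fates equal the generator's ground-truth fates."""
        dyn = bd.DynamicsParams(
            formation_prob_per_interval=0.12,
            elimination_prob_per_interval=0.10, size_drift_sd=0.03)
        offsets = {2: 0.3, 4: -0.4, 7: 0.2}
        for seed in (31, 32):
            scene = bd.generate_scene(
                seed, dynamics=dyn, length_um=150.0,
                arc_offset_by_session=offsets)
            res = bd.analyze_scene(scene)
            truth = {
                b.position_s: b for b in scene.boutons
                if max(b.amplitude_by_session.values()) > 3.05
            }
            matched = 0
            for t in res.tracks:
                if not t.included_in_analysis:
                    continue
                day0 = min(t.observations)
                pos = t.observations[day0][0] - sum(
                    offsets.get(d, 0.0) for d in (2, 4, 7) if d <= day0)
                near = min(truth, key=lambda p: abs(p - pos))
                if abs(near - pos) > 0.7:
                    continue
                b = truth[near]
                matched += 1
                assert t.preexisting == b.present(0)
                if b.fate == "preexisting_persistent":
                    assert not t.ever_eliminated
                if b.fate in ("preexisting_eliminated", "transient"):
                    assert t.ever_eliminated
            assert matched >= 0.8 * len(truth)
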