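import numpy as np
import pytest

import larvanav as ln


class TestFieldFrames:
    def test_frame_zero_is_blank_and_cells_never_decrease(self):
        frames, times = ln.generate_field_frames(seed=3)
        assert (frames[0] == 0.0).all()
        assert (np.diff(frames, axis=0) >= -1e-12).all()
        assert frames.min() >= 0.0 and frames.max() <= 1.0
        assert (np.diff(times) > 0).all()

    @pytest.mark.parametrize("side,axis,flip", [("left", 1, False), ("right", 1, True),
                                                ("bottom", 0, False), ("top", 0, True)])
    def test_source_side_mean_exceeds_far_side(self, side, axis, flip):
        frames, _ = ln.generate_field_frames(source_side=side, seed=3)
        for frame in frames[1:]:
            profile = frame.mean(axis=1 - axis)
            if flip:
                profile = profile[::-1]
            near = profile[: profile.size // 3].mean()
            far = profile[-profile.size // 3:].mean()
            assert near > far

    def test_exponential_profile_supported(self):
        frames, _ = ln.generate_field_frames(profile="exponential", seed=0)
        assert frames.max() <= 1.0
        with pytest.raises(ln.ValidationError):
            ln.generate_field_frames(profile="nope")

    def test_fifty_percent_contour_clears_the_walls(self):
        field = ln.make_plume_field(seed=1)
        final = field.frames[-1]
        high = final >= 0.5
        assert not high[:7, :].any() and not high[-7:, :].any()
        assert not high[:, :7].any() and not high[:, -7:].any()


class TestAgentSpec:
    def test_state_defaults_resolved(self):
        starved = ln.AgentSpec(state="starved")
        fed = ln.AgentSpec(state="fed")
        assert starved.pause_prob < fed.pause_prob
        assert starved.speed_log_mean > fed.speed_log_mean
        assert starved.wall_mode == "avoid" and fed.wall_mode == "follow"

    def test_wrong_knob_for_strategy_rejected(self):
        with pytest.raises(ln.ValidationError):
            ln.AgentSpec(strategy="chemokinesis", speed_gain_high=0.5, turn_gain_high=2.0)
        with pytest.raises(ln.ValidationError):
            ln.AgentSpec(strategy="anosmic", gradient_bias_deg=10.0)
        with pytest.raises(ln.ValidationError):
            ln.AgentSpec(strategy="klinokinesis")  # knob left neutral

    def test_for_strategy_sets_canonical_gains(self):
        assert ln.AgentSpec.for_strategy("chemokinesis").speed_gain_high == 0.5
        assert ln.AgentSpec.for_strategy("klinokinesis").turn_gain_high == 2.0
        assert ln.AgentSpec.for_strategy("chemotaxis").gradient_bias_deg == 20.0


class TestGeneration:
    def test_same_seed_identical_trajectory(self, plume):
        a = ln.generate_trajectory(ln.AgentSpec(), plume, phases=(60.0, 60.0), seed=7)
        b = ln.generate_trajectory(ln.AgentSpec(), plume, phases=(60.0, 60.0), seed=7)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_cohort_member_matches_solo_run(self, plume):
        spec = ln.CohortSpec(n=3, agent=ln.AgentSpec(), field=plume,
                             phases=(60.0, 60.0), seed=12)
        trajs, _ = ln.generate_cohort(spec)
        child = np.random.SeedSequence(12).spawn(3)[1]
        solo = ln.generate_trajectory(spec.agent, plume, phases=(60.0, 60.0), seed=child)
        np.testing.assert_array_equal(trajs[1].x, solo.x)
        np.testing.assert_array_equal(trajs[1].y, solo.y)

    def test_positions_stay_inside_arena(self, plume):
        tr = ln.generate_trajectory(ln.AgentSpec(state="fed"), plume,
                                    phases=(300.0, 300.0), seed=5)
        w, h = plume.arena
        assert (tr.x >= 0).all() and (tr.x <= w).all()
        assert (tr.y >= 0).all() and (tr.y <= h).all()

    def test_arena_mismatch_rejected(self, plume):
        agent = ln.AgentSpec(arena=(50.0, 50.0))
        with pytest.raises(ln.ValidationError):
            ln.generate_trajectory(agent, plume, seed=0)

    def test_round_trip_through_track_files(self, tmp_path, starved_cohort):
        trajs, _ = starved_cohort
        path = tmp_path / "cohort.csv"
        ln.write_tracks(trajs, path)
        back = ln.read_tracks(path)
        assert len(back) == len(trajs)
        np.testing.assert_array_equal(back[0].x, trajs[0].x)

    def test_ground_truth_sidecar(self, plume):
        spec = ln.CohortSpec(n=4, agent=ln.AgentSpec.for_strategy("chemokinesis"),
                             field=plume, phases=(60.0, 60.0), seed=1)
        _, truth = ln.generate_cohort(spec)
        assert list(truth["individual_id"]) == [f"ind{i:03d}" for i in range(4)]
        assert (truth["strategy"] == "chemokinesis").all()
        assert (truth["speed_gain_high"] == 0.5).all()


class TestGenerativeStructure:
    def test_anosmic_phases_statistically_identical(self, plume):
        from scipy import stats as sps
        tr = ln.generate_trajectory(ln.AgentSpec(), plume, seed=31)
        k = ln.derive_kinematics(tr, plume)
        acc = k.in_phase("acclimation") & k.valid
        exp = k.in_phase("experiment") & k.valid
        res = sps.ttest_ind(k.speed[acc], k.speed[exp], equal_var=False)
        assert res.pvalue > 0.01
        t_acc = k.turn[acc & ~np.isnan(k.turn)]
        t_exp = k.turn[exp & ~np.isnan(k.turn)]
        assert sps.ttest_ind(np.abs(t_acc), np.abs(t_exp), equal_var=False).pvalue > 0.01

    def test_chemokinetic_speed_ratio_matches_gain(self, plume):
        spec = ln.CohortSpec(n=6, agent=ln.AgentSpec.for_strategy("chemokinesis"),
                             field=plume, seed=17)
        trajs, _ = ln.generate_cohort(spec)
        hi_speeds, lo_speeds = [], []
        for tr in trajs:
            k = ln.derive_kinematics(tr, plume)
            m = k.in_phase("experiment") & k.valid & k.moving
            hi_speeds.append(k.speed[m & (k.c >= 0.5)])
            lo_speeds.append(k.speed[m & (k.c < 0.5)])
        ratio = np.concatenate(hi_speeds).mean() / np.concatenate(lo_speeds).mean()
        assert ratio == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("gain", [0.4, 0.7, 1.0])
    def test_speed_gain_recovered_across_settings(self, plume, gain):
        agent = (ln.AgentSpec.for_strategy("chemokinesis", speed_gain_high=gain)
                 if gain != 1.0 else ln.AgentSpec())
        spec = ln.CohortSpec(n=5, agent=agent, field=plume, phases=(400.0, 400.0), seed=23)
        trajs, _ = ln.generate_cohort(spec)
        hi, lo = [], []
        for tr in trajs:
            k = ln.derive_kinematics(tr, plume)
            m = k.in_phase("experiment") & k.valid & k.moving
            hi.append(k.speed[m & (k.c >= 0.5)])
            lo.append(k.speed[m & (k.c < 0.5)])
        ratio = np.concatenate(hi).mean() / np.concatenate(lo).mean()
        assert ratio == pytest.approx(gain, abs=0.1)

    def test_speed_turn_coupling_negative_and_stronger_when_fast(self, plume):
        spec = ln.CohortSpec(n=8, agent=ln.AgentSpec(), field=plume, seed=29)
        trajs, _ = ln.generate_cohort(spec)
        ks = [ln.derive_kinematics(t, plume) for t in trajs]
        pool = ln.build_pool(ks, include_nonmoving=False)
        speeds, turns = pool.speeds, np.abs(pool.turns)
        overall = np.corrcoef(speeds, turns)[0, 1]
        assert overall < 0
        med = np.median(speeds)
        above = speeds > med
        corr_above = np.corrcoef(speeds[above], turns[above])[0, 1]
        corr_below = np.corrcoef(speeds[~above], turns[~above])[0, 1]
        assert corr_above < 0
        assert corr_above < corr_below + 0.02

    def test_fed_starved_activity_contrast(self, plume):
        frames = {}
        for state, seed in (("fed", 41), ("starved", 43)):
            spec = ln.CohortSpec(n=8, agent=ln.AgentSpec(state=state), field=plume,
                                 phases=(400.0, 400.0), seed=seed)
            trajs, _ = ln.generate_cohort(spec)
            frames[state] = ln.metrics_frame(trajs, plume)
        assert frames["starved"]["moving_fraction_acc"].mean() > \
            frames["fed"]["moving_fraction_acc"].mean()
        assert frames["starved"]["wall_fraction_acc"].mean() < \
            frames["fed"]["wall_fraction_acc"].mean()


class TestEndToEnd:
    def test_chemokinesis_cohort_classified_exactly(self, plume):
        spec = ln.CohortSpec(n=30, agent=ln.AgentSpec.for_strategy("chemokinesis"),
                             field=plume, seed=2)
        trajs, _ = ln.generate_cohort(spec)
        _, results, call = ln.analyze_cohort(trajs, plume)
        assert (call.call, call.match) == ("chemokinesis", "exact")
        assert results["CS"].p_adj < 1e-10
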