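import math

import numpy as np
import pytest
from click.testing import CliRunner

import larvanav as ln
from larvanav.cli import main as cli_main


@pytest.fixture(scope="module")
def small_pools(plume):
    pools = {}
    for state, seed in (("fed", 100), ("starved", 101)):
        spec = ln.CohortSpec(n=4, agent=ln.AgentSpec(strategy="anosmic", state=state),
                             field=plume, phases=(400.0, 400.0), seed=seed)
        trajs, _ = ln.generate_cohort(spec)
        ks = [ln.derive_kinematics(t, plume) for t in trajs]
        pools[state] = ln.build_pool(ks, state=state)
    return pools


class TestPSlow:
    def test_half_at_boundary(self):
        assert ln.p_slow(0.5, 20.0) == pytest.approx(0.5)

    def test_logistic_value(self):
        # direct evaluation: 1 / (1 + e^-2)
        assert ln.p_slow(0.6, 20.0) == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=1e-12)
        assert ln.p_slow(0.6, 20.0) == pytest.approx(0.8808, abs=1e-4)

    def test_monotone_in_concentration(self):
        c = np.linspace(0, 1, 50)
        assert (np.diff(ln.p_slow(c, 20.0)) > 0).all()

    def test_hard_rule_in_steep_limit(self):
        assert ln.p_slow(0.51, 1e6) == pytest.approx(1.0)
        assert ln.p_slow(0.49, 1e6) == pytest.approx(0.0)


class TestPool:
    def test_even_split(self):
        p = ln.KinematicsPool([1.0, 2.0, 3.0, 4.0], [5.0, -5.0, 10.0, -10.0])
        np.testing.assert_array_equal(np.sort(p.slow_speeds), [1.0, 2.0])
        np.testing.assert_array_equal(np.sort(p.fast_speeds), [3.0, 4.0])

    def test_odd_count_tie_to_slow_half(self):
        p = ln.KinematicsPool([1.0, 2.0, 2.0, 2.0, 4.0], [0.0] * 5)
        assert p.slow_speeds.size == 3
        assert p.fast_speeds.size == 2
        assert p.slow_speeds.max() <= p.fast_speeds.min()

    def test_halves_partition_pool(self, small_pools):
        p = small_pools["starved"]
        assert p.slow_speeds.size + p.fast_speeds.size == len(p)
        assert p.slow_speeds.max() <= p.fast_speeds.min() + 1e-12

    def test_state_filter_and_phase_restriction(self, plume, small_pools):
        spec = ln.CohortSpec(n=2, agent=ln.AgentSpec(state="fed"), field=plume,
                             phases=(200.0, 200.0), seed=5)
        trajs, _ = ln.generate_cohort(spec)
        ks = [ln.derive_kinematics(t, plume) for t in trajs]
        pool = ln.build_pool(ks, state="fed")
        n_acc_steps = sum((k.in_phase("acclimation") & k.valid).sum() for k in ks)
        assert len(pool) == n_acc_steps
        with pytest.raises(ln.InsufficientDataError):
            ln.build_pool(ks, state="starved")

    def test_starved_pool_faster_than_fed(self, small_pools):
        assert small_pools["starved"].speeds.mean() > small_pools["fed"].speeds.mean()

    def test_csv_round_trip(self, tmp_path, small_pools):
        path = tmp_path / "pool.csv"
        ln.write_pool(small_pools["fed"], path)
        back = ln.read_pool(path)
        np.testing.assert_allclose(back.speeds, small_pools["fed"].speeds, atol=1e-9)
        assert back.state == "fed"


class TestSimulate:
    def test_straight_run_closed_form(self):
        # 10 mm/s toward the centre from 3 cm outside the patch: 3 s exactly
        pool = ln.KinematicsPool([10.0, 10.0], [0.0, 0.0], state="test")
        start = (ln.make_radial_field(20.0).food_radius + 3.0, 0.0)
        rec = ln.simulate_forager(pool, 20.0, ln.ForagingSimConfig(seed=1),
                                  start=start, heading=180.0)
        assert rec.discovery_time == pytest.approx(3.0)
        assert not rec.censored

    def test_zero_speed_pool_censors(self):
        pool = ln.KinematicsPool([0.0, 0.0], [3.0, -3.0], state="test")
        cfg = ln.ForagingSimConfig(seed=2, max_time=30.0)
        rec = ln.simulate_forager(pool, 10.0, cfg)
        assert rec.censored
        assert rec.discovery_time == 30.0

    def test_bit_identical_records_for_same_seed(self, small_pools):
        cfg = ln.ForagingSimConfig(seed=4, n_replicates=40, max_time=600.0)
        r1 = ln.simulate_batch(small_pools["starved"], 8.0, cfg)
        r2 = ln.simulate_batch(small_pools["starved"], 8.0, cfg)
        assert r1.equals(r2)
        assert ln.simulate_forager(small_pools["starved"], 8.0, cfg) == \
            ln.simulate_forager(small_pools["starved"], 8.0, cfg)

    def test_wall_jam_stands_still_instead_of_crashing(self):
        # a pool that can only swim hard and straight: jammed at the wall it
        # must wait, not raise
        pool = ln.KinematicsPool([10.0, 10.0], [0.5, -0.5], state="test")
        cfg = ln.ForagingSimConfig(seed=3, max_time=20.0, max_rejections=10)
        rec = ln.simulate_forager(pool, 6.0, cfg, start=(2.9, 0.0), heading=0.0)
        assert rec.discovery_time <= 20.0

    def test_inert_gate_when_halves_identical(self, small_pools):
        # identical halves make the slow/fast gate irrelevant: discovery-time
        # distributions under very different steepness agree
        sp = np.concatenate([small_pools["starved"].speeds] * 2)
        tn = np.concatenate([small_pools["starved"].turns] * 2)
        order = np.argsort(sp, kind="stable")
        pool = ln.KinematicsPool(sp[order], tn[order], state="test")
        means = []
        for k, seed in ((1.0, 11), (500.0, 12)):
            cfg = ln.ForagingSimConfig(seed=seed, n_replicates=250, smoothing_k=k)
            rec = ln.simulate_batch(pool, 6.0, cfg)
            means.append((rec.discovery_time.mean(),
                          rec.discovery_time.std(ddof=1) / np.sqrt(len(rec))))
        (m1, s1), (m2, s2) = means
        assert abs(m1 - m2) < 3.5 * math.hypot(s1, s2)

    def test_se_shrinks_with_replicates(self, small_pools):
        cfg1 = ln.ForagingSimConfig(seed=6, n_replicates=150)
        cfg2 = ln.ForagingSimConfig(seed=7, n_replicates=600)
        r1 = ln.simulate_batch(small_pools["starved"], 6.0, cfg1)
        r2 = ln.simulate_batch(small_pools["starved"], 6.0, cfg2)
        se1 = r1.discovery_time.std(ddof=1) / np.sqrt(len(r1))
        se2 = r2.discovery_time.std(ddof=1) / np.sqrt(len(r2))
        assert se1 / se2 == pytest.approx(2.0, rel=0.35)


class TestSweep:
    def test_default_diameters(self):
        d = np.asarray(ln.DEFAULT_DIAMETERS)
        assert d.size == 19
        assert d[0] == 5.0 and d[-1] == 20.0
        assert np.allclose(np.diff(d), d[1] - d[0])

    def test_summary_and_slopes(self, small_pools):
        cfg = ln.ForagingSimConfig(seed=5, n_replicates=60)
        res = ln.sweep(small_pools, diameters=(5.0, 9.0, 13.0), config=cfg)
        assert len(res.summary) == 6
        assert set(res.slopes) == {"fed", "starved"}
        # OLS slope recomputed by the normal equations
        sub = res.summary[res.summary.state == "fed"]
        x, ym = sub.diameter.to_numpy(), sub["mean"].to_numpy()
        slope = ((x - x.mean()) * (ym - ym.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slopes["fed"] == pytest.approx(slope, rel=1e-9)
        assert res.slope_difference == pytest.approx(res.slopes["fed"] - res.slopes["starved"])

    def test_cli_sweep_writes_outputs(self, tmp_path, small_pools):
        fed = tmp_path / "fed.csv"
        starved = tmp_path / "starved.csv"
        ln.write_pool(small_pools["fed"], fed)
        ln.write_pool(small_pools["starved"], starved)
        out = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "sweep", "--pool-fed", str(fed), "--pool-starved", str(starved),
            "--diameters", "5,8", "--reps", "20", "--seed", "1", "--out", str(out)])
        assert result.exit_code == 0, result.output
        for name in ("records.csv", "summary.csv", "slopes.json"):
            assert (out / name).exists()
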