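import numpy as np
import pytest
from scipy.stats import chisquare, pearsonr

from fissionfusion import (
    ArenaSpec,
    CalibrationError,
    SamplingSpec,
    VertexRuleConfig,
    WalkConfig,
    calibrate,
    density_experiment,
    simulate,
    simulate_frames,
    vertex_retreat_step,
)
from fissionfusion import _kernels
from fissionfusion.random_walk import iter_replicate_frames, social_time


def cfg(**kwargs):
    base = dict(n_agents=6, step=0.5, heading_change_prob=0.05, duration=30.0,
                seed=1)
    base.update(kwargs)
    return WalkConfig(**base)


class TestSimulate:
    def test_deterministic_from_seed(self):
        a = simulate_frames(cfg(seed=9))
        b = simulate_frames(cfg(seed=9))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, simulate_frames(cfg(seed=10)))

    def test_positions_inside_effective_arena(self):
        config = cfg(arena=ArenaSpec(area_scale=0.5), duration=60.0)
        frames = simulate_frames(config)
        assert frames.min() >= 0.0
        assert frames[..., 0].max() <= config.arena.effective_width
        assert frames[..., 1].max() <= config.arena.effective_height

    def test_per_tick_displacement_is_step(self):
        config = cfg(step=0.8, duration=20.0)
        frames = simulate_frames(config)
        # displacement equals the step except across a wall reflection, where
        # the unfolded distance is preserved; verify away from walls
        d = np.linalg.norm(np.diff(frames, axis=0), axis=-1)
        margin = 1.0
        inner = (
            (frames[:-1] > margin).all(axis=-1)
            & (frames[:-1] < 59.0).all(axis=-1)
            & (frames[1:] > margin).all(axis=-1)
            & (frames[1:] < 59.0).all(axis=-1)
        )
        assert np.allclose(d[inner], 0.8, atol=1e-9)

    def test_single_agent_social_time_zero(self):
        st, _ = social_time(cfg(n_agents=1), replicates=3, seed=0)
        assert st == 0.0

    def test_step_larger_than_arena_rejected(self):
        with pytest.raises(ValueError):
            cfg(step=61.0)

    def test_track_table_wrapping(self):
        table = simulate(cfg())
        assert table.n_individuals == 6
        assert table.n_frames == 150
        assert table.sample_rate == pytest.approx(5.0)

    def test_uniform_occupancy_over_grid_cells(self):
        # long single-agent run: occupancy of the 16 cells is uniform
        config = WalkConfig(n_agents=1, step=2.0, heading_change_prob=0.1,
                            duration=7200.0, seed=3)
        frames = simulate_frames(config)[:, 0, :]
        ix = np.clip((frames[:, 0] // 15).astype(int), 0, 3)
        iy = np.clip((frames[:, 1] // 15).astype(int), 0, 3)
        # thin to roughly independent visits: the cell-crossing time at
        # 10 cm/s is ~1.5 s, keep one sample per 10 s
        cells = (ix * 4 + iy)[::50]
        counts = np.bincount(cells, minlength=16)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_agents_move_independently(self):
        # frequent heading redraws keep the displacement series close to iid
        # so the plain-correlation bound is meaningful at this length
        config = cfg(n_agents=2, duration=360.0, seed=8, heading_change_prob=0.8)
        frames = simulate_frames(config)
        dx = np.diff(frames, axis=0)
        r, _ = pearsonr(dx[:, 0, 0], dx[:, 1, 0])
        assert abs(r) < 0.05


class TestVertexRetreatRule:
    def rule(self):
        return VertexRuleConfig(retreat_prob=1.0, radius=8.0)

    def test_interior_agent_never_fires(self, rng):
        square = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 20.0], [0.0, 20.0],
                           [10.0, 10.0]])
        fired, _ = vertex_retreat_step(square, 4, self.rule(), 0.5, rng, 0.0)
        assert not fired

    def test_vertex_with_close_neighbour_never_fires(self, rng):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [20.0, 0.0], [10.0, 20.0]])
        fired, _ = vertex_retreat_step(pts, 0, self.rule(), 0.5, rng, 0.0)
        assert not fired

    def test_collinear_hull_skips_rule(self, rng):
        pts = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 20.0]])
        fired, _ = vertex_retreat_step(pts, 0, self.rule(), 0.5, rng, 0.0)
        assert not fired

    def test_isolated_vertex_retreats_into_hull(self, rng):
        # over many random configurations the redirected next position lies
        # strictly inside the current hull
        from fissionfusion.group_geometry import hull_metrics

        checked = 0
        for _ in range(1000):
            pts = rng.uniform(0, 60, (8, 2))
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            np.fill_diagonal(d, np.inf)
            hull_idx = _kernels._hull_chain(
                pts[:, 0].copy(), pts[:, 1].copy(), np.empty(17, np.int64)
            )
            for agent in range(8):
                if d[agent].min() < 8.0:
                    continue
                fired, heading = vertex_retreat_step(
                    pts, agent, self.rule(), 0.5, rng, heading=-1.0
                )
                if not fired:
                    continue
                step_vec = 0.5 * np.array([np.cos(heading), np.sin(heading)])
                nxt = pts[agent] + step_vec
                others = np.delete(pts, agent, axis=0)
                # inside the hull of all current positions: the hull area is
                # unchanged when the next position is added
                per0, area0 = hull_metrics(pts)
                per1, area1 = hull_metrics(np.vstack([pts, nxt]))
                assert area1 <= area0 + 1e-9
                checked += 1
        assert checked > 200

    def test_rule_contracts_group_spread(self):
        base = cfg(n_agents=8, duration=60.0, seed=21)
        with_rule = WalkConfig(**{**base.__dict__, "rule": VertexRuleConfig()})
        areas = {}
        for name, config in (("free", base), ("rule", with_rule)):
            vals = []
            for frames in iter_replicate_frames(config, 15, 4):
                vals.append(_kernels.hull_metrics_frames(frames)[:, 1].mean())
            areas[name] = np.mean(vals)
        assert areas["rule"] < 0.75 * areas["free"]

    def test_zero_retreat_prob_matches_free_walk_statistics(self):
        base = cfg(n_agents=8, duration=60.0, seed=2)
        null_rule = WalkConfig(
            **{**base.__dict__, "rule": VertexRuleConfig(retreat_prob=0.0)}
        )
        means = {}
        for name, config in (("free", base), ("rule0", null_rule)):
            vals = [
                _kernels.hull_metrics_frames(f)[:, 1].mean()
                for f in iter_replicate_frames(config, 40, 6)
            ]
            means[name] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        diff = abs(means["free"][0] - means["rule0"][0])
        se = np.hypot(means["free"][1], means["rule0"][1])
        assert diff < 4 * se

    def test_compiled_and_interpreted_kernels_agree(self):
        rng = np.random.default_rng(0)
        n, ticks, k = 6, 60, 20
        args = (
            rng.uniform(0, 40, (n, 2)),
            rng.uniform(0, 2 * np.pi, n),
            0.5, 40.0, 40.0, 0.05, 0.8, 8.0,
            rng.random((ticks, n)),
            rng.uniform(0, 2 * np.pi, (ticks, n)),
            rng.random((ticks, n)),
            rng.uniform(0, 2 * np.pi, (ticks, n, k)),
        )
        # compiled and interpreted arithmetic may differ in the last ulp,
        # so agreement is asserted to a tolerance far below any physical scale
        assert np.allclose(
            _kernels.walk_with_rule(*args),
            _kernels.walk_with_rule_py(*args),
            atol=1e-9,
        )


class TestCalibration:
    def test_self_consistency_fixed_point(self):
        known = WalkConfig(n_agents=8, step=0.6, heading_change_prob=0.05,
                           duration=60.0, arena=ArenaSpec(area_scale=0.5))
        achieved, _ = social_time(known, replicates=30, seed=5)
        result = calibrate(
            achieved, 8, step=0.6, heading_change_prob=0.05,
            area_scales=[0.3, 0.4, 0.5, 0.65, 0.8],
            replicates=10, seed=5,
            arena=ArenaSpec(area_scale=1.0),
        )
        assert result.config.arena.area_scale == pytest.approx(0.5, abs=0.06)
        assert result.error <= 0.05

    def test_unreachable_target_raises_with_best(self):
        with pytest.raises(CalibrationError) as exc:
            calibrate(0.99, 4, step=0.5, heading_change_prob=0.05,
                      area_scales=[0.8, 1.0], replicates=4, seed=0)
        assert exc.value.best.error > 0.05

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate(1.2, 6)


@pytest.fixture(scope="module")
def comparison():
    config = WalkConfig(n_agents=12, step=0.7, heading_change_prob=0.03,
                        duration=90.0, arena=ArenaSpec(area_scale=0.75))
    return density_experiment(
        config, n_low=6, replicates_probabilities=12,
        replicates_geometry=25, seed=3,
    )


class TestDensityExperiment:

    def test_social_time_drops_with_density(self, comparison):
        assert comparison.social_time_low < comparison.social_time_high

    def test_p_leave_unchanged_within_monte_carlo_error(self, comparison):
        hi = comparison.estimates_high.p_leave_nn
        lo = comparison.estimates_low.p_leave_nn
        se = np.sqrt(
            hi.value * (1 - hi.value) / hi.denominator
            + lo.value * (1 - lo.value) / lo.denominator
        )
        assert abs(hi.value - lo.value) < 4 * se

    def test_low_density_social_time_matches_pairwise_independence(self):
        # measure the pair-proximity probability at n=12, then predict n=6
        config = WalkConfig(n_agents=12, step=0.7, heading_change_prob=0.03,
                            duration=180.0, arena=ArenaSpec(area_scale=0.75))
        spec = SamplingSpec()
        prox = []
        for frames in iter_replicate_frames(config, 20, 9):
            sampled = frames[::25]
            d = np.linalg.norm(sampled[:, :, None] - sampled[:, None], axis=-1)
            iu = np.triu_indices(12, 1)
            prox.append((d[:, iu[0], iu[1]] < spec.neighbour_radius).mean())
        a = np.mean(prox)
        predicted = 1 - (1 - a) ** 5
        measured, se = social_time(config.with_agents(6), 30, seed=10, spec=spec)
        assert abs(measured - predicted) < max(3 * se, 0.02)
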