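"""Correlated random-walk null model for fission-fusion dynamics.

Independent agents advance a fixed step per tick and, with a per-tick
probability, redraw their heading uniformly; walls reflect specularly.  Under
specular reflection with uniform initialisation the stationary occupancy is
exactly uniform (the per-tick update is a measure-preserving bijection of the
arena), which has a sharp consequence: the sampled social-time fraction of
independent walkers is a functional of occupancy alone and cannot be tuned by
step length or turning probability.  Encounter rate is therefore calibrated
through the effective arena scale - the density knob - while step and turning
probability set the movement and transition time scales (they are fixed from
observed swimming speeds and contact-phase turnover).

The optional vertex-retreat rule makes an agent that sits on the group's
convex hull with no conspecific within its social radius turn back into the
hull with a set probability; it is the candidate mechanism by which a group
contracts its spread without changing where it goes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .trajectories import ArenaSpec, TrackTable
from .social_states import SamplingSpec, nearest_neighbour_states

__all__ = [
    "VertexRuleConfig",
    "WalkConfig",
    "CalibrationResult",
    "CalibrationError",
    "simulate",
    "simulate_frames",
    "iter_replicate_frames",
    "social_time",
    "vertex_retreat_step",
    "calibrate",
    "density_experiment",
    "DensityComparison",
    "CAVE_MOVEMENT",
    "SURFACE_MOVEMENT",
]

#: Movement parameters (step cm/tick, heading-change probability/tick) fixed
#: from observed per-treatment swimming distances (~620 cm and ~310 cm per
#: 180 s) and from the turnover of sampled social states.
CAVE_MOVEMENT = (0.7, 0.03)
SURFACE_MOVEMENT = (0.3, 0.03)

#: Rejection-sampling budget for hull-entering headings.
_N_CANDIDATES = 20


@dataclass(frozen=True)
class VertexRuleConfig:
    """Vertex-retreat rule: retreat probability and social radius (cm)."""

    retreat_prob: float = 0.8
    radius: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retreat_prob <= 1.0:
            raise ValueError("retreat_prob must lie in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class WalkConfig:
    """Full parameterisation of one simulated recording."""

    n_agents: int
    step: float
    heading_change_prob: float
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    tick: float = 0.2
    duration: float = 180.0
    rule: VertexRuleConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be at least 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.step > min(self.arena.effective_width, self.arena.effective_height):
            raise ValueError("step larger than the effective arena side")
        if not 0.0 <= self.heading_change_prob <= 1.0:
            raise ValueError("heading_change_prob must lie in [0, 1]")
        n_ticks = self.duration / self.tick
        if abs(n_ticks - round(n_ticks)) > 1e-9:
            raise ValueError("duration must be an integer number of ticks")

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration / self.tick))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.tick

    def with_agents(self, n_agents: int) -> "WalkConfig":
        return replace(self, n_agents=n_agents)

    def with_area_scale(self, area_scale: float) -> "WalkConfig":
        return replace(self, arena=replace(self.arena, area_scale=area_scale))

    def agent_ids(self) -> list[str]:
        width = max(2, len(str(self.n_agents)))
        return [f"A{i + 1:0{width}d}" for i in range(self.n_agents)]


def _simulate_free(config: WalkConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent walkers, vectorised over agents; returns (T, N, 2)."""
    w = config.arena.effective_width
    h = config.arena.effective_height
    n = config.n_agents
    pos = rng.uniform(0.0, [w, h], (n, 2))
    hd = rng.uniform(0.0, 2 * np.pi, n)
    frames = np.empty((config.n_ticks, n, 2))
    two_w, two_h = 2.0 * w, 2.0 * h
    for t in range(config.n_ticks):
        redraw = rng.random(n) < config.heading_change_prob
        hd = np.where(redraw, rng.uniform(0.0, 2 * np.pi, n), hd)
        vx = config.step * np.cos(hd)
        vy = config.step * np.sin(hd)
        nx = pos[:, 0] + vx
        ny = pos[:, 1] + vy
        fx = np.abs(nx) % two_w
        fx = np.where(fx > w, two_w - fx, fx)
        fy = np.abs(ny) % two_h
        fy = np.where(fy > h, two_h - fy, fy)
        sx = np.where(np.floor(nx / w).astype(np.int64) % 2 == 0, 1.0, -1.0)
        sy = np.where(np.floor(ny / h).astype(np.int64) % 2 == 0, 1.0, -1.0)
        hd = np.arctan2(vy * sy, vx * sx)
        pos = np.column_stack([fx, fy])
        frames[t] = pos
    return frames


def _simulate_rule(config: WalkConfig, rng: np.random.Generator) -> np.ndarray:
    """Walkers with the vertex-retreat rule; returns (T, N, 2).

    Random inputs are pre-drawn so the kernel (compiled or not) is
    deterministic given the generator state.
    """
    w = config.arena.effective_width
    h = config.arena.effective_height
    n = config.n_agents
    ticks = config.n_ticks
    pos0 = rng.uniform(0.0, [w, h], (n, 2))
    hd0 = rng.uniform(0.0, 2 * np.pi, n)
    u_turn = rng.random((ticks, n))
    new_heading = rng.uniform(0.0, 2 * np.pi, (ticks, n))
    u_rule = rng.random((ticks, n))
    cand = rng.uniform(0.0, 2 * np.pi, (ticks, n, _N_CANDIDATES))
    rule = config.rule
    return _kernels.walk_with_rule(
        pos0,
        hd0,
        config.step,
        w,
        h,
        config.heading_change_prob,
        rule.retreat_prob,
        rule.radius,
        u_turn,
        new_heading,
        u_rule,
        cand,
    )


def simulate_frames(config: WalkConfig, seed: int | None = None) -> np.ndarray:
    """One simulated recording as a raw (n_ticks, n_agents, 2) array."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.rule is not None and config.n_agents >= 3:
        return _simulate_rule(config, rng)
    return _simulate_free(config, rng)


def simulate(config: WalkConfig, seed: int | None = None) -> TrackTable:
    """Simulate one recording and wrap it as a validated TrackTable."""
    frames = simulate_frames(config, seed=seed)
    times = np.arange(config.n_ticks) * config.tick
    return TrackTable(
        arena=config.arena,
        ids=config.agent_ids(),
        times=times,
        positions=frames,
        sample_rate=config.sample_rate,
        group_id="sim",
    )


def iter_replicate_frames(
    config: WalkConfig, replicates: int, seed: int
) -> Iterator[np.ndarray]:
    """Independent replicate recordings with derived per-replicate seeds."""
    base = np.random.SeedSequence(seed)
    for child in base.spawn(replicates):
        rng = np.random.default_rng(child)
        if config.rule is not None and config.n_agents >= 3:
            yield _simulate_rule(config, rng)
        else:
            yield _simulate_free(config, rng)


def _sampled_social_fraction(
    frames: np.ndarray, config: WalkConfig, spec: SamplingSpec
) -> float:
    stride = spec.sample_interval / config.tick
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("sample_interval must be a multiple of the tick")
    sampled = frames[:: int(round(stride))]
    if config.n_agents < 2:
        return 0.0
    social, _ = nearest_neighbour_states(sampled, spec.neighbour_radius)
    return float(social.mean())


def social_time(
    config: WalkConfig,
    replicates: int,
    seed: int,
    spec: SamplingSpec | None = None,
) -> tuple[float, float]:
    """Mean and standard error of the sampled social-time fraction."""
    spec = spec or SamplingSpec()
    vals = np.array(
        [
            _sampled_social_fraction(frames, config, spec)
            for frames in iter_replicate_frames(config, replicates, seed)
        ]
    )
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return float(vals.mean()), se


def vertex_retreat_step(
    positions: np.ndarray,
    agent: int,
    rule: VertexRuleConfig,
    step: float,
    rng: np.random.Generator,
    heading: float,
) -> tuple[bool, float]:
    """Apply the vertex-retreat rule to one agent for one tick.

    Returns ``(fired, heading)``: when the agent is a convex-hull vertex with
    no conspecific within the social radius and the retreat draw succeeds, the
    returned heading is redrawn uniformly from the headings whose next
    position lies strictly inside the current hull (falling back to the hull
    centroid direction when no candidate enters); otherwise the incoming
    heading is returned unchanged.  Degenerate (collinear) hulls skip the
    rule.  This is the reference implementation of the rule used inside the
    simulation kernel; it is exposed for direct geometric testing.
    """
    positions = np.asarray(positions, float)
    n = len(positions)
    if n < 3:
        raise ValueError("the rule needs at least 3 agents")
    xs, ys = positions[:, 0], positions[:, 1]
    hull = np.empty(2 * n + 1, np.int64)
    k = _kernels._hull_chain(xs, ys, hull)
    if k < 3:
        return False, heading
    if agent not in set(int(h) for h in hull[:k]):
        return False, heading
    d = np.hypot(xs - xs[agent], ys - ys[agent])
    d[agent] = np.inf
    if d.min() < rule.radius:
        return False, heading
    if rng.random() >= rule.retreat_prob:
        return False, heading
    for ang in rng.uniform(0.0, 2 * np.pi, _N_CANDIDATES):
        px = xs[agent] + step * np.cos(ang)
        py = ys[agent] + step * np.sin(ang)
        if _kernels._point_strictly_inside(px, py, xs, ys, hull, k, 1e-12):
            return True, float(ang)
    cx, cy = positions.mean(axis=0)
    return True, float(np.arctan2(cy - ys[agent], cx - xs[agent]))


@dataclass
class CalibrationResult:
    """Outcome of matching the null model to a target social-time level."""

    config: WalkConfig
    achieved: float
    target: float
    replicates: int

    @property
    def error(self) -> float:
        return abs(self.achieved - self.target)


class CalibrationError(RuntimeError):
    def __init__(self, message: str, best: CalibrationResult):
        super().__init__(message)
        self.best = best


def calibrate(
    target_social_time: float,
    n_agents: int,
    *,
    step: float = 0.5,
    heading_change_prob: float = 0.03,
    area_scales: Sequence[float] | None = None,
    spec: SamplingSpec | None = None,
    seed: int = 0,
    replicates: int = 20,
    arena: ArenaSpec | None = None,
    tolerance: float = 0.05,
) -> CalibrationResult:
    """Grid-search the effective arena scale to a target social-time level.

    Movement parameters are held fixed (they do not move the sampled social
    time under uniform occupancy); the search dimension is the effective
    density.  The search is two-stage: a coarse scan over ``area_scales``
    followed by a refined local grid around the coarse optimum with doubled
    replication.  Within each stage all grid points share the same replicate
    seeds (common random numbers), so the social-time curve is smooth in the
    scale and the argmin is not biased by independent noise.  Ties break
    toward the larger scale, i.e. the least restrictive arena.  Raises
    :class:`CalibrationError` when no grid point comes within ``tolerance``
    of the target, reporting the best found.
    """
    if not 0.0 < target_social_time < 1.0:
        raise ValueError("target_social_time must lie in (0, 1)")
    spec = spec or SamplingSpec()
    arena = arena or ArenaSpec()
    if area_scales is None:
        area_scales = np.round(np.linspace(0.06, 1.0, 48), 4)

    def scan(
        scales: Sequence[float], reps: int, scan_seed: int
    ) -> CalibrationResult:
        best: CalibrationResult | None = None
        for scale in sorted(set(float(s) for s in scales), reverse=True):
            config = WalkConfig(
                n_agents=n_agents,
                step=step,
                heading_change_prob=heading_change_prob,
                arena=replace(arena, area_scale=scale),
                seed=seed,
            )
            achieved, _ = social_time(config, reps, scan_seed, spec)
            result = CalibrationResult(config, achieved, target_social_time, reps)
            if best is None or result.error < best.error:
                best = result
        assert best is not None
        return best

    coarse = scan(area_scales, replicates, seed + 7919)
    lo = max(min(area_scales), coarse.config.arena.area_scale - 0.03)
    hi = min(max(area_scales), coarse.config.arena.area_scale + 0.03)
    fine_scales = np.round(np.arange(lo, hi + 1e-9, 0.005), 4)
    best = scan(fine_scales, 2 * replicates, seed + 104729)
    if best.error > tolerance:
        raise CalibrationError(
            f"no arena scale reached within {tolerance} of "
            f"{target_social_time} (best: {best.achieved:.3f} at "
            f"area_scale={best.config.arena.area_scale})",
            best,
        )
    return best


@dataclass
class DensityComparison:
    """Paired high/low-density simulation summaries and their reductions."""

    estimates_high: "object"
    estimates_low: "object"
    social_time_high: float
    social_time_low: float
    social_time_se_high: float
    social_time_se_low: float
    mean_perimeter_high: float
    mean_perimeter_low: float
    mean_area_high: float
    mean_area_low: float
    perimeter_reduction: float
    area_reduction: float
    replicates_probabilities: int
    replicates_geometry: int


def density_experiment(
    config_high: WalkConfig,
    n_low: int = 6,
    replicates_probabilities: int = 20,
    replicates_geometry: int = 100,
    seed: int = 0,
    spec: SamplingSpec | None = None,
) -> DensityComparison:
    """Re-run one configuration at two group sizes and compare.

    Only ``n_agents`` differs between the paired runs; social-state
    probabilities are estimated on pooled replicates, hull metrics averaged
    per frame over all replicates, and reductions computed on unrounded means.
    """
    from .social_states import StateSequence, estimate_probabilities
    from .group_geometry import polygon_reduction

    spec = spec or SamplingSpec()
    config_low = config_high.with_agents(n_low)
    out = {}
    for tag, config, sub in (
        ("high", config_high, 0),
        ("low", config_low, 1),
    ):
        st, se = social_time(
            config, replicates_probabilities, seed + sub, spec=spec
        )
        seqs = []
        stride = int(round(spec.sample_interval / config.tick))
        for frames in iter_replicate_frames(
            config, replicates_probabilities, seed + sub
        ):
            social, nn = nearest_neighbour_states(
                frames[::stride], spec.neighbour_radius
            )
            ids = config.agent_ids()
            for j in range(config.n_agents):
                seqs.append(
                    StateSequence(
                        focal_id=ids[j],
                        states=[
                            ids[nn[k, j]] if social[k, j] else None
                            for k in range(social.shape[0])
                        ],
                    )
                )
        est = estimate_probabilities(seqs, halve_ci=True)
        pers, areas = [], []
        for frames in iter_replicate_frames(
            config, replicates_geometry, seed + 1000 + sub
        ):
            metrics = _kernels.hull_metrics_frames(frames)
            pers.append(metrics[:, 0].mean())
            areas.append(metrics[:, 1].mean())
        out[tag] = (st, se, est, float(np.mean(pers)), float(np.mean(areas)))

    st_h, se_h, est_h, per_h, area_h = out["high"]
    st_l, se_l, est_l, per_l, area_l = out["low"]
    return DensityComparison(
        estimates_high=est_h,
        estimates_low=est_l,
        social_time_high=st_h,
        social_time_low=st_l,
        social_time_se_high=se_h,
        social_time_se_low=se_l,
        mean_perimeter_high=per_h,
        mean_perimeter_low=per_l,
        mean_area_high=area_h,
        mean_area_low=area_l,
        perimeter_reduction=polygon_reduction(per_h, per_l),
        area_reduction=polygon_reduction(area_h, area_l),
        replicates_probabilities=replicates_probabilities,
        replicates_geometry=replicates_geometry,
    )
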