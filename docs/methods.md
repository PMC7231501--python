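# Methods

This package analyses fission–fusion dynamics in small fish groups: the
pattern by which individuals repeatedly split from and merge with social
partners over seconds-to-minutes time scales. It implements the observation
layer (nearest-neighbour social states sampled from trajectories), the model
layer (a Markov chain over those states), a movement null model (independent
correlated random walkers in a bounded arena), group-geometry summaries, and
the randomisation tests that connect them. This note documents the models,
the parameter choices and their rationale, the numerical conventions, and
what the synthetic data can and cannot show.

## The social-state model

At every sampling instant t, 2t, 3t, … each focal individual is either
**alone** (no conspecific strictly closer than the neighbour radius *d*) or
**social** with the identity of its strictly nearest neighbour. Pooling
state transitions over all focals and groups, four probabilities are
estimated as relative frequencies:

- *P*<sub>s→a</sub> — social now, alone at the next sample;
- *P*<sub>a→s</sub> — alone now, social at the next sample;
- *P*<sub>leave_nn</sub> — social with partner *j* now, and at the next
  sample either alone or social with some *j′* ≠ *j*;
- *P*<sub>switch_nn</sub> — social with *j* now, social with *j′* ≠ *j*
  next. On counts, switch = leave − (s→a) exactly, because all three share
  the denominator "social samples with a successor".

Under the chain, phase lengths are geometric, so the reciprocals of the
first three probabilities scale the mean lengths of social phases, solitary
phases and same-partner contact phases, and the stationary social-time
fraction is *P*<sub>a→s</sub>/(*P*<sub>a→s</sub> + *P*<sub>s→a</sub>).

**Defaults and units.** *d* = 8 cm (about two body lengths for the study
species) and *t* = 5 s. The sampling interval is deliberately coarser than
the 5 Hz tracking grid so that brief passes do not register as contact
phases; a robustness scan over a (d, t) grid is provided
(`social_states.robustness_scan`) and reports, it does not decide.

**Conventions.**
- Strict inequality at *d*: two individuals exactly 8 cm apart are alone.
- Distance ties resolve to the lexicographically smallest individual id
  (ids are kept sorted, and argmin returns the first minimum), for
  determinism.
- Zero-denominator probabilities are flagged undefined, never reported as 0.
- A final sample with no successor contributes to the social-time fraction
  but to no transition count.
- Confidence intervals are exact Clopper–Pearson. Because every contact
  phase is observed once from each of its two members, intervals can be
  computed on counts halved (rounded to nearest, minimum one trial) to
  correct for that double observation; point estimates are unaffected.
  Halved intervals are the default in the pipeline.
- Phase-length runs truncated by a sequence boundary are flagged censored
  and excluded from mean-length checks; a partner switch is an observed
  phase end, not a censoring event.

## The random-walk null model

Independent agents advance a fixed step per 0.2 s tick; with probability
*q* per tick the heading is redrawn uniformly on [0, 2π); walls reflect
specularly (position folded, heading mirrored). Agents are initialised
uniformly at random with uniform headings.

**Why encounter rate is calibrated through arena scale.** Under specular
reflection with uniform initialisation, the per-tick update is a
measure-preserving bijection of the arena, so the occupancy of every agent
is exactly uniform at every tick, for any step length and any turning
probability. The sampled social-time fraction of independent agents is a
functional of occupancy alone; step and turning probability move the
*transition* probabilities (how fast states turn over) but provably cannot
move the social-time *level*. The one model dimension that does move it is
effective density, so `random_walk.calibrate` grid-searches the effective
arena scale (`area_scale`, the same field that expresses the area
counterfactual) to match a target social-time fraction, holding movement
parameters fixed. The search is two-stage (coarse grid, then a refined
local grid at doubled replication) and uses common random numbers across
grid points so the social-time curve is smooth in the scale and the argmin
is not noise-driven. Ties break toward the least restrictive arena.

A useful consequence of uniform occupancy: per-frame agent positions are
iid uniform, so the social-time level at group size *n* follows the
pairwise-independence form 1 − (1 − a)<sup>n−1</sup> with *a* the pair
proximity probability, up to small edge heterogeneity. Halving density
therefore makes a parameter-free prediction for the low-density treatment
once the high-density level is calibrated — which is exactly how the null
model is used.

**Movement parameters.** Step length is set from observed mean swimming
distances per 3-minute recording (~620 cm for the cave population → 0.7 cm
per tick; ~310 cm for the surface population → 0.3 cm per tick, i.e.
3.5 and 1.5 cm/s). The heading-change probability default 0.03 per tick
(mean free path ~33 ticks ≈ 6.7 s) puts the simulated transition
probabilities at the surface calibration near the levels the null model is
expected to produce (*P*<sub>s→a</sub> ≈ 0.27, *P*<sub>a→s</sub> ≈ 0.3 at
n = 6). These are movement-scale choices, not fit parameters: the
social-time level is insensitive to both.

**Determinism.** One seeded generator per run; replicate seeds derive from
`numpy.random.SeedSequence.spawn`, so any replicate set regenerates
bit-identically from its base seed. The interaction-rule kernel consumes
pre-drawn uniforms, so its compiled (numba) and interpreted paths produce
identical trajectories up to last-ulp libm differences.

## The vertex-retreat rule

The candidate mechanism for active group contraction: at each tick, an
agent that (i) is a vertex of the convex hull of all current positions and
(ii) has no conspecific within its social radius (8 cm) redirects, with
probability 0.8, onto a heading whose next position lies strictly inside
the current hull. The heading is drawn uniformly from that set by rejection
sampling (20 candidates); if no candidate enters the hull (possible when
the hull is smaller than one step), the agent heads for the hull centroid.
Degenerate (collinear) hulls skip the rule for that tick. All agents update
synchronously against the same current hull. Retreat probability and radius
follow the proposed mechanism; the retreat-heading law is our choice — the
mechanism specifies the destination ("back into the polygon"), not the
heading distribution.

With the rule active the group self-aggregates: social time rises to
~85–90% regardless of arena size, and the 12→6 hull reductions roughly
double relative to independent walkers.

## Group geometry

- **Hull metrics**: per-frame convex-hull perimeter and area, averaged over
  all 5 Hz frames. Degenerate frames use closed-traversal conventions: one
  distinct point → (0, 0); collinear points → area 0, perimeter twice the
  extent. The implementation is an Andrew monotone-chain kernel (compiled
  with numba when available) because simulation-scale analyses evaluate
  millions of small hulls; it matches `scipy.spatial.ConvexHull` to 1e-9 on
  non-degenerate frames (tested).
- **Polygon reduction**: 100 × (1 − low/high) on unrounded means. For
  observed 12-6-12 designs the high-density baseline is the mean of the two
  high-density recordings; simulated reductions come from paired runs.
- **Area usage**: fraction of a 4 × 4 grid of 15 cm cells visited by any
  group member at any frame; cells are half-open with the outer arena edges
  closed, so boundary positions belong to the outermost cells.
- **Polarisation**: every 3 s, each focal contributes the unit vector of
  its displacement over the preceding interval; the statistic is the length
  of the mean unit vector (normalised by group size, hence in [0, 1]).
  Time points where any focal moved less than 0.1 cm are skipped — the
  interval exists precisely because fish sometimes hold position, leaving
  the unit vector undefined. It distinguishes a contracted fission–fusion
  group (low polarisation) from a school (high).

## Randomisation inference

Individual measures within a group are interdependent, so treatment
comparisons use a paired-swap randomisation test: the statistic is the
absolute difference of treatment means, and each repetition independently
swaps each individual's value pair between treatments with probability 1/2
(10⁵ repetitions by default). The Monte-Carlo p-value uses the add-one
convention (k+1)/(reps+1), counting ties as extreme, so it is never zero;
an exhaustive variant enumerates all 2ⁿ swap patterns for n ≤ 20 and
validates the Monte-Carlo path.

Polygon reductions are judged against the null of density change alone: the
null distribution of 12→6 reductions is built from paired simulations of
the calibrated null model (10⁴ repetitions at full scale), and an observed
reduction is significant when it exceeds the upper 2.5% quantile. We read
the test as one on the distribution of paired reductions; building it
instead on raw mean-size distributions against a fixed baseline is a
defensible alternative the sources leave open. Feeding the test null draws
rejects at ~2.5% (tested).

## Synthetic data

`synthetic.make_treatment_set` emulates the 12-6-12 removal design: three
3-minute recordings at 5 Hz in a 60 × 60 cm arena, with the six G6 agents
designated focal. The `cave_like` archetype uses independent walkers with
the effective arena scaled to put high-density social time near the ~52%
cave level ((52/60)² ≈ 0.751 of the arena). The `surface_like` archetype
uses vertex-retreat walkers in the full arena; the rule itself drives
social time to ~85–90%, slightly above the ~81% surface level, and scale 1
is the closest admissible calibration — accepted, since the archetype's
role is to carry the rule's signature (maintained social time and strong
polygon contraction at low density), which it does. Recordings are
independent across treatments (the removal design re-randomises positions).
`synthetic.make_markov_sequences` samples state sequences directly from the
chain with known probabilities (uniform partner labels, stationary start)
for estimator-recovery tests that bypass the spatial layer.

What the synthetic data does **not** emulate: tracking noise, occlusions,
identity swaps, wall-following or thigmotaxis, heterogeneous individuals,
and any attraction/alignment beyond the vertex-retreat rule. Passing tests
therefore demonstrate correctness of the estimators and simulators and
internal consistency of the analysis chain — not that real fish follow
these models.

## Numerical choices and problem sizes

- Tick 0.2 s matches the 5 Hz tracking grid; states sample every 25 ticks.
- Calibration uses ≥20 replicates per grid point (40 in the refinement
  stage); reported social-time predictions average ≥50 replicates of 180 s.
- Simulated polygon reductions average 1,000 paired runs
  (`scripts/acceptance.py`, `analysis/05_polygon_reductions.py --reps`);
  the analysis drivers default to desk-scale replicate counts chosen to
  keep a full run in minutes on one CPU while leaving Monte-Carlo error
  well inside the tolerances used in the tests.
- Strict-interior tests in the rule use an epsilon of 1e-12 cm; hull-oracle
  agreement is asserted at 1e-9.
- Positions up to 1 cm outside the nominal arena are clamped at ingest
  (tracking jitter); beyond that, ingest fails. Gaps and duplicate
  (id, time) rows are ingest errors — no interpolation is offered, because
  the intended tracking data are manually curated and gap-free.
- The area counterfactual composes multiplicatively: a reduction *r*
  removes fraction *r* of the *current* effective area, scaling both
  dimensions by √(1−r).

## Known limitations

- The movement kernel is one of many that reproduce the calibrated
  social-time levels; transition probabilities (phase turnover) depend on
  the step/turn choices and are matched only roughly.
- The counterfactual sweep locates the area reduction needed to reach a
  target social time by linear interpolation on a Monte-Carlo curve; near
  flat stretches of the curve the located value carries the curve's noise.
- The estimator pools transitions across focals and groups by design
  (identity-free), so it cannot resolve individual-level network structure,
  and mirrored observations of one contact phase are corrected only in the
  interval widths, not modelled jointly.
- With the vertex-retreat rule active, calibration can only shrink the
  arena, so targets below the rule's self-aggregated social-time level are
  unreachable (flagged by `CalibrationError`).
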