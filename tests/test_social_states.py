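import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import beta, chisquare

from fissionfusion import (
    ALONE,
    SamplingSpec,
    StateSequence,
    binomial_ci,
    build_state_sequences,
    estimate_probabilities,
    make_markov_sequences,
    phase_lengths,
    robustness_scan,
)

from conftest import make_track


def seq(*states):
    return StateSequence(focal_id="X", states=[None if s == "A" else s for s in states])


class TestBuildStateSequences:
    def test_three_fish_line(self):
        pts = np.array([[[0.0, 0.0], [5.0, 0.0], [20.0, 0.0]]])
        track = make_track(pts, ids=["F1", "F2", "F3"])
        seqs = {
            s.focal_id: s.states
            for s in build_state_sequences(track, SamplingSpec(sample_interval=0.2))
        }
        assert seqs["F1"] == ["F2"]
        assert seqs["F2"] == ["F1"]
        assert seqs["F3"] == [ALONE]

    def test_exactly_at_radius_is_alone(self):
        pts = np.array([[[0.0, 0.0], [8.0, 0.0]]])
        track = make_track(pts, ids=["F1", "F2"])
        seqs = build_state_sequences(track, SamplingSpec(sample_interval=0.2))
        assert all(s.states == [ALONE] for s in seqs)

    def test_distance_tie_goes_to_smallest_id(self):
        pts = np.array([[[0.0, 0.0], [3.0, 0.0], [-3.0, 0.0]]]) + 30.0
        track = make_track(pts, ids=["F1", "F2", "F3"])
        seqs = {s.focal_id: s.states for s in
                build_state_sequences(track, SamplingSpec(sample_interval=0.2))}
        assert seqs["F1"] == ["F2"]  # F2 and F3 both at 3 cm

    def test_interval_must_divide_spacing(self, small_sim_track):
        with pytest.raises(ValueError):
            build_state_sequences(small_sim_track, SamplingSpec(sample_interval=0.3))

    def test_matches_brute_force_scan(self, rng):
        pts = rng.uniform(0, 60, (7, 10, 2))
        ids = [f"F{i:02d}" for i in range(10)]
        track = make_track(pts, ids=ids, sample_rate=5.0)
        seqs = {s.focal_id: s.states for s in
                build_state_sequences(track, SamplingSpec(sample_interval=0.2))}
        for k in range(7):
            d = cdist(pts[k], pts[k])
            np.fill_diagonal(d, np.inf)
            for j, focal in enumerate(ids):
                order = sorted(range(10), key=lambda m: (d[j, m], ids[m]))
                nearest = order[0]
                expected = ids[nearest] if d[j, nearest] < 8.0 else ALONE
                assert seqs[focal][k] == expected


class TestEstimateProbabilities:
    def test_worked_example(self):
        est = estimate_probabilities([seq("A", "A", "j1", "j1", "j2", "A")])
        assert est.p_a_to_s.value == pytest.approx(1 / 2)
        assert est.p_s_to_a.value == pytest.approx(1 / 3)
        assert est.p_leave_nn.value == pytest.approx(2 / 3)
        assert est.p_switch_nn.value == pytest.approx(1 / 3)
        assert est.social_time_fraction.value == pytest.approx(3 / 6)

    def test_all_alone_degenerate(self):
        est = estimate_probabilities([seq("A", "A", "A")])
        assert est.social_time_fraction.value == 0.0
        assert est.p_a_to_s.value == 0.0
        assert not est.p_s_to_a.defined
        assert est.p_s_to_a.value is None
        assert not est.p_leave_nn.defined

    def test_count_identity_shared_denominator(self):
        est = estimate_probabilities(
            [seq("j1", "j2", "A", "j1", "j1", "j3", "A", "A")]
        )
        assert (
            est.p_switch_nn.numerator + est.p_s_to_a.numerator
            == est.p_leave_nn.numerator
        )
        assert est.p_switch_nn.denominator == est.p_leave_nn.denominator

    @given(
        st.lists(
            st.lists(st.sampled_from(["A", "j1", "j2", "j3"]), min_size=2, max_size=30),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_count_identity_property(self, raw):
        est = estimate_probabilities([seq(*states) for states in raw])
        assert (
            est.p_switch_nn.numerator + est.p_s_to_a.numerator
            == est.p_leave_nn.numerator
        )
        for e in (est.p_leave_nn, est.p_s_to_a, est.p_a_to_s, est.p_switch_nn):
            if e.defined:
                assert 0.0 <= e.value <= 1.0
                assert e.ci[0] <= e.value <= e.ci[1]

    def test_parameter_recovery_on_direct_chain(self):
        p_as, p_sa, p_sw = 0.4, 0.2, 0.15
        seqs, _ = make_markov_sequences(
            p_as, p_sa, p_sw, n_focals=4, length=2600, seed=77
        )
        est = estimate_probabilities(seqs)
        for e, truth in (
            (est.p_a_to_s, p_as),
            (est.p_s_to_a, p_sa),
            (est.p_switch_nn, p_sw),
            (est.p_leave_nn, p_sa + p_sw),
        ):
            se = np.sqrt(truth * (1 - truth) / e.denominator)
            assert abs(e.value - truth) < 3 * se

    def test_two_state_stationarity_identity(self):
        p_as, p_sa = 0.3, 0.2
        seqs, _ = make_markov_sequences(p_as, p_sa, 0.0, n_focals=5, length=4000,
                                        seed=5)
        est = estimate_probabilities(seqs)
        expected = p_as / (p_as + p_sa)
        n = est.social_time_fraction.denominator
        # samples are serially correlated; allow a generous multiple of the
        # iid binomial standard error
        assert abs(est.social_time_fraction.value - expected) < 8 * np.sqrt(
            expected * (1 - expected) / n
        )


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 1.0

    def test_matches_beta_quantile_closed_form(self):
        lo, hi = binomial_ci(3, 10)
        assert lo == pytest.approx(beta.ppf(0.025, 3, 8), abs=1e-10)
        assert hi == pytest.approx(beta.ppf(0.975, 4, 7), abs=1e-10)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(0, 7), (3, 10), (25, 40), (40, 40)]:
            lo, hi = binomial_ci(k, n)
            slo, shi = statsmodels.proportion_confint(k, n, 0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-9)
            assert hi == pytest.approx(shi, abs=1e-9)

    def test_halving_widens_interval(self):
        lo, hi = binomial_ci(30, 100)
        hlo, hhi = binomial_ci(30, 100, halve=True)
        assert (hlo, hhi) == binomial_ci(15, 50)
        assert hhi - hlo > hi - lo

    def test_halving_rounds_to_nearest_with_min_one_trial(self):
        assert binomial_ci(1, 1, halve=True) == binomial_ci(1, 1)
        assert binomial_ci(3, 7, halve=True) == binomial_ci(2, 4)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)


class TestPhaseLengths:
    def test_worked_example(self):
        pl = phase_lengths([seq("A", "A", "j1", "j1", "j2", "A")])
        assert pl.social == [(3, False)]
        assert sorted(pl.contact) == [(1, False), (2, False)]
        assert pl.solitary == [(2, True), (1, True)]

    def test_all_social_single_partner_is_censored(self):
        pl = phase_lengths([seq("j1", "j1", "j1")])
        assert pl.contact == [(3, True)]
        assert pl.social == [(3, True)]
        assert pl.solitary == []

    def test_mean_social_phase_matches_geometric_reciprocal(self):
        p_sa = 0.25
        seqs, _ = make_markov_sequences(0.5, p_sa, 0.1, n_focals=6, length=2000,
                                        seed=11)
        means = phase_lengths(seqs).mean_uncensored()
        assert means["social"] == pytest.approx(1 / p_sa, rel=0.05)

    def test_phase_lengths_are_geometric(self):
        # chi-square goodness of fit of uncensored solitary phases against
        # the geometric law with p estimated from the same chain
        p_as = 0.3
        seqs, _ = make_markov_sequences(p_as, 0.3, 0.0, n_focals=10, length=1000,
                                        seed=13)
        lengths = np.array(
            [n for n, cens in phase_lengths(seqs).solitary if not cens]
        )
        p_hat = 1.0 / lengths.mean()
        kmax = 12
        observed = np.array(
            [(lengths == k).sum() for k in range(1, kmax)]
            + [(lengths >= kmax).sum()]
        )
        probs = np.array(
            [p_hat * (1 - p_hat) ** (k - 1) for k in range(1, kmax)]
        )
        probs = np.append(probs, 1 - probs.sum())
        stat, p = chisquare(observed, probs * len(lengths), ddof=1)
        assert p > 0.01


class TestRobustnessScan:
    def test_scan_covers_grid_and_varies_smoothly(self, small_sim_track):
        df = robustness_scan(small_sim_track, d_values=[6.0, 8.0, 10.0],
                             t_values=[1.0, 5.0])
        assert len(df) == 6
        # social time grows with the neighbour radius at fixed t
        sub = df[df.t == 5.0].sort_values("d")
        assert sub.social_time_fraction.is_monotonic_increasing
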