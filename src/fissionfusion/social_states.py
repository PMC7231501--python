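"""Nearest-neighbour social states and the Markov model of fission-fusion.

At every sampling instant a focal individual is either ALONE (no conspecific
strictly closer than the neighbour radius d) or social with the identity of
its strictly nearest neighbour.  Pooling the sampled state transitions over
all focals and groups gives relative-frequency estimates of four
probabilities:

* ``p_s_to_a``   - discontinuing social contact (social now, alone next),
* ``p_a_to_s``   - discontinuing being alone (alone now, social next),
* ``p_leave_nn`` - losing the current nearest neighbour (by going alone or by
  switching partner),
* ``p_switch_nn``- switching partner while staying social; by construction
  its count numerator equals leave minus s-to-a on the shared denominator.

Reciprocals of the first three scale the mean lengths of same-partner contact
phases, social phases and solitary phases.  Because every contact phase is
observed once from each of its two members, confidence intervals can
optionally be computed on halved counts to avoid double-counting; the point
estimates are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .trajectories import TrackTable

__all__ = [
    "ALONE",
    "SamplingSpec",
    "StateSequence",
    "ProbabilityEstimate",
    "MarkovEstimates",
    "PhaseLengths",
    "nearest_neighbour_states",
    "build_state_sequences",
    "estimate_probabilities",
    "binomial_ci",
    "phase_lengths",
    "robustness_scan",
]

#: Sentinel for the solitary state.
ALONE = None


@dataclass(frozen=True)
class SamplingSpec:
    """Neighbour radius d (cm) and state-sampling interval t (s).

    Defaults are two body lengths (8 cm) and 5 s; the sampling interval is
    deliberately much coarser than the tracking rate so that brief passes do
    not masquerade as contact phases.
    """

    neighbour_radius: float = 8.0
    sample_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.neighbour_radius <= 0:
            raise ValueError("neighbour_radius must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


@dataclass
class StateSequence:
    """Per-focal sequence of sampled states (ALONE or a neighbour id)."""

    focal_id: str
    states: list

    def __post_init__(self) -> None:
        for s in self.states:
            if s is not ALONE and s == self.focal_id:
                raise ValueError("a focal cannot be its own neighbour")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ProbabilityEstimate:
    """A pooled relative frequency with its counts and exact 95% CI."""

    numerator: int
    denominator: int
    ci: tuple[float, float] | None = None

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        if not self.defined:
            return None
        return self.numerator / self.denominator

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.defined:
            return "ProbabilityEstimate(undefined)"
        lo, hi = self.ci if self.ci else (float("nan"), float("nan"))
        return (
            f"ProbabilityEstimate({self.value:.4f}, {self.numerator}/"
            f"{self.denominator}, ci=({lo:.4f}, {hi:.4f}))"
        )


@dataclass
class MarkovEstimates:
    """The four model probabilities plus the overall social-time fraction."""

    p_leave_nn: ProbabilityEstimate
    p_s_to_a: ProbabilityEstimate
    p_a_to_s: ProbabilityEstimate
    p_switch_nn: ProbabilityEstimate
    social_time_fraction: ProbabilityEstimate
    halved_ci: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in (
            "p_leave_nn",
            "p_s_to_a",
            "p_a_to_s",
            "p_switch_nn",
            "social_time_fraction",
        ):
            est: ProbabilityEstimate = getattr(self, name)
            lo, hi = est.ci if est.ci else (np.nan, np.nan)
            rows.append(
                {
                    "probability": name,
                    "estimate": est.value if est.defined else np.nan,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "ci_low": lo,
                    "ci_high": hi,
                    "defined": est.defined,
                }
            )
        return pd.DataFrame(rows)


def binomial_ci(
    successes: int,
    trials: int,
    halve: bool = False,
    level: float = 0.95,
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a proportion.

    With ``halve`` set, successes and trials are divided by two and rounded to
    the nearest integer (minimum one trial) before computing the interval;
    this corrects interval width for contact phases observed once from each
    partner while leaving point estimates untouched.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if halve:
        successes = int(np.floor(successes / 2 + 0.5))
        trials = max(1, int(np.floor(trials / 2 + 0.5)))
        successes = min(successes, trials)
    res = binomtest(successes, trials)
    ci = res.proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


def nearest_neighbour_states(
    positions: np.ndarray, neighbour_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised state construction on a (S, N, 2) stack of sampled frames.

    Returns ``social`` (S, N) bool and ``nn_index`` (S, N) int giving each
    focal's strictly nearest conspecific (by column index).  Columns must be
    ordered by individual id: exact distance ties then resolve to the
    lexicographically smallest id because argmin returns the first minimum.
    """
    positions = np.asarray(positions, float)
    if positions.ndim != 3 or positions.shape[2] != 2:
        raise ValueError("positions must have shape (S, N, 2)")
    n = positions.shape[1]
    diff = positions[:, :, None, :] - positions[:, None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    dist[:, np.arange(n), np.arange(n)] = np.inf
    nn_index = np.argmin(dist, axis=2)
    nn_dist = np.take_along_axis(dist, nn_index[..., None], axis=2)[..., 0]
    social = nn_dist < neighbour_radius  # strict inequality at d
    return social, nn_index


def build_state_sequences(
    table: TrackTable, spec: SamplingSpec | None = None
) -> list[StateSequence]:
    """Sample every individual's social state every t seconds.

    Every individual acts as a focal.  The sampling interval must be an
    integer multiple of the tracking sample spacing.
    """
    spec = spec or SamplingSpec()
    stride = spec.sample_interval * table.sample_rate
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError(
            "sample_interval must be a positive multiple of the track spacing"
        )
    stride = int(round(stride))
    sampled = table.positions[::stride]
    social, nn_index = nearest_neighbour_states(sampled, spec.neighbour_radius)
    seqs = []
    for j, focal in enumerate(table.ids):
        states = [
            table.ids[nn_index[k, j]] if social[k, j] else ALONE
            for k in range(sampled.shape[0])
        ]
        seqs.append(StateSequence(focal_id=focal, states=states))
    return seqs


def estimate_probabilities(
    seqs: Iterable[StateSequence],
    halve_ci: bool = False,
    ci_level: float = 0.95,
) -> MarkovEstimates:
    """Pooled relative-frequency estimates of the four model probabilities.

    Counts are pooled over all focals regardless of identity.  A zero
    denominator leaves the corresponding probability undefined (flagged, not
    zero).  A final sample with no successor contributes to the social-time
    fraction but to no transition count.
    """
    n_social_now = 0  # social samples with a successor
    n_s_to_a = 0
    n_switch = 0
    n_alone_now = 0
    n_a_to_s = 0
    n_social_samples = 0
    n_samples = 0
    for seq in seqs:
        states = seq.states
        n_samples += len(states)
        n_social_samples += sum(1 for s in states if s is not ALONE)
        for k in range(len(states) - 1):
            cur, nxt = states[k], states[k + 1]
            if cur is not ALONE:
                n_social_now += 1
                if nxt is ALONE:
                    n_s_to_a += 1
                elif nxt != cur:
                    n_switch += 1
            else:
                n_alone_now += 1
                if nxt is not ALONE:
                    n_a_to_s += 1
    n_leave = n_s_to_a + n_switch

    def make(num: int, den: int) -> ProbabilityEstimate:
        ci = binomial_ci(num, den, halve=halve_ci, level=ci_level) if den else None
        return ProbabilityEstimate(num, den, ci)

    return MarkovEstimates(
        p_leave_nn=make(n_leave, n_social_now),
        p_s_to_a=make(n_s_to_a, n_social_now),
        p_a_to_s=make(n_a_to_s, n_alone_now),
        p_switch_nn=make(n_switch, n_social_now),
        social_time_fraction=make(n_social_samples, n_samples),
        halved_ci=halve_ci,
    )


@dataclass
class PhaseLengths:
    """Maximal-run lengths (in sampling intervals) with end-censoring flags.

    ``solitary`` are runs of ALONE, ``social`` runs of any social state, and
    ``contact`` runs with an unchanged partner.  A run touching the start or
    end of its sequence is censored: its true length is only bounded below.
    """

    solitary: list[tuple[int, bool]] = field(default_factory=list)
    social: list[tuple[int, bool]] = field(default_factory=list)
    contact: list[tuple[int, bool]] = field(default_factory=list)

    @staticmethod
    def _mean(runs: list[tuple[int, bool]]) -> float:
        lengths = [n for n, censored in runs if not censored]
        return float(np.mean(lengths)) if lengths else float("nan")

    def mean_uncensored(self) -> dict[str, float]:
        return {
            "solitary": self._mean(self.solitary),
            "social": self._mean(self.social),
            "contact": self._mean(self.contact),
        }


def _runs(keys: list, n: int) -> list[tuple[int, bool]]:
    """Maximal runs of equal keys; None keys are skipped entirely."""
    runs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or keys[i] != keys[start]:
            if keys[start] is not None:
                censored = start == 0 or i == n
                runs.append((i - start, censored))
            start = i
    return runs


def phase_lengths(seqs: Iterable[StateSequence]) -> PhaseLengths:
    """Distributions of solitary, social and same-partner phase lengths."""
    out = PhaseLengths()
    for seq in seqs:
        n = len(seq.states)
        solitary_keys = ["alone" if s is ALONE else None for s in seq.states]
        social_keys = ["social" if s is not ALONE else None for s in seq.states]
        contact_keys = [s if s is not ALONE else None for s in seq.states]
        out.solitary.extend(_runs(solitary_keys, n))
        out.social.extend(_runs(social_keys, n))
        # contact runs also end on a partner switch; a switch boundary is an
        # observed end, so censoring still only applies at sequence edges
        out.contact.extend(_runs(contact_keys, n))
    return out


def robustness_scan(
    table: TrackTable,
    d_values: Sequence[float],
    t_values: Sequence[float],
    halve_ci: bool = False,
) -> pd.DataFrame:
    """Re-estimate the model over a grid of (d, t) choices.

    Returns one row per grid point with all probabilities and counts; the
    scan reports, it does not decide.
    """
    rows = []
    for d in d_values:
        for t in t_values:
            spec = SamplingSpec(neighbour_radius=d, sample_interval=t)
            est = estimate_probabilities(
                build_state_sequences(table, spec), halve_ci=halve_ci
            )
            row = {"d": d, "t": t}
            for name in (
                "p_leave_nn",
                "p_s_to_a",
                "p_a_to_s",
                "p_switch_nn",
                "social_time_fraction",
            ):
                e: ProbabilityEstimate = getattr(est, name)
                row[name] = e.value if e.defined else np.nan
                row[f"{name}_n"] = e.denominator
            rows.append(row)
    return pd.DataFrame(rows)
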