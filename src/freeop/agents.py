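"""Synthetic learner/rater cohorts.

Each agent tracks the two conditional outcome probabilities of the
schedule with a pair of delta-rule estimators: the bin's outcome updates
the contingent estimate P̂(O|A) when the agent pressed, and the
non-contingent estimate P̂(O|~A) otherwise.  Pressing itself is a
logistic policy on the estimated contingency, so response rates adapt to
ΔP in every profile.  Block-end causal ratings are a separate, weighted
read-out of the same estimates — the weights are what differ between
group profiles, which is how a cohort can adapt its behaviour to a
contingency while failing to report it.

The rating read-out is

    rating = clamp( g·100·( wA·P̂(O|A) − wNA·P̂(O|~A) + wR·r̄ )
                    + b + Normal(0, σ), −100, 100 )

where ``r̄`` is the block's experienced reward rate.  ``wA`` and ``wNA``
are pathway-specific awareness sensitivities; ``wR`` is an
outcome-density weight that lets a profile (mis)attribute freely
delivered rewards to its own action, the mechanism used here for the
ageing-related misjudgement of negative contingencies.  With ``wR = 0``
the read-out reduces to the pure two-pathway contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .schedule import (
    BlockResult,
    SessionRecord,
    SessionSpec,
    make_session_spec,
    run_block,
)

__all__ = [
    "AgentProfile",
    "LearnerState",
    "GROUP_PRESETS",
    "GROUP_SIZES",
    "update_estimates",
    "press_probability",
    "make_rating",
    "simulate_session",
    "simulate_cohort",
    "simulate_study",
]


@dataclass(frozen=True)
class AgentProfile:
    """Learning, policy and rating parameters defining a synthetic group.

    Parameters
    ----------
    learning_rate : float
        Delta-rule step size α in (0, 1] shared by both estimators.
    policy_intercept, policy_slope : float
        Log-odds intercept β0 and slope β1 ≥ 0 of the press policy
        ``logistic(β0 + β1·ΔP̂)``.
    rating_gain : float
        Overall gain g > 0 of the rating read-out, in rating units per
        unit probability (the scale spans ±100).
    weight_contingent, weight_noncontingent : float
        Awareness sensitivities wA, wNA ≥ 0 to the two estimates.
    weight_reward_rate : float
        Outcome-density weight wR ≥ 0: sensitivity of the rating to the
        block's overall reward rate irrespective of its source.
    rating_bias : float
        Additive rating offset b, in rating units.
    rating_noise_sd : float
        Rating noise σ ≥ 0, in rating units.
    round_ratings : bool
        Round ratings to integers (visual-analogue scales are recorded
        coarsely); on by default.
    """

    learning_rate: float = 0.15
    policy_intercept: float = -0.5
    policy_slope: float = 3.0
    rating_gain: float = 1.0
    weight_contingent: float = 1.0
    weight_noncontingent: float = 1.0
    weight_reward_rate: float = 0.0
    rating_bias: float = 0.0
    rating_noise_sd: float = 12.0
    round_ratings: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.policy_slope < 0:
            raise ValueError("policy_slope must be >= 0")
        if self.rating_gain <= 0:
            raise ValueError("rating_gain must be > 0")
        for name in ("weight_contingent", "weight_noncontingent",
                     "weight_reward_rate", "rating_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LearnerState:
    """Running estimates of the two conditional outcome probabilities."""

    est_p_contingent: float = 0.5
    est_p_noncontingent: float = 0.5
    n_press_updates: int = 0
    n_nopress_updates: int = 0


#: Group profiles.  Policy parameters are shared — every group adapts its
#: pressing to contingency — while the rating read-outs differ:
#: * younger_control: both awareness pathways intact.
#: * older_control / age_matched_control / latPFC: non-contingent pathway
#:   blunted and partially replaced by outcome-density misattribution,
#:   producing intact positive-range awareness but flat-to-inverted
#:   ratings on the negative range.
#: * vmPFC: contingent pathway additionally blunted and ratings elevated
#:   overall.
_OLDER_LIKE = dict(
    weight_contingent=1.0,
    weight_noncontingent=0.1,
    weight_reward_rate=0.35,
    rating_bias=10.0,
)
GROUP_PRESETS: dict[str, AgentProfile] = {
    "younger_control": AgentProfile(),
    "older_control": AgentProfile(**_OLDER_LIKE),
    "age_matched_control": AgentProfile(**_OLDER_LIKE),
    "latPFC": AgentProfile(**_OLDER_LIKE),
    "vmPFC": AgentProfile(
        weight_contingent=0.2,
        weight_noncontingent=0.1,
        weight_reward_rate=0.35,
        rating_bias=25.0,
        rating_noise_sd=15.0,
    ),
}

#: Study group sizes.
GROUP_SIZES: dict[str, int] = {
    "vmPFC": 8,
    "latPFC": 7,
    "age_matched_control": 17,
    "older_control": 15,
    "younger_control": 15,
}


def update_estimates(
    state: LearnerState, pressed: bool, rewarded: bool, learning_rate: float
) -> LearnerState:
    """Delta-rule update of one pathway's probability estimate.

    Exactly one estimate moves per bin — the contingent one if the agent
    pressed, otherwise the non-contingent one — by
    ``est += α·(outcome − est)``.  The state is updated in place and
    returned.
    """
    if not (0.0 < learning_rate <= 1.0):
        raise ValueError("learning_rate must be in (0, 1]")
    outcome = 1.0 if rewarded else 0.0
    if pressed:
        state.est_p_contingent += learning_rate * (
            outcome - state.est_p_contingent
        )
        state.n_press_updates += 1
    else:
        state.est_p_noncontingent += learning_rate * (
            outcome - state.est_p_noncontingent
        )
        state.n_nopress_updates += 1
    return state


def press_probability(state: LearnerState, profile: AgentProfile) -> float:
    """Logistic press policy on the estimated contingency.

    ``logistic(β0 + β1·(P̂(O|A) − P̂(O|~A)))`` — strictly increasing in
    the estimated ΔP whenever β1 > 0.
    """
    z = profile.policy_intercept + profile.policy_slope * (
        state.est_p_contingent - state.est_p_noncontingent
    )
    return 1.0 / (1.0 + math.exp(-z))


def make_rating(
    state: LearnerState,
    profile: AgentProfile,
    rng: np.random.Generator,
    *,
    reward_rate: float = 0.0,
) -> float:
    """Block-end causal rating on the −100 … 100 scale.

    Applies the weighted read-out described in the module docstring and
    clamps to the scale bounds; rounded to an integer when the profile
    requests it.
    """
    core = 100.0 * profile.rating_gain * (
        profile.weight_contingent * state.est_p_contingent
        - profile.weight_noncontingent * state.est_p_noncontingent
        + profile.weight_reward_rate * reward_rate
    )
    rating = core + profile.rating_bias
    if profile.rating_noise_sd > 0:
        rating += profile.rating_noise_sd * rng.standard_normal()
    rating = min(100.0, max(-100.0, rating))
    if profile.round_ratings:
        rating = float(round(rating))
    return rating


def simulate_session(
    profile: AgentProfile,
    spec: SessionSpec,
    seed_seq: np.random.SeedSequence | int,
    *,
    subject_id: str = "s0",
    group: str = "custom",
) -> SessionRecord:
    """Run one agent through a full 12-block session.

    The seed is split into three independent streams — policy draws,
    outcome draws and rating noise — so schedule noise and agent
    behaviour are separately reproducible.  Estimates start at 0.5
    (maximum-uncertainty prior) and carry over between blocks.
    """
    if isinstance(seed_seq, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(seed_seq))
    policy_ss, outcome_ss, rating_ss = seed_seq.spawn(3)
    policy_rng = np.random.default_rng(policy_ss)
    outcome_rng = np.random.default_rng(outcome_ss)
    rating_rng = np.random.default_rng(rating_ss)

    state = LearnerState()
    alpha = profile.learning_rate
    record = SessionRecord(subject_id=subject_id, group=group)
    for block_spec in spec.blocks:
        policy = lambda _bin: press_probability(state, profile)  # noqa: E731
        observer = lambda pressed, rewarded: update_estimates(  # noqa: E731
            state, pressed, rewarded, alpha
        )
        bins = run_block(
            policy, block_spec, policy_rng,
            outcome_rng=outcome_rng, observer=observer,
        )
        reward_rate = sum(b.rewarded for b in bins) / len(bins)
        rating = make_rating(
            state, profile, rating_rng, reward_rate=reward_rate
        )
        record.blocks.append(
            BlockResult(spec=block_spec, bins=bins, rating=rating)
        )
    return record


def simulate_cohort(
    profile: AgentProfile,
    n_subjects: int,
    seed: int | np.random.SeedSequence,
    *,
    group: str = "custom",
    duration_bins: int | None = None,
    order_indices: Optional[Sequence[int]] = None,
) -> list[SessionRecord]:
    """Simulate ``n_subjects`` full sessions for one group profile.

    Subjects are assigned Latin-square rows round-robin (row ``i mod 9``
    for subject ``i``) unless explicit ``order_indices`` are given.
    Reproducible: the same seed yields bit-identical session logs.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if isinstance(seed, (int, np.integer)):
        seed = np.random.SeedSequence(int(seed))
    kwargs = {} if duration_bins is None else {"duration_bins": duration_bins}
    sessions = []
    for i, subject_ss in enumerate(seed.spawn(n_subjects)):
        order = order_indices[i] if order_indices is not None else i % 9
        spec = make_session_spec(order, **kwargs)
        sessions.append(
            simulate_session(
                profile, spec, subject_ss,
                subject_id=f"{group}_{i:02d}", group=group,
            )
        )
    return sessions


def simulate_study(
    seed: int,
    *,
    presets: dict[str, AgentProfile] | None = None,
    sizes: dict[str, int] | None = None,
    duration_bins: int | None = None,
) -> list[SessionRecord]:
    """Simulate the full multi-group study (all five presets by default).

    One sub-seed is derived per group from the master seed, so adding or
    removing a group does not perturb the others' data.
    """
    presets = GROUP_PRESETS if presets is None else presets
    sizes = GROUP_SIZES if sizes is None else sizes
    master = np.random.SeedSequence(int(seed))
    sessions: list[SessionRecord] = []
    for group_ss, group in zip(master.spawn(len(presets)), presets):
        sessions.extend(
            simulate_cohort(
                presets[group],
                sizes[group],
                group_ss,
                group=group,
                duration_bins=duration_bins,
            )
        )
    return sessions
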