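"""Bin-based free-operant reward schedule.

The task divides each block into unsignalled 1-second bins.  Within a bin
the agent either presses (only the first press counts) or withholds; at the
end of the bin an outcome is delivered with probability ``p_contingent``
(P(O|A)) if a press occurred and ``p_noncontingent`` (P(O|~A)) otherwise.
The programmed instrumental contingency of a block is the difference
between the two conditional probabilities, ``delta_p = P(O|A) - P(O|~A)``.

A session consists of 12 such blocks of 60 bins: a fixed three-block
training triplet (high contingency, degraded contingency, zero
contingency) followed by nine experimental blocks whose order is
counterbalanced across subjects with a cyclic Latin square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BlockSpec",
    "BinRecord",
    "SessionSpec",
    "BlockResult",
    "SessionRecord",
    "DEFAULT_DURATION_BINS",
    "ANALYSED_CONDITIONS",
    "SIMULTANEOUS_CONDITIONS",
    "EXPERIMENTAL_CONDITIONS",
    "TRAINING_TRIPLET",
    "GROUPS",
    "delta_p",
    "latin_square",
    "make_session_spec",
    "constant_policy",
    "run_block",
]

DEFAULT_DURATION_BINS = 60

#: Group labels carried through session records and logs.
GROUPS = (
    "vmPFC",
    "latPFC",
    "age_matched_control",
    "older_control",
    "younger_control",
)


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return value


def delta_p(p_contingent: float, p_noncontingent: float) -> float:
    """Programmed instrumental contingency, ΔP = P(O|A) − P(O|~A).

    Positive values mean pressing raises the chance of reward, negative
    values mean pressing lowers it, and zero means the action has no
    causal effect on outcome delivery.

    Parameters
    ----------
    p_contingent : float
        Probability of an outcome given a press, in [0, 1].
    p_noncontingent : float
        Probability of an outcome given no press, in [0, 1].

    Returns
    -------
    float
        Signed contingency in [−1, 1].
    """
    p_contingent = _check_probability(p_contingent, "p_contingent")
    p_noncontingent = _check_probability(p_noncontingent, "p_noncontingent")
    return p_contingent - p_noncontingent


@dataclass(frozen=True)
class BlockSpec:
    """Programmed conditional probabilities and duration of one block."""

    p_contingent: float
    p_noncontingent: float
    duration_bins: int = DEFAULT_DURATION_BINS
    role: str = "experimental"

    def __post_init__(self) -> None:
        _check_probability(self.p_contingent, "p_contingent")
        _check_probability(self.p_noncontingent, "p_noncontingent")
        if int(self.duration_bins) < 1:
            raise ValueError("duration_bins must be >= 1")
        if self.role not in ("training", "experimental"):
            raise ValueError(f"unknown block role {self.role!r}")

    @property
    def delta_p(self) -> float:
        return delta_p(self.p_contingent, self.p_noncontingent)


@dataclass(frozen=True)
class BinRecord:
    """One 1-second bin: whether a (first) press occurred and whether it
    was followed by an outcome."""

    pressed: bool
    rewarded: bool


# The five analysed conditions: one conditional probability varied while
# the other is held at zero.  ΔP spans −0.6 … 0.6.
ANALYSED_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.0, 0.6),
    (0.0, 0.3),
    (0.0, 0.0),
    (0.3, 0.0),
    (0.6, 0.0),
)

# The remaining four experimental blocks vary both probabilities
# simultaneously; they are presented but excluded from analysis.
SIMULTANEOUS_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.6, 0.3),
    (0.3, 0.6),
    (0.6, 0.6),
    (0.3, 0.3),
)

EXPERIMENTAL_CONDITIONS: tuple[tuple[float, float], ...] = (
    ANALYSED_CONDITIONS + SIMULTANEOUS_CONDITIONS
)

# Fixed training triplet: high contingency, degraded contingency (P(O|~A)
# raised with P(O|A) held), zero contingency.
TRAINING_TRIPLET: tuple[tuple[float, float], ...] = (
    (0.6, 0.0),
    (0.6, 0.6),
    (0.0, 0.0),
)


@dataclass(frozen=True)
class SessionSpec:
    """Ordered block list for one subject's session."""

    blocks: tuple[BlockSpec, ...]
    order_index: int

    def __post_init__(self) -> None:
        if len(self.blocks) != 12:
            raise ValueError(f"a session has 12 blocks, got {len(self.blocks)}")


@dataclass
class BlockResult:
    """One completed block: its spec, the per-bin records and the
    block-end causal rating (None until rated)."""

    spec: BlockSpec
    bins: list[BinRecord]
    rating: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.bins) != self.spec.duration_bins:
            raise ValueError(
                f"bin count {len(self.bins)} != duration_bins "
                f"{self.spec.duration_bins}"
            )
        if self.rating is not None and not (-100.0 <= self.rating <= 100.0):
            raise ValueError("rating must be in [-100, 100]")


@dataclass
class SessionRecord:
    """Full session for one subject: blocks of bins plus one causal
    rating per block, with subject and group labels."""

    subject_id: str
    group: str
    blocks: list[BlockResult] = field(default_factory=list)


def latin_square(n: int) -> np.ndarray:
    """Cyclic n×n Latin square: entry (r, c) = (r + c) mod n.

    Every symbol appears exactly once per row and per column, which
    provides the positional counterbalancing required for the nine
    experimental blocks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(n)
    return (idx[:, None] + idx[None, :]) % n


def make_session_spec(
    order_index: int,
    *,
    duration_bins: int = DEFAULT_DURATION_BINS,
    training: Sequence[tuple[float, float]] = TRAINING_TRIPLET,
    conditions: Sequence[tuple[float, float]] = EXPERIMENTAL_CONDITIONS,
) -> SessionSpec:
    """Build the 12-block session for Latin-square row ``order_index``.

    Blocks 1–3 are the fixed training triplet (identical for every
    subject); blocks 4–12 are the experimental conditions permuted by the
    chosen row of a cyclic Latin square over ``conditions``.

    Raises
    ------
    ValueError
        If ``order_index`` is outside ``[0, len(conditions))``.
    """
    n = len(conditions)
    if not (0 <= order_index < n):
        raise ValueError(
            f"order_index must be in [0, {n}), got {order_index}"
        )
    square = latin_square(n)
    blocks = [
        BlockSpec(pc, pnc, duration_bins, role="training")
        for pc, pnc in training
    ]
    for col in range(n):
        pc, pnc = conditions[square[order_index, col]]
        blocks.append(BlockSpec(pc, pnc, duration_bins, role="experimental"))
    return SessionSpec(blocks=tuple(blocks), order_index=order_index)


def constant_policy(p: float) -> Callable[[int], float]:
    """Press policy that presses with fixed probability ``p`` in every bin."""
    _check_probability(p, "press probability")
    return lambda _bin: p


def run_block(
    press_policy: Callable[[int], float],
    spec: BlockSpec,
    rng: np.random.Generator,
    *,
    outcome_rng: Optional[np.random.Generator] = None,
    observer: Optional[Callable[[bool, bool], None]] = None,
) -> list[BinRecord]:
    """Simulate one block of the free-operant schedule.

    For each bin the policy is queried for a press probability; a press is
    drawn from it, and the outcome is then drawn from ``p_contingent`` if
    a press occurred, else from ``p_noncontingent``.  Press draws come
    from ``rng`` and outcome draws from ``outcome_rng`` (``rng`` again if
    not given), so behaviour and schedule noise can run on independent
    streams.

    ``observer(pressed, rewarded)`` is called after every bin; adaptive
    agents use it to update their estimates as the block unfolds.
    """
    if outcome_rng is None:
        outcome_rng = rng
    n = spec.duration_bins
    # drawing the uniforms up front keeps the per-bin loop cheap
    press_u = rng.random(n)
    outcome_u = outcome_rng.random(n)
    p_c = spec.p_contingent
    p_nc = spec.p_noncontingent
    bins: list[BinRecord] = []
    append = bins.append
    for i in range(n):
        p_press = press_policy(i)
        if not (0.0 <= p_press <= 1.0):
            raise ValueError(
                f"press policy returned {p_press!r} outside [0, 1] at bin {i}"
            )
        pressed = press_u[i] < p_press
        rewarded = outcome_u[i] < (p_c if pressed else p_nc)
        append(BinRecord(pressed=bool(pressed), rewarded=bool(rewarded)))
        if observer is not None:
            observer(pressed, rewarded)
    return bins
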