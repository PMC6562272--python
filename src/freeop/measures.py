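"""Outcome measures computed from session logs.

Two quantities are analysed per block: the response rate (pressed bins
divided by total bins — with 1-second bins this is presses per second)
and the block-end causal rating.  Analyses are restricted to the
experimental blocks in which a single conditional probability was varied
while the other stayed at zero: the positive set (ΔP ∈ {0, 0.3, 0.6},
P(O|~A) = 0) and the negative set (ΔP ∈ {−0.6, −0.3, 0}, P(O|A) = 0).
The zero-contingency block (0, 0) serves as the 0 level of both sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .schedule import BinRecord, BlockResult, SessionRecord

__all__ = [
    "BlockMeasures",
    "response_rate",
    "experienced_probabilities",
    "block_measures",
    "filter_analysed_blocks",
    "degradation_contrast",
    "measures_frame",
]

_SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class BlockMeasures:
    """Per-block outcome measures.

    ``experienced_p_contingent`` / ``experienced_p_noncontingent`` are
    NaN when their denominator is zero (the agent never, or always,
    pressed in the block).
    """

    programmed_delta_p: float
    response_rate: float
    experienced_p_contingent: float
    experienced_p_noncontingent: float
    rating: float | None


def response_rate(bins: Sequence[BinRecord]) -> float:
    """Pressed bins / total bins for one block.

    Raises ``ValueError`` on an empty bin list.
    """
    if len(bins) == 0:
        raise ValueError("response_rate of an empty block is undefined")
    return sum(b.pressed for b in bins) / len(bins)


def experienced_probabilities(
    bins: Sequence[BinRecord],
) -> tuple[float, float]:
    """Experienced P(O|A) and P(O|~A) for one block.

    Conditional frequencies of reward among pressed and unpressed bins.
    A side whose denominator is zero is returned as NaN — a flag value,
    not an error — and propagates as missing data downstream.
    """
    if len(bins) == 0:
        raise ValueError("experienced probabilities of an empty block are undefined")
    n_press = n_press_rew = n_nopress = n_nopress_rew = 0
    for b in bins:
        if b.pressed:
            n_press += 1
            n_press_rew += b.rewarded
        else:
            n_nopress += 1
            n_nopress_rew += b.rewarded
    p_c = n_press_rew / n_press if n_press else math.nan
    p_nc = n_nopress_rew / n_nopress if n_nopress else math.nan
    return p_c, p_nc


def block_measures(block: BlockResult) -> BlockMeasures:
    """All per-block measures for one completed block."""
    p_c, p_nc = experienced_probabilities(block.bins)
    return BlockMeasures(
        programmed_delta_p=block.spec.delta_p,
        response_rate=response_rate(block.bins),
        experienced_p_contingent=p_c,
        experienced_p_noncontingent=p_nc,
        rating=block.rating,
    )


def _in_sign(block: BlockResult, sign: str) -> bool:
    if block.spec.role != "experimental":
        return False
    if sign == "positive":
        return block.spec.p_noncontingent == 0.0
    return block.spec.p_contingent == 0.0


def filter_analysed_blocks(
    session: SessionRecord, sign: str
) -> list[BlockMeasures]:
    """Measures for the analysed blocks of one contingency sign.

    ``sign='positive'`` selects experimental blocks with P(O|~A) = 0
    (ΔP ∈ {0, 0.3, 0.6}); ``sign='negative'`` those with P(O|A) = 0
    (ΔP ∈ {−0.6, −0.3, 0}).  The (0, 0) block qualifies for both signs;
    training blocks never qualify, even when their probabilities match.
    Blocks are returned in ascending ΔP order.
    """
    if sign not in _SIGNS:
        raise ValueError(f"sign must be one of {_SIGNS}, got {sign!r}")
    selected = [
        block_measures(b) for b in session.blocks if _in_sign(b, sign)
    ]
    selected.sort(key=lambda m: m.programmed_delta_p)
    return selected


def degradation_contrast(session: SessionRecord) -> float:
    """Response-rate drop from training Block 1 to training Block 2.

    Block 1 runs a positive contingency and Block 2 degrades it by
    raising P(O|~A), so the pair satisfies the conditions of contingency
    degradation; a positive contrast indicates adaptive reduction of
    responding once outcomes arrive for free.
    """
    if len(session.blocks) < 2:
        raise ValueError("session lacks the training blocks")
    b1, b2 = session.blocks[0], session.blocks[1]
    if b1.spec.role != "training" or b2.spec.role != "training":
        raise ValueError("blocks 1-2 are not training blocks")
    if not (b1.spec.delta_p > 0 and b2.spec.delta_p == 0):
        raise ValueError(
            "training blocks 1-2 do not form a degradation pair "
            f"(ΔP = {b1.spec.delta_p}, {b2.spec.delta_p})"
        )
    return response_rate(b1.bins) - response_rate(b2.bins)


def measures_frame(
    sessions: Iterable[SessionRecord], sign: str
) -> pd.DataFrame:
    """Long-format analysed-block measures for a set of sessions.

    One row per subject × analysed block with columns ``subject_id``,
    ``group``, ``delta_p``, ``response_rate``, ``rating``,
    ``experienced_p_contingent`` and ``experienced_p_noncontingent`` —
    the table consumed by the statistics stage.
    """
    rows = []
    for s in sessions:
        for m in filter_analysed_blocks(s, sign):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "delta_p": m.programmed_delta_p,
                    "response_rate": m.response_rate,
                    "rating": m.rating,
                    "experienced_p_contingent": m.experienced_p_contingent,
                    "experienced_p_noncontingent": m.experienced_p_noncontingent,
                }
            )
    return pd.DataFrame(rows)
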