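"""Signal-detection response bias for the probabilistic reward task (PRT).

The PRT presents two barely discriminable stimuli; correct responses to
the "rich" stimulus are rewarded three times more often than correct
responses to the "lean" one.  Reward learning is quantified by the
signal-detection response bias

    log b = 0.5 * log10( (rich_correct + 0.5)(lean_incorrect + 0.5)
                       / (rich_incorrect + 0.5)(lean_correct + 0.5) ),

with 0.5 added to every cell so the statistic is finite for empty cells.
The behavioral anhedonia measure is the stress-induced double difference
(block 2 - block 1 post-stress) - (block 2 - block 1 pre-stress).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlockCounts",
    "tally_block",
    "response_bias",
    "stress_change_rb",
    "subject_bias_table",
]

_STIMULI = ("rich", "lean")


@dataclass(frozen=True)
class BlockCounts:
    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int
    rich_rewarded: int = 0
    lean_rewarded: int = 0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rich_rewarded > self.rich_correct or self.lean_rewarded > self.lean_correct:
            raise ValueError("rewarded counts cannot exceed correct counts")

    @property
    def total(self) -> int:
        return (self.rich_correct + self.rich_incorrect
                + self.lean_correct + self.lean_incorrect)


def tally_block(trials: pd.DataFrame) -> BlockCounts:
    """Exhaustive, mutually exclusive counts for one block of PRT trials."""
    unknown = set(trials["stimulus"]) - set(_STIMULI)
    if unknown:
        raise ValueError(f"unknown stimulus labels: {sorted(unknown)}")
    c = trials["correct"].astype(bool)
    rich = trials["stimulus"] == "rich"
    rewarded = trials["rewarded"].astype(bool) if "rewarded" in trials else pd.Series(False, index=trials.index)
    return BlockCounts(
        rich_correct=int((rich & c).sum()),
        rich_incorrect=int((rich & ~c).sum()),
        lean_correct=int((~rich & c).sum()),
        lean_incorrect=int((~rich & ~c).sum()),
        rich_rewarded=int((rich & c & rewarded).sum()),
        lean_rewarded=int((~rich & c & rewarded).sum()),
    )


def response_bias(counts: BlockCounts, base: float = 10.0) -> float:
    """Signal-detection response bias log b with 0.5 cell correction."""
    num = (counts.rich_correct + 0.5) * (counts.lean_incorrect + 0.5)
    den = (counts.rich_incorrect + 0.5) * (counts.lean_correct + 0.5)
    return float(0.5 * np.log(num / den) / np.log(base))


def stress_change_rb(
    pre: tuple[float, float], post: tuple[float, float]
) -> float:
    """Stress-induced change in reward learning:
    (post B2 - post B1) - (pre B2 - pre B1); inputs are (B1, B2) response
    biases per session."""
    for pair in (pre, post):
        if len(pair) != 2 or any(v is None or not np.isfinite(v) for v in pair):
            raise ValueError("each session needs finite (block1, block2) response biases")
    return float((post[1] - post[0]) - (pre[1] - pre[0]))


def subject_bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject response biases and stress change from trial records.

    Expects columns ``subject, session, block, stimulus, response,
    correct, rewarded`` with sessions ``prestress``/``poststress`` and
    blocks 1/2.  Subjects missing any of the four session-blocks are
    dropped (listwise for this behavioral unit) and reported via the
    ``complete`` column.
    """
    rows = []
    for subject, sub in trials.groupby("subject", sort=True):
        rb: dict[tuple[str, int], float] = {}
        for (session, block), blk in sub.groupby(["session", "block"]):
            rb[(str(session), int(block))] = response_bias(tally_block(blk))
        keys = [("prestress", 1), ("prestress", 2), ("poststress", 1), ("poststress", 2)]
        complete = all(k in rb for k in keys)
        row = {
            "subject": subject,
            "rb_pre_b1": rb.get(keys[0], np.nan),
            "rb_pre_b2": rb.get(keys[1], np.nan),
            "rb_post_b1": rb.get(keys[2], np.nan),
            "rb_post_b2": rb.get(keys[3], np.nan),
            "complete": complete,
        }
        row["stress_change"] = (
            stress_change_rb((row["rb_pre_b1"], row["rb_pre_b2"]),
                             (row["rb_post_b1"], row["rb_post_b2"]))
            if complete else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
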