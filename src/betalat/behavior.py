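"""Categorization of button presses and behavioral summaries.

A press within 2 s after a deviant in the attended ear is a hit; within 2 s
after a deviant in the unattended ear a spatial error (SE); anything else a
random error (RE). When a press falls in the 2-s windows of several deviants
it is assigned to the most recent deviant that has not already absorbed a
response; each deviant absorbs at most one response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .schedule import SEQUENCE_PERIOD, SessionSchedule

RESPONSE_WINDOW = 2.0

HIT = "hit"
SE = "SE"
RE = "RE"


@dataclass(frozen=True)
class ResponseRecord:
    time: float  # seconds from block start
    block: int
    category: str  # hit | SE | RE
    latency: Optional[float] = None  # seconds from the assigned deviant

    def __post_init__(self):
        if self.category in (HIT, SE):
            if self.latency is None or not 0 < self.latency <= RESPONSE_WINDOW:
                raise ValueError("hit/SE latency must lie in (0, 2] s")


@dataclass(frozen=True)
class BehaviorSummary:
    prop_hits: float  # percent of total presses
    prop_se: float
    prop_re: float
    tdr_high: float  # attended deviants responded to, per predictability
    tdr_low: float
    n_responses: int
    valid: bool  # False when there were no responses at all


def categorize_responses(responses, schedule: SessionSchedule) -> list:
    """Assign each (time, block) press exactly one category.

    ``responses`` is an iterable of (time_s, block_index) pairs; times must
    be sorted within each block. A press outside the block bounds
    [0, duration + 2 s] is rejected with an error.
    """
    by_block = {}
    for t, b in responses:
        by_block.setdefault(int(b), []).append(float(t))

    records = []
    for bi, times in sorted(by_block.items()):
        if bi < 0 or bi >= schedule.n_blocks:
            raise ValueError(f"unknown block index {bi}")
        block = schedule.blocks[bi]
        bound = block.duration + RESPONSE_WINDOW
        if any(np.diff(times) < 0):
            raise ValueError(f"response times not sorted within block {bi}")
        deviants = sorted(block.deviant_events(), key=lambda e: e.onset)
        absorbed = [False] * len(deviants)
        for t in times:
            if not 0 <= t <= bound:
                raise ValueError(
                    f"response at {t:.3f} s outside block {bi} bounds "
                    f"[0, {bound:.1f}]"
                )
            candidates = [
                i for i, e in enumerate(deviants)
                if not absorbed[i] and 0 < t - e.onset <= RESPONSE_WINDOW
            ]
            if candidates:
                i = max(candidates, key=lambda i: deviants[i].onset)
                absorbed[i] = True
                cat = HIT if deviants[i].ear == block.attended_ear else SE
                records.append(
                    ResponseRecord(time=t, block=bi, category=cat,
                                   latency=t - deviants[i].onset)
                )
            else:
                records.append(ResponseRecord(time=t, block=bi, category=RE))
    return records


def target_detection_rate(records, schedule, predictability: str) -> float:
    """Proportion of attended-ear deviants responded to (hits / targets)."""
    blocks = [i for i, b in enumerate(schedule.blocks)
              if b.predictability == predictability]
    n_targets = sum(schedule.blocks[i].attended_deviant_count() for i in blocks)
    n_hits = sum(r.category == HIT and r.block in blocks for r in records)
    return n_hits / n_targets


def summarize_behavior(records, schedule: SessionSchedule) -> BehaviorSummary:
    """Response-type proportions (% of presses) and per-predictability TDR."""
    n = len(records)
    if n == 0:
        return BehaviorSummary(
            prop_hits=np.nan, prop_se=np.nan, prop_re=np.nan,
            tdr_high=0.0, tdr_low=0.0, n_responses=0, valid=False,
        )
    counts = {HIT: 0, SE: 0, RE: 0}
    for r in records:
        counts[r.category] += 1
    return BehaviorSummary(
        prop_hits=100.0 * counts[HIT] / n,
        prop_se=100.0 * counts[SE] / n,
        prop_re=100.0 * counts[RE] / n,
        tdr_high=target_detection_rate(records, schedule, "high"),
        tdr_low=target_detection_rate(records, schedule, "low"),
        n_responses=n,
        valid=True,
    )


def summary_frame(summaries: dict) -> pd.DataFrame:
    """Per-subject summary table (rows: subjects)."""
    rows = []
    for subject, s in summaries.items():
        rows.append((subject, s.prop_hits, s.prop_se, s.prop_re,
                     s.tdr_high, s.tdr_low, s.n_responses))
    return pd.DataFrame(
        rows, columns=["subject", "prop_hits", "prop_se", "prop_re",
                       "tdr_high", "tdr_low", "n_responses"]
    )
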