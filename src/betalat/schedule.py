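"""Dichotic rhythm stimulus schedules.

Two isochronous tone streams are presented, one per ear: a slow stream
(SOA 0.8 s, 1.25 Hz, 3 tones) and a fast stream (SOA 0.6 s, 5/3 Hz, 4 tones).
The streams start together, so each 2.4-s sequence cycle contains 7 tones at
6 distinct onsets (a 3-against-4 polyrhythm). Irregular sequences carry one
SOA deviant: a single tone shifted 90 ms earlier. Blocks contain 50 regular
sequences plus 10 (high predictability) or 25 (low predictability) irregular
ones, with at least one regular sequence between irregulars. A session is 8
blocks covering the full attended-ear x dichotic-configuration x
predictability counterbalancing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

SLOW_SOA = 0.8
FAST_SOA = 0.6
N_SLOW = 3
N_FAST = 4
SEQUENCE_PERIOD = N_SLOW * SLOW_SOA  # 2.4 s (== N_FAST * FAST_SOA)
DEVIANT_SHIFT = -0.090
N_REGULAR = 50
N_IRREGULAR = {"high": 10, "low": 25}

EARS = ("left", "right")
PREDICTABILITIES = ("high", "low")
DICHOTIC_CONFIGS = ("slow_left", "slow_right")

#: merged sequence position (2..6) -> (stream, within-stream position)
#: position 1 is the shared first beat of both streams and never deviates.
ELIGIBLE_DEVIANT_POSITIONS = {
    2: ("fast", 2),
    3: ("slow", 2),
    4: ("fast", 3),
    5: ("slow", 3),
    6: ("fast", 4),
}


@dataclass(frozen=True)
class ToneEvent:
    onset: float  # seconds from block start
    ear: str
    stream: str  # 'slow' | 'fast'
    sequence_index: int
    position_in_sequence: int  # merged order 1..6 (the two first tones share 1)
    position_in_stream: int  # 1..3 (slow) or 1..4 (fast)
    is_deviant: bool = False


@dataclass(frozen=True)
class SequenceSpec:
    slow_soa: float = SLOW_SOA
    fast_soa: float = FAST_SOA
    n_slow: int = N_SLOW
    n_fast: int = N_FAST
    deviant_shift: Optional[float] = None
    deviant_stream: Optional[str] = None
    deviant_position: Optional[int] = None  # within-stream position

    def __post_init__(self):
        if abs(self.n_slow * self.slow_soa - self.n_fast * self.fast_soa) > 1e-9:
            raise ValueError("streams must share the sequence period")
        has_dev = self.deviant_shift is not None
        if has_dev != (self.deviant_position is not None) or (
            has_dev != (self.deviant_stream is not None)
        ):
            raise ValueError("deviant fields must be given together")
        if has_dev:
            if self.deviant_stream not in ("slow", "fast"):
                raise ValueError("deviant_stream must be 'slow' or 'fast'")
            if self.deviant_position == 1:
                raise ValueError(
                    "deviants may occur only in the 5 tones following the first"
                )
            n = self.n_slow if self.deviant_stream == "slow" else self.n_fast
            if not 2 <= self.deviant_position <= n:
                raise ValueError("deviant_position outside the stream")

    @property
    def period(self) -> float:
        return self.n_slow * self.slow_soa

    @property
    def is_regular(self) -> bool:
        return self.deviant_shift is None


def regular_sequence() -> SequenceSpec:
    return SequenceSpec()


def deviant_sequence(merged_position: int) -> SequenceSpec:
    """Irregular sequence with the deviant at a merged position 2..6."""
    if merged_position not in ELIGIBLE_DEVIANT_POSITIONS:
        raise ValueError(
            "deviants may occur only in the 5 tones following the first"
        )
    stream, pos = ELIGIBLE_DEVIANT_POSITIONS[merged_position]
    return SequenceSpec(
        deviant_shift=DEVIANT_SHIFT, deviant_stream=stream, deviant_position=pos
    )


def build_sequence(
    spec: SequenceSpec,
    sequence_index: int = 0,
    t0: float = 0.0,
    slow_ear: str = "left",
) -> list:
    """Tone events of one sequence; the deviant tone alone is shifted earlier.

    Returns 7 events (3 slow + 4 fast); the two streams' first tones are
    simultaneous, so there are 6 distinct onsets.
    """
    fast_ear = "right" if slow_ear == "left" else "left"
    nominal = []  # (nominal_onset, stream, within-stream position)
    for i in range(spec.n_slow):
        nominal.append((i * spec.slow_soa, "slow", i + 1))
    for i in range(spec.n_fast):
        nominal.append((i * spec.fast_soa, "fast", i + 1))
    # merged position from nominal onsets: simultaneous tones share a rank
    onsets = sorted({round(t, 9) for t, _, _ in nominal})
    rank = {t: i + 1 for i, t in enumerate(onsets)}

    events = []
    for t, stream, pos in nominal:
        is_dev = (
            not spec.is_regular
            and stream == spec.deviant_stream
            and pos == spec.deviant_position
        )
        onset = t + (spec.deviant_shift if is_dev else 0.0)
        events.append(
            ToneEvent(
                onset=t0 + onset,
                ear=slow_ear if stream == "slow" else fast_ear,
                stream=stream,
                sequence_index=sequence_index,
                position_in_sequence=rank[round(t, 9)],
                position_in_stream=pos,
                is_deviant=is_dev,
            )
        )
    events.sort(key=lambda e: (e.onset, e.stream))
    return events


@dataclass(frozen=True)
class BlockSpec:
    """One experimental block: composition, condition labels and tone events."""

    predictability: str
    attended_ear: str
    dichotic_config: str
    sequences: tuple  # SequenceSpec per sequence, in presentation order
    events: tuple  # ToneEvent, chronological

    def __post_init__(self):
        if self.predictability not in PREDICTABILITIES:
            raise ValueError(f"bad predictability {self.predictability!r}")
        if self.attended_ear not in EARS:
            raise ValueError(f"bad attended_ear {self.attended_ear!r}")
        if self.dichotic_config not in DICHOTIC_CONFIGS:
            raise ValueError(f"bad dichotic_config {self.dichotic_config!r}")

    @property
    def slow_ear(self) -> str:
        return "left" if self.dichotic_config == "slow_left" else "right"

    @property
    def attended_tempo(self) -> str:
        return "slow" if self.slow_ear == self.attended_ear else "fast"

    @property
    def attended_soa(self) -> float:
        return SLOW_SOA if self.attended_tempo == "slow" else FAST_SOA

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def duration(self) -> float:
        return self.n_sequences * SEQUENCE_PERIOD

    def is_regular(self) -> np.ndarray:
        return np.array([s.is_regular for s in self.sequences])

    def deviant_events(self) -> list:
        return [e for e in self.events if e.is_deviant]

    def attended_deviant_count(self) -> int:
        return sum(e.ear == self.attended_ear for e in self.deviant_events())

    def retained_regular_indices(self) -> np.ndarray:
        """Regular sequences kept for EEG analysis.

        A regular sequence is excluded when the immediately preceding
        sequence contains an SOA deviant (motor/deviance confound); the
        first sequence of a block has no predecessor and is kept if regular.
        """
        reg = self.is_regular()
        keep = reg.copy()
        keep[1:] &= reg[:-1]
        return np.where(keep)[0]


def build_block(
    predictability: str,
    attended_ear: str,
    dichotic_config: str,
    rng: np.random.Generator,
) -> BlockSpec:
    """Assemble one block: 50 regular + 10/25 irregular sequences.

    Irregular sequences are placed by drawing, without replacement, distinct
    "gaps" immediately before each regular sequence; this realizes uniform
    placement under the constraints that at least one regular sequence
    separates irregulars and that the block ends with a regular sequence.
    Deviant positions are balanced over the 5 eligible tones (2 or 5 each).
    """
    if predictability not in N_IRREGULAR:
        raise ValueError(f"bad predictability {predictability!r}")
    n_irr = N_IRREGULAR[predictability]
    per_position = n_irr // len(ELIGIBLE_DEVIANT_POSITIONS)
    positions = np.repeat(sorted(ELIGIBLE_DEVIANT_POSITIONS), per_position)
    rng.shuffle(positions)
    gaps = set(rng.choice(N_REGULAR, size=n_irr, replace=False).tolist())

    specs = []
    it = iter(positions)
    for g in range(N_REGULAR):
        if g in gaps:
            specs.append(deviant_sequence(int(next(it))))
        specs.append(regular_sequence())

    slow_ear = "left" if dichotic_config == "slow_left" else "right"
    events = []
    for k, spec in enumerate(specs):
        events.extend(
            build_sequence(spec, sequence_index=k, t0=k * SEQUENCE_PERIOD,
                           slow_ear=slow_ear)
        )
    return BlockSpec(
        predictability=predictability,
        attended_ear=attended_ear,
        dichotic_config=dichotic_config,
        sequences=tuple(specs),
        events=tuple(events),
    )


@dataclass(frozen=True)
class SessionSchedule:
    """8 blocks covering the 2 x 2 x 2 counterbalancing, in random order."""

    blocks: tuple

    def __post_init__(self):
        cells = {(b.attended_ear, b.dichotic_config, b.predictability)
                 for b in self.blocks}
        if len(cells) != len(self.blocks):
            raise ValueError("duplicate counterbalancing cells")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def counterbalancing_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": range(self.n_blocks),
                "attended_ear": [b.attended_ear for b in self.blocks],
                "dichotic_config": [b.dichotic_config for b in self.blocks],
                "predictability": [b.predictability for b in self.blocks],
                "attended_tempo": [b.attended_tempo for b in self.blocks],
            }
        )

    def attended_deviant_total(self) -> int:
        return sum(b.attended_deviant_count() for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, b in enumerate(self.blocks):
            for e in b.events:
                rows.append(
                    (bi, e.sequence_index, e.onset, e.ear, e.stream,
                     e.position_in_sequence, e.is_deviant, b.attended_ear,
                     b.predictability, b.dichotic_config)
                )
        return pd.DataFrame(
            rows,
            columns=["block", "sequence_index", "onset_s", "ear", "stream",
                     "position", "is_deviant", "attended_ear",
                     "predictability", "dichotic_config"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_session(rng: np.random.Generator) -> SessionSchedule:
    """Full counterbalanced 8-block session in randomized block order."""
    cells = [
        (ear, cfg, pred)
        for ear in EARS
        for cfg in DICHOTIC_CONFIGS
        for pred in PREDICTABILITIES
    ]
    order = rng.permutation(len(cells))
    blocks = tuple(
        build_block(cells[i][2], cells[i][0], cells[i][1], rng) for i in order
    )
    return SessionSchedule(blocks=blocks)


def read_session_tsv(path) -> pd.DataFrame:
    """Read a schedule TSV back as a DataFrame (long event table)."""
    return pd.read_csv(path, sep="\t")
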