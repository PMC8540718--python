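"""From momentary self-reports to a per-second mood label track.

Each EMA answer is a (happiness, activeness) pair on 0–4 Likert scales.
Centering both scales at 2 places the answer in the valence × arousal plane
of the circumplex model of affect; the angular octant names the discrete
mood state (pleasure at 0°, excitement at 45°, arousal at 90°, distress,
displeasure, depression, sleepiness, contentment going round), with the
exact center mapped to a distinct *neutral* state.

An answer's state is then extrapolated to a window of W minutes centered on
the answer time, on the assumption that the reported affect persists for a
while before and after the report. Overlapping claims of consecutive answers
are split evenly at the midpoint between the answer times, and windows are
truncated at the recording bounds, so the labeled seconds of a day form a
partition. Seconds claimed by no answer carry the sentinel −1.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .e4_io import EMAAnswer

__all__ = [
    "Mood",
    "UNLABELED",
    "LabelSeries",
    "EMA_WINDOW_CHOICES_MIN",
    "mood_from_answer",
    "likert_mood_table",
    "expand_labels",
    "attach_labels",
]

#: sentinel for seconds carrying no mood state
UNLABELED = -1

#: extrapolation window widths used by the study protocol, minutes
EMA_WINDOW_CHOICES_MIN = (30, 60, 120)


class Mood(enum.IntEnum):
    """Discrete circumplex states; values are the label codes."""

    PLEASURE = 0
    EXCITEMENT = 1
    AROUSAL = 2
    DISTRESS = 3
    DISPLEASURE = 4
    DEPRESSION = 5
    SLEEPINESS = 6
    CONTENTMENT = 7
    NEUTRAL = 8

    @property
    def display_name(self) -> str:
        return self.name.capitalize()


#: octant order anticlockwise from the positive-valence axis
_OCTANTS = [
    Mood.PLEASURE, Mood.EXCITEMENT, Mood.AROUSAL, Mood.DISTRESS,
    Mood.DISPLEASURE, Mood.DEPRESSION, Mood.SLEEPINESS, Mood.CONTENTMENT,
]


def mood_from_answer(happiness: int, activeness: int) -> Mood:
    """Quantize a Likert pair to its circumplex octant.

    Both scales are centered at 2 (valence = happiness − 2, arousal =
    activeness − 2); the 45°-wide sectors are centered on the eight state
    directions, and the exact center is *neutral*.
    """
    if not (0 <= happiness <= 4 and 0 <= activeness <= 4):
        raise ValueError(f"Likert values must be in 0..4, got ({happiness}, {activeness})")
    v, a = happiness - 2, activeness - 2
    if v == 0 and a == 0:
        return Mood.NEUTRAL
    angle = math.degrees(math.atan2(a, v))
    sector = int(round(angle / 45.0)) % 8
    return _OCTANTS[sector]


def likert_mood_table() -> pd.DataFrame:
    """The full 25-cell Likert grid with its state assignment."""
    rows = [
        {
            "happiness": h,
            "activeness": a,
            "code": int(mood_from_answer(h, a)),
            "state": mood_from_answer(h, a).name.lower(),
        }
        for h in range(5)
        for a in range(5)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LabelSeries:
    """Per-second mood codes covering one wear day at 1 Hz."""

    start_epoch: float
    labels: np.ndarray  # int array; UNLABELED or Mood codes

    rate: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        valid = set(int(m) for m in Mood) | {UNLABELED}
        if labels.size and not set(np.unique(labels)) <= valid:
            raise ValueError("labels contain codes outside the mood vocabulary")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def end_epoch(self) -> float:
        return self.start_epoch + self.labels.size / self.rate

    def labeled_seconds(self) -> int:
        return int(np.sum(self.labels != UNLABELED))

    def to_frame(self) -> pd.DataFrame:
        epochs = self.start_epoch + np.arange(self.labels.size) / self.rate
        return pd.DataFrame({"epoch": epochs, "code": self.labels})


def _claimed_intervals(
    emas: Sequence[EMAAnswer], day_start: float, day_end: float, width_s: float
) -> list[tuple[float, float]]:
    """Per-answer claimed [l, r) after midpoint splits and day truncation."""
    times = [a.answer_epoch for a in emas]
    half = width_s / 2.0
    lefts = [t - half for t in times]
    rights = [t + half for t in times]
    for i in range(len(times) - 1):
        if rights[i] > lefts[i + 1]:  # overlapping claims: split at the midpoint
            mid = (times[i] + times[i + 1]) / 2.0
            rights[i] = min(rights[i], mid)
            lefts[i + 1] = max(lefts[i + 1], mid)
    return [
        (max(l, day_start), min(r, day_end)) for l, r in zip(lefts, rights)
    ]


def expand_labels(
    emas: Sequence[EMAAnswer],
    day_start: float,
    day_end: float,
    width_min: float,
) -> LabelSeries:
    """Extrapolate answers to a per-second label track over the day span.

    Each answer claims ``[t − W/2, t + W/2)``; overlapping claims of
    consecutive answers are split evenly at the midpoint of the answer times
    and claims are truncated at the day bounds, so no second is claimed
    twice. Unclaimed seconds are −1.
    """
    if width_min <= 0:
        raise ValueError("width_min must be positive")
    start = math.floor(day_start)
    n = max(int(math.ceil(day_end)) - start, 0)
    labels = np.full(n, UNLABELED, dtype=np.int64)
    emas = sorted(emas)
    if not emas:
        warnings.warn("no EMA answers in day; label series is all -1")
        return LabelSeries(start_epoch=float(start), labels=labels)
    intervals = _claimed_intervals(emas, day_start, day_end, width_min * 60.0)
    for ema, (l, r) in zip(emas, intervals):
        i0 = max(int(math.ceil(l - start - 1e-9)), 0)
        i1 = min(max(int(math.ceil(r - start - 1e-9)), i0), n)
        labels[i0:i1] = int(mood_from_answer(ema.happiness, ema.activeness))
    return LabelSeries(start_epoch=float(start), labels=labels)


def attach_labels(
    feature_table: pd.DataFrame,
    label_series: LabelSeries,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Assign a mood label to each feature window by per-second majority.

    A window receives label L ≠ −1 when at least ``min_fraction`` of its
    seconds carry L; ties are broken toward the label appearing earlier in
    the window (i.e. the earlier answer). Windows that fail the threshold
    are dropped from the supervised dataset.
    """
    labels = label_series.labels
    s0 = label_series.start_epoch
    out_labels: list[int] = []
    keep: list[bool] = []
    for ws, we in zip(feature_table["window_start_epoch"], feature_table["window_end_epoch"]):
        i0 = max(int(math.ceil(ws - s0 - 1e-9)), 0)
        i1 = min(max(int(math.ceil(we - s0 - 1e-9)), i0), labels.size)
        seg = labels[i0:i1]
        n_window = max(int(round(we - ws)), 1)
        best, best_count, best_first = UNLABELED, 0, -1
        for code in np.unique(seg):
            if code == UNLABELED:
                continue
            count = int(np.sum(seg == code))
            first = int(np.argmax(seg == code))
            if count > best_count or (count == best_count and first < best_first):
                best, best_count, best_first = int(code), count, first
        if best != UNLABELED and best_count >= min_fraction * n_window:
            out_labels.append(best)
            keep.append(True)
        else:
            out_labels.append(UNLABELED)
            keep.append(False)
    table = feature_table.copy()
    table["label"] = out_labels
    return table.loc[keep].reset_index(drop=True)
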