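"""Reading and writing wristband channel recordings and EMA answer logs.

The on-disk channel dialect follows the Empatica E4 session export: one CSV
per channel, whose first row is the session start time (UTC epoch seconds,
fractional allowed) and second row the sample rate in Hz; every following row
is one sample. ``ACC.csv`` carries three comma-separated columns (x, y, z) in
signed counts at 1/64 g per count (8-bit, ±2 g full scale); ``TEMP.csv``,
``EDA.csv`` and ``HR.csv`` carry one column in °C, µS and beats/min.

EMA (ecological momentary assessment) answers — two 5-level Likert items,
happiness and activeness — are stored as a flat CSV log with one row per
answered prompt.

All timestamps in this package are UTC epoch seconds and all intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "SignalRecording",
    "EMAAnswer",
    "DayRecording",
    "FormatError",
    "ACC_COUNTS_PER_G",
    "EXPECTED_RATE_HZ",
    "read_e4_channel",
    "read_acc",
    "read_channel_dir",
    "write_e4_channel",
    "write_acc",
    "read_ema_log",
    "write_ema_log",
    "split_into_days",
]

#: nominal accelerometer scale: signed 8-bit counts over a ±2 g range
ACC_COUNTS_PER_G = 64.0

#: minimum per-channel data for a wear day to count as analysable
MIN_VALID_DAY_S = 600.0


class FormatError(ValueError):
    """A channel or EMA file does not follow the expected dialect."""


class Channel(str, enum.Enum):
    ACC_X = "ACC_X"
    ACC_Y = "ACC_Y"
    ACC_Z = "ACC_Z"
    TEMP = "TEMP"
    EDA = "EDA"
    HR = "HR"

    @property
    def file_stem(self) -> str:
        return "ACC" if self.value.startswith("ACC") else self.value


#: built-in sensor rates of the emulated wristband (Hz)
EXPECTED_RATE_HZ: dict[Channel, float] = {
    Channel.ACC_X: 32.0,
    Channel.ACC_Y: 32.0,
    Channel.ACC_Z: 32.0,
    Channel.TEMP: 4.0,
    Channel.EDA: 4.0,
    Channel.HR: 1.0,
}


@dataclass(frozen=True)
class SignalRecording:
    """One uniformly sampled channel.

    Sample ``k`` is implicitly timestamped ``start_epoch + k / rate``.
    Units: g for ACC (after count scaling), °C for TEMP, µS for EDA,
    beats/min for HR.
    """

    channel: Channel
    start_epoch: float
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError(f"{self.channel.value}: non-finite samples")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def end_epoch(self) -> float:
        """End of the half-open span covered by the samples."""
        return self.start_epoch + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_epoch + np.arange(self.samples.size) / self.rate

    def slice_epoch(self, start: float, end: float) -> np.ndarray:
        """Samples whose timestamps fall in ``[start, end)``."""
        i0 = int(np.ceil((start - self.start_epoch) * self.rate - 1e-9))
        i1 = int(np.ceil((end - self.start_epoch) * self.rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.samples.size)
        return self.samples[i0:i1]


@dataclass(frozen=True, order=True)
class EMAAnswer:
    """One answered mood prompt: happiness and activeness on 0–4 scales."""

    answer_epoch: float
    notify_epoch: float
    happiness: int
    activeness: int
    participant_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in ("happiness", "activeness"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(f"{name} must be an integer in 0..4, got {v!r}")
        if self.answer_epoch < self.notify_epoch:
            raise ValueError(
                "answer_epoch precedes notify_epoch "
                f"({self.answer_epoch} < {self.notify_epoch})"
            )

    @property
    def reaction_time_s(self) -> float:
        return self.answer_epoch - self.notify_epoch


@dataclass
class DayRecording:
    """One wear session (device on in the morning, off before sleep)."""

    participant_id: str
    day_index: int
    channels: dict[Channel, SignalRecording]
    emas: list[EMAAnswer]
    valid: bool = True

    @property
    def span(self) -> tuple[float, float]:
        starts = [rec.start_epoch for rec in self.channels.values()]
        ends = [rec.end_epoch for rec in self.channels.values()]
        return min(starts), max(ends)


# ---------------------------------------------------------------------------
# channel files


def _parse_header(rows: list[list[str]], path: Path) -> tuple[float, float]:
    if len(rows) < 2:
        raise FormatError(f"{path}: need two header rows (start epoch, rate)")
    try:
        start_epoch = float(rows[0][0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: row 1 is not an epoch timestamp: {rows[0]!r}") from exc
    try:
        rate = float(rows[1][0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: row 2 is not a sample rate: {rows[1]!r}") from exc
    if rate <= 0:
        raise FormatError(f"{path}: row 2 rate must be positive, got {rate}")
    return start_epoch, rate


def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]


def read_e4_channel(
    path: str | Path,
    channel: Channel,
    acc_counts_per_g: float = ACC_COUNTS_PER_G,
) -> SignalRecording:
    """Read one channel from a session-export CSV.

    For the three-column ACC file the requested axis is selected and raw
    counts are scaled to g units. A rate differing from the channel's
    nominal rate yields a warning, not an error.
    """
    path = Path(path)
    rows = _read_rows(path)
    start_epoch, rate = _parse_header(rows, path)

    expected = EXPECTED_RATE_HZ[channel]
    if rate != expected:
        warnings.warn(
            f"{path}: rate {rate} Hz differs from the nominal "
            f"{expected} Hz for {channel.value}",
            stacklevel=2,
        )

    is_acc = channel.file_stem == "ACC"
    col = {"ACC_X": 0, "ACC_Y": 1, "ACC_Z": 2}.get(channel.value, 0)
    ncols = 3 if is_acc else 1
    values = np.empty(len(rows) - 2)
    for i, row in enumerate(rows[2:], start=3):
        if len(row) < ncols:
            raise FormatError(f"{path}: row {i} has {len(row)} column(s), expected {ncols}")
        try:
            values[i - 3] = float(row[col])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric sample at row {i}: {row[col]!r}") from exc
    if is_acc:
        values /= acc_counts_per_g
    return SignalRecording(channel=channel, start_epoch=start_epoch, rate=rate, samples=values)


def read_acc(
    path: str | Path, acc_counts_per_g: float = ACC_COUNTS_PER_G
) -> tuple[SignalRecording, SignalRecording, SignalRecording]:
    """Read the three accelerometer axes from one ACC file."""
    return tuple(
        read_e4_channel(path, ch, acc_counts_per_g)
        for ch in (Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z)
    )


def read_channel_dir(day_dir: str | Path) -> dict[Channel, SignalRecording]:
    """Read ``ACC.csv``/``TEMP.csv``/``EDA.csv``/``HR.csv`` from a directory."""
    day_dir = Path(day_dir)
    channels: dict[Channel, SignalRecording] = {}
    acc_path = day_dir / "ACC.csv"
    if acc_path.exists():
        x, y, z = read_acc(acc_path)
        channels.update({Channel.ACC_X: x, Channel.ACC_Y: y, Channel.ACC_Z: z})
    for ch in (Channel.TEMP, Channel.EDA, Channel.HR):
        p = day_dir / f"{ch.value}.csv"
        if p.exists():
            channels[ch] = read_e4_channel(p, ch)
    return channels


def _fmt(v: float) -> str:
    return format(v, ".6f").rstrip("0").rstrip(".")


def write_e4_channel(path: str | Path, rec: SignalRecording) -> None:
    """Write a single-column channel file in the session-export dialect."""
    with open(path, "w", newline="") as fh:
        fh.write(f"{_fmt(rec.start_epoch)}\n{_fmt(rec.rate)}\n")
        for v in rec.samples:
            fh.write(f"{_fmt(v)}\n")


def write_acc(
    path: str | Path,
    x: SignalRecording,
    y: SignalRecording,
    z: SignalRecording,
    acc_counts_per_g: float = ACC_COUNTS_PER_G,
) -> None:
    """Write a three-column ACC file; g values are converted back to counts."""
    if not (len(x) == len(y) == len(z)):
        raise ValueError("ACC axes must have equal length")
    counts = np.column_stack([x.samples, y.samples, z.samples]) * acc_counts_per_g
    with open(path, "w", newline="") as fh:
        fh.write(f"{_fmt(x.start_epoch)}\n{_fmt(x.rate)}\n")
        for row in counts:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# EMA log

EMA_COLUMNS = ["participant_id", "notify_epoch", "answer_epoch", "happiness", "activeness"]


def read_ema_log(path: str | Path) -> list[EMAAnswer]:
    """Read an EMA answer log, validating Likert bounds and sorting by time."""
    path = Path(path)
    answers: list[EMAAnswer] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(EMA_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                answers.append(
                    EMAAnswer(
                        participant_id=row["participant_id"],
                        notify_epoch=float(row["notify_epoch"]),
                        answer_epoch=float(row["answer_epoch"]),
                        happiness=int(row["happiness"]),
                        activeness=int(row["activeness"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
    return sorted(answers)


def write_ema_log(path: str | Path, answers: Iterable[EMAAnswer]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EMA_COLUMNS)
        for a in answers:
            writer.writerow(
                [a.participant_id, _fmt(a.notify_epoch), _fmt(a.answer_epoch), a.happiness, a.activeness]
            )


# ---------------------------------------------------------------------------
# day segmentation


def split_into_days(
    channels: Mapping[Channel, Sequence[SignalRecording] | SignalRecording],
    emas: Sequence[EMAAnswer] = (),
    gap_threshold_s: float = 4 * 3600.0,
    participant_id: str = "",
    min_valid_s: float = MIN_VALID_DAY_S,
) -> list[DayRecording]:
    """Group per-channel recording sessions into wear days.

    Sessions whose spans are separated by more than ``gap_threshold_s`` belong
    to different days (the device is taken off overnight). Each EMA answer is
    assigned to the day whose span contains it, or to the nearest day within
    the threshold; farther answers are dropped with a warning. Days with less
    than ``min_valid_s`` of data in any channel are flagged ``valid=False``.
    """
    if gap_threshold_s <= 0:
        raise ValueError("gap_threshold_s must be positive")

    sessions: list[tuple[float, float, Channel, SignalRecording]] = []
    for ch, recs in channels.items():
        if isinstance(recs, SignalRecording):
            recs = [recs]
        for rec in recs:
            sessions.append((rec.start_epoch, rec.end_epoch, ch, rec))
    if not sessions:
        return []
    sessions.sort(key=lambda s: s[0])

    # cluster session spans: a new day starts when the gap to the running
    # span end exceeds the threshold
    clusters: list[list[tuple[float, float, Channel, SignalRecording]]] = [[sessions[0]]]
    span_end = sessions[0][1]
    for sess in sessions[1:]:
        if sess[0] - span_end > gap_threshold_s:
            clusters.append([sess])
        else:
            clusters[-1].append(sess)
        span_end = max(span_end, sess[1])

    days: list[DayRecording] = []
    for day_index, cluster in enumerate(clusters):
        day_channels: dict[Channel, SignalRecording] = {}
        for _, _, ch, rec in cluster:
            if ch in day_channels:
                raise ValueError(
                    f"day {day_index}: two {ch.value} sessions closer than the "
                    "gap threshold; merge or lower gap_threshold_s"
                )
            day_channels[ch] = rec
        valid = all(rec.duration_s >= min_valid_s for rec in day_channels.values())
        days.append(
            DayRecording(
                participant_id=participant_id,
                day_index=day_index,
                channels=day_channels,
                emas=[],
                valid=valid,
            )
        )

    spans = [d.span for d in days]
    for ema in sorted(emas):
        best, best_dist = None, float("inf")
        for d, (s, e) in zip(days, spans):
            dist = 0.0 if s <= ema.answer_epoch < e else min(
                abs(ema.answer_epoch - s), abs(ema.answer_epoch - e)
            )
            if dist < best_dist:
                best, best_dist = d, dist
        if best is not None and best_dist <= gap_threshold_s:
            best.emas.append(ema)
        else:
            logger.warning(
                "EMA at %s is outside every day span (+%.0f s); dropped",
                ema.answer_epoch,
                gap_threshold_s,
            )
    return days
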