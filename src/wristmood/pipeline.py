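"""End-to-end orchestration: wear days in, supervised dataset out.

Ties the stages together per day: condition each channel, slide 60-s
windows over the common time span, extract the 194 features, extrapolate
EMA answers to a per-second label track and attach majority labels to the
windows. A window is emitted only when every modality can fill its
features; windows where more than half of the temperature samples were
flagged implausible are dropped entirely so feature rows stay aligned
across modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as F
from .config import PipelineConfig
from .dataset_model import SupervisedDataset, drop_rare_classes
from .e4_io import Channel, DayRecording, SignalRecording
from .ema_labeling import LabelSeries, attach_labels, expand_labels
from .preprocess import (
    EdaComponents,
    clean_temperature,
    filter_acc,
    normalize_hr_daily,
    process_eda,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessedDay",
    "preprocess_day",
    "day_feature_table",
    "label_feature_table",
    "build_dataset",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ["participant_id", "day_index", "window_start_epoch", "window_end_epoch"]

REQUIRED_CHANNELS = (
    Channel.ACC_X, Channel.ACC_Y, Channel.ACC_Z, Channel.TEMP, Channel.EDA, Channel.HR,
)


@dataclass
class PreprocessedDay:
    """All conditioned signals of one wear day on a shared time span."""

    day: DayRecording
    acc: tuple[SignalRecording, SignalRecording, SignalRecording, SignalRecording]
    temp: SignalRecording
    temp_valid: np.ndarray
    eda: EdaComponents
    hr: SignalRecording

    @property
    def span(self) -> tuple[float, float]:
        starts = [self.acc[0].start_epoch, self.temp.start_epoch,
                  self.eda.start_epoch, self.hr.start_epoch]
        ends = [self.acc[0].end_epoch, self.temp.end_epoch,
                self.eda.start_epoch + len(self.eda) / self.eda.rate, self.hr.end_epoch]
        return max(starts), min(ends)


def preprocess_day(day: DayRecording, cfg: PipelineConfig | None = None) -> PreprocessedDay:
    cfg = cfg or PipelineConfig()
    missing = [c.value for c in REQUIRED_CHANNELS if c not in day.channels]
    if missing:
        raise ValueError(f"day {day.day_index}: missing channel(s) {missing}")
    acc = filter_acc(
        day.channels[Channel.ACC_X],
        day.channels[Channel.ACC_Y],
        day.channels[Channel.ACC_Z],
        cfg.acc_filter,
    )
    temp, temp_valid = clean_temperature(day.channels[Channel.TEMP], cfg.temp_threshold_C)
    eda = process_eda(day.channels[Channel.EDA], cfg.eda_filter)
    hr = normalize_hr_daily(day.channels[Channel.HR], cfg.hr_baseline_min)
    return PreprocessedDay(day=day, acc=acc, temp=temp, temp_valid=temp_valid, eda=eda, hr=hr)


def _segment(samples: np.ndarray, rec_start: float, rate: float, ws: float, we: float) -> np.ndarray:
    i0 = int(round((ws - rec_start) * rate))
    i1 = i0 + int(round((we - ws) * rate))
    i0 = max(i0, 0)
    i1 = min(i1, samples.size)
    return samples[i0:i1], i0, i1


def day_feature_table(
    pre: PreprocessedDay, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Extract every window's 194 features for one preprocessed day."""
    cfg = cfg or PipelineConfig()
    start, end = pre.span
    rows = []
    dropped = 0
    for ws, we in F.windows(start, end, cfg.window):
        fx, _, _ = _segment(pre.acc[0].samples, pre.acc[0].start_epoch, pre.acc[0].rate, ws, we)
        fy, _, _ = _segment(pre.acc[1].samples, pre.acc[1].start_epoch, pre.acc[1].rate, ws, we)
        fz, _, _ = _segment(pre.acc[2].samples, pre.acc[2].start_epoch, pre.acc[2].rate, ws, we)
        fn, _, _ = _segment(pre.acc[3].samples, pre.acc[3].start_epoch, pre.acc[3].rate, ws, we)
        tseg, t0, t1 = _segment(pre.temp.samples, pre.temp.start_epoch, pre.temp.rate, ws, we)
        tmask = pre.temp_valid[t0:t1]
        hseg, _, _ = _segment(pre.hr.samples, pre.hr.start_epoch, pre.hr.rate, ws, we)
        e0 = int(round((ws - pre.eda.start_epoch) * pre.eda.rate))
        e1 = e0 + int(round((we - ws) * pre.eda.rate))

        if tmask.mean() < 0.5:
            dropped += 1  # unusable temperature invalidates the whole window
            continue
        times = np.arange(tseg.size)[tmask] / pre.temp.rate
        try:
            vals = {}
            vals.update(F.acc_features(fx, fy, fz, fn, fs=pre.acc[0].rate))
            vals.update(F.temp_features(tseg[tmask], fs=pre.temp.rate, times_s=times))
            vals.update(F.hr_features(hseg, fs=pre.hr.rate))
            vals.update(
                F.eda_features(
                    eda=pre.eda.eda[e0:e1], scl=pre.eda.scl[e0:e1],
                    scr=pre.eda.scr[e0:e1], fs=pre.eda.rate,
                )
            )
        except ValueError as exc:
            logger.warning("window [%s, %s) skipped: %s", ws, we, exc)
            dropped += 1
            continue
        if not all(np.isfinite(v) for v in vals.values()):
            logger.warning("window [%s, %s) dropped: non-finite feature", ws, we)
            dropped += 1
            continue
        row = {
            "participant_id": pre.day.participant_id,
            "day_index": pre.day.day_index,
            "window_start_epoch": ws,
            "window_end_epoch": we,
        }
        row.update(vals)
        rows.append(row)
    if dropped:
        logger.info("day %d: dropped %d window(s)", pre.day.day_index, dropped)
    columns = METADATA_COLUMNS + F.feature_columns()
    return pd.DataFrame(rows, columns=columns)


def label_feature_table(
    table: pd.DataFrame,
    day: DayRecording,
    ema_window_min: float,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, LabelSeries]:
    """Expand the day's EMA answers and attach majority labels to windows."""
    cfg = cfg or PipelineConfig()
    day_start, day_end = day.span
    series = expand_labels(day.emas, day_start, day_end, ema_window_min)
    labeled = attach_labels(table, series, cfg.label_min_fraction)
    return labeled, series


def build_dataset(
    days: list[DayRecording],
    ema_window_min: float | None = None,
    cfg: PipelineConfig | None = None,
    apply_prevalence_filter: bool = True,
) -> SupervisedDataset:
    """Full pipeline over valid days, ending in a prevalence-filtered dataset."""
    cfg = cfg or PipelineConfig()
    width = ema_window_min if ema_window_min is not None else cfg.ema_window_min
    tables = []
    participant = days[0].participant_id if days else ""
    for day in days:
        if not day.valid:
            logger.info("day %d flagged non-valid; skipped", day.day_index)
            continue
        pre = preprocess_day(day, cfg)
        table = day_feature_table(pre, cfg)
        labeled, _ = label_feature_table(table, day, width, cfg)
        if len(labeled):
            tables.append(labeled)
    if not tables:
        raise ValueError("no labeled windows in any valid day")
    full = pd.concat(tables, ignore_index=True)
    ds = SupervisedDataset.from_table(full, participant_id=participant)
    if apply_prevalence_filter:
        ds = drop_rare_classes(ds, cfg.min_class_fraction)
    return ds
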