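"""Per-signal conditioning chains.

Each wristband channel gets its own chain before feature extraction:

* ACC — Euclidean norm of the raw axes, then all four series band-pass
  filtered (0.2–10 Hz, 3rd-order Butterworth, zero phase).
* TEMP — a 2 °C jump rule flags implausible samples (sensor losing skin
  contact) instead of filtering.
* EDA — 1.5 Hz low-pass, then decomposition into a slow tonic level (SCL)
  and a fast phasic residual (SCR) with ``eda = scl + scr`` holding exactly.
* HR — z-scored against the first ten minutes of each wear day so levels are
  comparable across days and participants.

All filters are applied forward-backward (zero phase): the analysis is
offline, and phase distortion would shift features relative to the EMA
labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .e4_io import SignalRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "EdaComponents",
    "ACC_BANDPASS",
    "EDA_LOWPASS",
    "SCL_LOWPASS",
    "apply_filter",
    "filter_acc",
    "clean_temperature",
    "process_eda",
    "normalize_hr_daily",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter description.

    ``low_hz`` is ignored for ``kind="lowpass"`` (the passband starts at DC);
    ``high_hz`` is the upper corner in both kinds.
    """

    kind: str  # "bandpass" | "lowpass"
    order: int = 3
    low_hz: float = 0.0
    high_hz: float = 0.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "bandpass" and not 0 <= self.low_hz < self.high_hz:
            raise ValueError("bandpass needs 0 <= low_hz < high_hz")
        if self.high_hz <= 0:
            raise ValueError("high_hz must be positive")

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if self.high_hz >= nyq:
            raise ValueError(f"high_hz {self.high_hz} >= Nyquist {nyq} at fs={fs}")
        if self.kind == "bandpass":
            return signal.butter(
                self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
            )
        return signal.butter(self.order, self.high_hz, btype="lowpass", fs=fs, output="sos")


#: ACC conditioning: 0.2–10 Hz band-pass, 3rd order
ACC_BANDPASS = FilterSpec("bandpass", order=3, low_hz=0.2, high_hz=10.0)
#: EDA conditioning: 1.5 Hz low-pass, 3rd order
EDA_LOWPASS = FilterSpec("lowpass", order=3, high_hz=1.5)
#: tonic-level extraction: very slow low-pass applied to a moving median
SCL_LOWPASS = FilterSpec("lowpass", order=3, high_hz=0.05)

#: moving-median length used before the tonic low-pass (seconds); must be
#: several times the ~4 s phasic decay or the tonic estimate chases bumps
SCL_MEDIAN_S = 32.0


def apply_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply a FilterSpec; forward-backward when ``zero_phase``."""
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    if not spec.zero_phase:
        return signal.sosfilt(sos, x)
    padlen = 3 * (2 * len(sos) + 1)
    if x.size <= max(padlen, 3 * spec.order):
        raise ValueError(
            f"segment of {x.size} samples too short for order-{spec.order} "
            f"zero-phase filtering (need > {padlen})"
        )
    return signal.sosfiltfilt(sos, x)


def filter_acc(
    x: SignalRecording,
    y: SignalRecording,
    z: SignalRecording,
    spec: FilterSpec = ACC_BANDPASS,
) -> tuple[SignalRecording, SignalRecording, SignalRecording, SignalRecording]:
    """Band-pass the three axes plus the Euclidean norm of the raw vector.

    The norm is computed on the raw samples first, then all four series are
    filtered, so the norm keeps the gravity-modulated magnitude before DC is
    removed by the passband.
    """
    if not (len(x) == len(y) == len(z)):
        raise ValueError("ACC axes must have equal length")
    if not (x.rate == y.rate == z.rate):
        raise ValueError("ACC axes must share a sample rate")
    norm = np.sqrt(x.samples**2 + y.samples**2 + z.samples**2)
    out = []
    for rec, samples in ((x, x.samples), (y, y.samples), (z, z.samples), (x, norm)):
        filtered = apply_filter(samples, spec, rec.rate)
        out.append(
            SignalRecording(
                channel=rec.channel, start_epoch=rec.start_epoch, rate=rec.rate, samples=filtered
            )
        )
    return tuple(out)


def clean_temperature(
    t: SignalRecording, threshold_C: float = 2.0
) -> tuple[SignalRecording, np.ndarray]:
    """Flag implausible skin-temperature samples.

    A sample is invalid when it differs from the *last valid* sample by
    strictly more than ``threshold_C`` — skin temperature cannot jump that
    fast, so such steps indicate the sensor leaving the skin. The first
    sample is taken as valid by convention. Returns the recording unchanged
    plus a boolean validity mask; downstream windows exclude invalid samples.
    """
    samples = t.samples
    mask = np.ones(samples.size, dtype=bool)
    if samples.size == 0:
        return t, mask
    last_valid = samples[0]
    for k in range(1, samples.size):
        if abs(samples[k] - last_valid) > threshold_C:
            mask[k] = False
        else:
            last_valid = samples[k]
    if not mask.any():
        warnings.warn("all temperature samples invalid; downstream windows will be skipped")
    return t, mask


@dataclass(frozen=True)
class EdaComponents:
    """Filtered electrodermal activity and its tonic/phasic split.

    ``eda == scl + scr`` at every sample by construction: the phasic skin
    conductance response (SCR) is defined as the residual of the filtered
    signal over the tonic skin conductance level (SCL).
    """

    start_epoch: float
    rate: float
    eda: np.ndarray
    scl: np.ndarray
    scr: np.ndarray

    def __post_init__(self) -> None:
        if not (self.eda.size == self.scl.size == self.scr.size):
            raise ValueError("components must share a length")

    def __len__(self) -> int:
        return self.eda.size


def process_eda(
    e: SignalRecording,
    lowpass: FilterSpec = EDA_LOWPASS,
    scl_lowpass: FilterSpec = SCL_LOWPASS,
    scl_median_s: float = SCL_MEDIAN_S,
) -> EdaComponents:
    """Filter EDA and split it into tonic (SCL) and phasic (SCR) components.

    SCL is a 32-s moving median of the filtered signal, smoothed by a
    0.05 Hz low-pass; the median suppresses the fast SCR bumps before the
    smoother so the tonic estimate does not chase them (a bump elevated for
    ~10 s must occupy less than half the median window to be rejected).
    SCR is the exact residual, so the additive decomposition holds sample
    for sample.
    """
    raw = e.samples
    if np.any(raw < 0):
        warnings.warn("negative skin conductance clipped to 0 µS (device floor)")
        raw = np.clip(raw, 0.0, None)
    eda = apply_filter(raw, lowpass, e.rate)
    k = int(round(scl_median_s * e.rate))
    k += 1 - k % 2  # odd kernel for a centered median
    med = ndimage.median_filter(eda, size=k, mode="nearest")
    scl = apply_filter(med, scl_lowpass, e.rate)
    scr = eda - scl
    return EdaComponents(start_epoch=e.start_epoch, rate=e.rate, eda=eda, scl=scl, scr=scr)


def normalize_hr_daily(
    hr: SignalRecording, baseline_min: float = 10.0
) -> SignalRecording:
    """Z-score a day's heart-rate series against its first minutes.

    The baseline is the first ``baseline_min`` minutes of the wear day; the
    whole day is mapped to ``(hr - mean(baseline)) / std(baseline)``. A
    zero-spread baseline falls back to a unit divisor; a day shorter than the
    baseline uses the whole day (with a warning).
    """
    n_base = int(round(baseline_min * 60.0 * hr.rate))
    if hr.samples.size == 0:
        raise ValueError("empty heart-rate recording")
    if hr.samples.size < n_base:
        warnings.warn(
            f"day shorter than the {baseline_min:g}-min baseline; using the whole day"
        )
        n_base = hr.samples.size
    base = hr.samples[:n_base]
    mu = float(np.mean(base))
    sd = float(np.std(base))
    if sd == 0.0:
        sd = 1.0
    return SignalRecording(
        channel=hr.channel,
        start_epoch=hr.start_epoch,
        rate=hr.rate,
        samples=(hr.samples - mu) / sd,
    )
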