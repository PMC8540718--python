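"""Sliding-window feature extraction.

Features are computed over 60-s windows advancing with 10 % overlap and are
grouped by modality: 72 accelerometer, 13 skin-temperature, 27 heart-rate and
82 electrodermal features — 194 per window. Feature names follow the field's
customary symbols (MAX, P90, MAVFD, aLF, LFHF, ALSC, …); the full ordered
column list is available from :func:`feature_columns`.

Spectral descriptors come from a Welch power spectral density of the
mean-removed segment (Hann window, sub-segments capped at 256 samples with
50 % overlap; short segments use a single full-length segment). ``FPq`` is
the spectral-edge frequency: the lowest frequency below which q % of the
total power lies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EdaComponents

__all__ = [
    "WindowSpec",
    "windows",
    "welch_psd",
    "time_stats",
    "spectral_stats",
    "band_power",
    "band_peak",
    "acc_features",
    "temp_features",
    "hr_features",
    "eda_features",
    "feature_columns",
    "MODALITY_COUNTS",
    "ACC_AXES",
    "EDA_COMPONENTS",
    "HRV_BANDS",
]

MODALITY_COUNTS = {"acc": 72, "temp": 13, "hr": 27, "eda": 82}
ACC_AXES = ("x", "y", "z", "n")
EDA_COMPONENTS = ("eda", "scl", "scr")

#: conventional heart-rate-variability bands, Hz (half-open [lo, hi))
HRV_BANDS = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

#: electrodermal band powers, Hz
EDA_BANDS = {"F1SC": (0.1, 0.2), "F2SC": (0.2, 0.3), "F3SC": (0.3, 0.4)}

#: Welch segment cap, samples
WELCH_NPERSEG_CAP = 256


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 60-s windows, 10 % overlap by default."""

    length_s: float = 60.0
    overlap_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.length_s * (1.0 - self.overlap_frac)


def windows(start: float, end: float, spec: WindowSpec = WindowSpec()) -> list[tuple[float, float]]:
    """Half-open window intervals fully inside ``[start, end)``."""
    out: list[tuple[float, float]] = []
    k = 0
    while True:
        ws = start + k * spec.step_s
        we = ws + spec.length_s
        if we > end + 1e-9:
            break
        out.append((ws, we))
        k += 1
    return out


# ---------------------------------------------------------------------------
# shared primitives


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def welch_psd(x: np.ndarray, fs: float, nperseg_cap: int = WELCH_NPERSEG_CAP):
    """One-sided Welch PSD (Hann, 50 % overlap) of the mean-removed segment.

    The segment mean is subtracted once up front (so a constant input has an
    all-zero spectrum and band powers are not polluted by DC leakage);
    segments longer than the cap are averaged over capped sub-segments,
    shorter inputs use a single segment, i.e. a windowed periodogram.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean() if x.size else x
    nperseg = min(x.size, nperseg_cap)
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg, detrend=False)


def spectral_edge(f: np.ndarray, p: np.ndarray, q: float) -> float:
    """Lowest frequency below which ``q`` % of total power lies; 0 if no power."""
    total = p.sum()
    if total <= 0:
        return 0.0
    c = np.cumsum(p)
    idx = int(np.searchsorted(c, q / 100.0 * total))
    idx = min(idx, f.size - 1)
    return float(f[idx])


def band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Integrated power in ``[lo, hi)`` (bin power × bin width)."""
    if f.size < 2:
        return 0.0
    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    return float(p[mask].sum() * df)


def band_peak(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Frequency of the PSD maximum inside ``[lo, hi)``; ``lo`` if empty."""
    mask = (f >= lo) & (f < hi)
    if not mask.any():
        return float(lo)
    sub_f, sub_p = f[mask], p[mask]
    return float(sub_f[int(np.argmax(sub_p))])


def _first_diff_stats(x: np.ndarray) -> dict[str, float]:
    """MAVFD family: mean absolute first/second differences, raw and z-scored."""
    z = _zscore(x)
    d1, d2 = np.diff(x), np.diff(x, n=2)
    zd1, zd2 = np.diff(z), np.diff(z, n=2)
    return {
        "MAVFD": float(np.mean(np.abs(d1))) if d1.size else 0.0,
        "MAVFDN": float(np.mean(np.abs(zd1))) if zd1.size else 0.0,
        "MAVSD": float(np.mean(np.abs(d2))) if d2.size else 0.0,
        "MAVSDN": float(np.mean(np.abs(zd2))) if zd2.size else 0.0,
    }


def time_stats(x: np.ndarray) -> dict[str, float]:
    """The 13 generic time-domain measures of a segment.

    MAX and P90 are taken on the rectified segment; MIN on the raw one.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    ax = np.abs(x)
    mean = float(np.mean(x))
    out = {
        "MAX": float(np.max(ax)),
        "P90": float(np.percentile(ax, 90)),
        "VAR": float(np.var(x)),
        "MAD": float(np.mean(np.abs(x - mean))),
        "Norm": float(np.sqrt(np.sum(x**2))),
        "AMP": float(np.max(x) - mean),
        "MIN": float(np.min(x)),
        "STD": float(np.std(x)),
        "RMS": float(np.sqrt(np.mean(x**2))),
    }
    out.update(_first_diff_stats(x))
    return out


def spectral_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    """FM/FSTD (mean and spread of PSD amplitudes) and FP25/50/75 edges."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("segment must have at least 16 samples for spectral stats")
    f, p = welch_psd(x, fs)
    return {
        "FM": float(np.mean(p)),
        "FSTD": float(np.std(p)),
        "FP25": spectral_edge(f, p, 25),
        "FP50": spectral_edge(f, p, 50),
        "FP75": spectral_edge(f, p, 75),
    }


# ---------------------------------------------------------------------------
# modality feature sets

_ACC_MEASURES = [
    "MAX", "P90", "VAR", "MAD", "Norm", "AMP", "MIN", "STD", "RMS",
    "MAVFD", "MAVFDN", "MAVSD", "MAVSDN",
    "FM", "FSTD", "FP25", "FP50", "FP75",
]


def acc_features(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, norm: np.ndarray, fs: float = 32.0
) -> dict[str, float]:
    """72 accelerometer features: 18 measures × 4 series (x, y, z, norm)."""
    out: dict[str, float] = {}
    for axis, seg in zip(ACC_AXES, (x, y, z, norm)):
        vals = {**time_stats(seg), **spectral_stats(seg, fs)}
        for m in _ACC_MEASURES:
            out[f"acc_{m}_{axis}"] = vals[m]
    return out


def temp_features(
    seg: np.ndarray, fs: float = 4.0, times_s: np.ndarray | None = None
) -> dict[str, float]:
    """13 skin-temperature features.

    ``times_s`` are sample times relative to the window start (needed when
    invalid samples were removed and the remaining ones are not contiguous);
    SRL/IRL are the least-squares line slope (°C/s) and intercept on them.
    """
    seg = np.asarray(seg, dtype=float)
    if seg.size < 3:
        raise ValueError("temperature segment must have at least 3 samples")
    if times_s is None:
        times_s = np.arange(seg.size) / fs
    slope, intercept = np.polyfit(times_s, seg, 1)
    out = {
        "temp_MT": float(np.mean(seg)),
        "temp_SRL": float(slope),
        "temp_IRL": float(intercept),
        "temp_STD": float(np.std(seg)),
    }
    out.update({f"temp_{k}": v for k, v in _first_diff_stats(seg).items()})
    out.update({f"temp_{k}": v for k, v in spectral_stats(seg, fs).items()})
    return out


def _smooth_mean(x: np.ndarray, k: int) -> float:
    """Mean of a centered k-sample moving average (edges use partial windows)."""
    s = pd.Series(x).rolling(k, center=True, min_periods=1).mean()
    return float(s.mean())


def hr_features(seg: np.ndarray, fs: float = 1.0) -> dict[str, float]:
    """27 heart-rate features from the daily-normalized 1 Hz series.

    14 time-domain measures plus 13 band descriptors of the heart-rate
    variability spectrum over the conventional VLF/LF/HF bands. With 60-s
    windows the VLF band sits at the resolution limit and its power can be
    0; absent high-frequency power makes LFHF 0 by convention.
    """
    seg = np.asarray(seg, dtype=float)
    if seg.size < 16:
        raise ValueError("heart-rate segment must have at least 16 samples")
    ax = np.abs(seg)
    mean = float(np.mean(seg))
    out = {
        "hr_MAXHR": float(np.max(ax)),
        "hr_P90HR": float(np.percentile(ax, 90)),
        "hr_VARHR": float(np.var(seg)),
        "hr_MADHR": float(np.mean(np.abs(seg - mean))),
        "hr_normHR": float(np.sqrt(np.sum(seg**2))),
        "hr_Mean": mean,
        "hr_MIN": float(np.min(seg)),
        "hr_STD": float(np.std(seg)),
    }
    out.update({f"hr_{k}": v for k, v in _first_diff_stats(seg).items()})
    out["hr_SM"] = _smooth_mean(seg, int(round(5 * fs)))
    out["hr_MFD"] = float(np.mean(np.diff(seg)))

    f, p = welch_psd(seg, fs)
    powers = {name: band_power(f, p, lo, hi) for name, (lo, hi) in HRV_BANDS.items()}
    total = sum(powers.values())
    lf, hf = powers["LF"], powers["HF"]
    out.update(
        {
            "hr_aVLF": powers["VLF"],
            "hr_aLF": lf,
            "hr_aHF": hf,
            "hr_aTotal": total,
            "hr_pVLF": 100.0 * powers["VLF"] / total if total > 0 else 0.0,
            "hr_pLF": 100.0 * lf / total if total > 0 else 0.0,
            "hr_pHF": 100.0 * hf / total if total > 0 else 0.0,
            "hr_nLF": lf / (lf + hf) if lf + hf > 0 else 0.0,
            "hr_nHF": hf / (lf + hf) if lf + hf > 0 else 0.0,
            "hr_LFHF": lf / hf if hf > 0 else 0.0,
            "hr_peakVLF": band_peak(f, p, *HRV_BANDS["VLF"]),
            "hr_peakLF": band_peak(f, p, *HRV_BANDS["LF"]),
            "hr_peakHF": band_peak(f, p, *HRV_BANDS["HF"]),
        }
    )
    return out


_EDA_TIME_MEASURES = [
    "MSC", "SDSC", "MASC", "MISC", "DRSC", "FMSC", "FDSC", "SMSC", "SDSC2",
    "ALSC", "INSC", "APSC", "RMSC", "ILSC", "ELSC", "SKSC", "KUSC", "MOSC",
]
_EDA_FREQ_MEASURES = ["F1SC", "F2SC", "F3SC", "FMSCR", "FSTDSCR", "FP25", "FP50", "FP75"]


def _eda_component_time(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    d1, d2 = np.diff(x), np.diff(x, n=2)
    alsc = float(np.sum(np.sqrt(1.0 + d1**2)))
    sum_sq = float(np.sum(x**2))
    apsc = sum_sq / x.size
    mean = float(np.mean(x))
    sd = float(np.std(x))
    if sd > 0:
        z = (x - mean) / sd
        sksc = float(np.mean(z**3))
        kusc = float(np.mean(z**4))  # Pearson kurtosis (normal -> 3)
    else:
        sksc = kusc = 0.0
    return {
        "MSC": mean,
        "SDSC": sd,
        "MASC": float(np.max(x)),
        "MISC": float(np.min(x)),
        "DRSC": float(np.max(x) - np.min(x)),
        "FMSC": float(np.mean(d1)) if d1.size else 0.0,
        "FDSC": float(np.std(d1)) if d1.size else 0.0,
        "SMSC": float(np.mean(d2)) if d2.size else 0.0,
        "SDSC2": float(np.std(d2)) if d2.size else 0.0,
        "ALSC": alsc,
        "INSC": float(np.sum(np.abs(x))),
        "APSC": apsc,
        "RMSC": float(np.sqrt(apsc)),
        "ILSC": float(np.sum(np.abs(x)) / alsc) if alsc > 0 else 0.0,
        "ELSC": sum_sq / alsc if alsc > 0 else 0.0,
        "SKSC": sksc,
        "KUSC": kusc,
        "MOSC": float(np.mean((x - mean) ** 5)),
    }


def _eda_component_freq(x: np.ndarray, fs: float) -> dict[str, float]:
    f, p = welch_psd(x, fs)
    out = {name: band_power(f, p, lo, hi) for name, (lo, hi) in EDA_BANDS.items()}
    out["FMSCR"] = float(np.mean(p))
    out["FSTDSCR"] = float(np.std(p))
    out["FP25"] = spectral_edge(f, p, 25)
    out["FP50"] = spectral_edge(f, p, 50)
    out["FP75"] = spectral_edge(f, p, 75)
    return out


def eda_features(components: EdaComponents | None = None, *, eda=None, scl=None, scr=None,
                 fs: float = 4.0) -> dict[str, float]:
    """82 electrodermal features over the filtered signal and its split.

    18 time measures and 8 spectral measures per component (filtered EDA,
    tonic SCL, phasic SCR) plus the MAVFD difference family on the filtered
    signal only: 3 × 26 + 4 = 82.
    """
    if components is not None:
        eda, scl, scr = components.eda, components.scl, components.scr
        fs = components.rate
    segs = {"eda": np.asarray(eda, float), "scl": np.asarray(scl, float),
            "scr": np.asarray(scr, float)}
    out: dict[str, float] = {}
    for comp, seg in segs.items():
        if seg.size < 16:
            raise ValueError("EDA component segment must have at least 16 samples")
        tvals = _eda_component_time(seg)
        for m in _EDA_TIME_MEASURES:
            out[f"eda_{m}_{comp}"] = tvals[m]
    for k, v in _first_diff_stats(segs["eda"]).items():
        out[f"eda_{k}_eda"] = v
    for comp, seg in segs.items():
        fvals = _eda_component_freq(seg, fs)
        for m in _EDA_FREQ_MEASURES:
            out[f"eda_{m}_{comp}"] = fvals[m]
    return out


def feature_columns() -> list[str]:
    """The stable 194-column order: ACC, TEMP, HR, then EDA blocks."""
    cols: list[str] = []
    for axis in ACC_AXES:
        cols += [f"acc_{m}_{axis}" for m in _ACC_MEASURES]
    cols += ["temp_MT", "temp_SRL", "temp_IRL", "temp_STD",
             "temp_MAVFD", "temp_MAVFDN", "temp_MAVSD", "temp_MAVSDN",
             "temp_FM", "temp_FSTD", "temp_FP25", "temp_FP50", "temp_FP75"]
    cols += ["hr_MAXHR", "hr_P90HR", "hr_VARHR", "hr_MADHR", "hr_normHR",
             "hr_Mean", "hr_MIN", "hr_STD",
             "hr_MAVFD", "hr_MAVFDN", "hr_MAVSD", "hr_MAVSDN", "hr_SM", "hr_MFD",
             "hr_aVLF", "hr_aLF", "hr_aHF", "hr_aTotal",
             "hr_pVLF", "hr_pLF", "hr_pHF", "hr_nLF", "hr_nHF", "hr_LFHF",
             "hr_peakVLF", "hr_peakLF", "hr_peakHF"]
    for comp in EDA_COMPONENTS:
        cols += [f"eda_{m}_{comp}" for m in _EDA_TIME_MEASURES]
    cols += ["eda_MAVFD_eda", "eda_MAVFDN_eda", "eda_MAVSD_eda", "eda_MAVSDN_eda"]
    for comp in EDA_COMPONENTS:
        cols += [f"eda_{m}_{comp}" for m in _EDA_FREQ_MEASURES]
    assert len(cols) == sum(MODALITY_COUNTS.values())
    return cols
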