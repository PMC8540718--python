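"""Naive, loop-level recomputations of every windowed feature.

These deliberately avoid the library code paths used by the package
(`scipy.signal.welch`, vectorized stats): spectra are built segment by
segment from an explicit Hann window and an FFT, percentiles are
interpolated by hand from a sorted copy, and every statistic is written out
directly from its definition. They exist so the 194 features can be checked
against an independent derivation.
"""

from __future__ import annotations

import math

import numpy as np

HRV_BANDS = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}
EDA_BANDS = {"F1SC": (0.1, 0.2), "F2SC": (0.2, 0.3), "F3SC": (0.3, 0.4)}


def naive_percentile(x, q):
    """Linear-interpolation percentile from a sorted copy."""
    s = sorted(float(v) for v in x)
    h = (len(s) - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_welch(x, fs, cap=256):
    """Hann-windowed averaged periodogram of the mean-removed segment."""
    x = [float(v) for v in x]
    m = sum(x) / len(x)
    x = [v - m for v in x]
    n = len(x)
    nperseg = min(n, cap)
    step = nperseg - nperseg // 2
    w = [0.5 - 0.5 * math.cos(2 * math.pi * k / nperseg) for k in range(nperseg)]
    wsum2 = sum(v * v for v in w)
    psds = []
    start = 0
    while start + nperseg <= n:
        seg = [x[start + k] * w[k] for k in range(nperseg)]
        spec = np.fft.rfft(seg)
        p = (np.abs(spec) ** 2) / (fs * wsum2)
        p = p.copy()
        # one-sided doubling, except DC and (for even nperseg) Nyquist
        for k in range(1, p.size - (1 if nperseg % 2 == 0 else 0)):
            p[k] *= 2.0
        psds.append(p)
        start += step
    psd = np.mean(psds, axis=0)
    freqs = np.array([k * fs / nperseg for k in range(psd.size)])
    return freqs, psd


def naive_edge(f, p, q):
    total = float(sum(p))
    if total <= 0:
        return 0.0
    target = q / 100.0 * total
    c = 0.0
    for k in range(len(p)):
        c += p[k]
        if c >= target - 1e-12 * total:
            return float(f[k])
    return float(f[-1])


def naive_band_power(f, p, lo, hi):
    if len(f) < 2:
        return 0.0
    df = f[1] - f[0]
    return float(sum(pk for fk, pk in zip(f, p) if lo <= fk < hi) * df)


def naive_band_peak(f, p, lo, hi):
    best_f, best_p = None, -1.0
    for fk, pk in zip(f, p):
        if lo <= fk < hi and pk > best_p:
            best_f, best_p = float(fk), float(pk)
    return lo if best_f is None else best_f


def _mean(x):
    return sum(x) / len(x)


def _std(x):
    m = _mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def _diffs(x, order=1):
    for _ in range(order):
        x = [b - a for a, b in zip(x[:-1], x[1:])]
    return x


def _mavfd_family(x):
    sd = _std(x)
    m = _mean(x)
    z = [(v - m) / sd for v in x] if sd > 0 else [0.0] * len(x)
    d1, d2 = _diffs(x), _diffs(x, 2)
    zd1, zd2 = _diffs(z), _diffs(z, 2)
    mav = lambda d: _mean([abs(v) for v in d]) if d else 0.0
    return {"MAVFD": mav(d1), "MAVFDN": mav(zd1), "MAVSD": mav(d2), "MAVSDN": mav(zd2)}


def naive_time_stats(x):
    x = [float(v) for v in x]
    ax = [abs(v) for v in x]
    m = _mean(x)
    out = {
        "MAX": max(ax),
        "P90": naive_percentile(ax, 90),
        "VAR": _std(x) ** 2,
        "MAD": _mean([abs(v - m) for v in x]),
        "Norm": math.sqrt(sum(v * v for v in x)),
        "AMP": max(x) - m,
        "MIN": min(x),
        "STD": _std(x),
        "RMS": math.sqrt(_mean([v * v for v in x])),
    }
    out.update(_mavfd_family(x))
    return out


def naive_spectral_stats(x, fs):
    f, p = naive_welch(x, fs)
    return {
        "FM": _mean(list(p)),
        "FSTD": _std(list(p)),
        "FP25": naive_edge(f, p, 25),
        "FP50": naive_edge(f, p, 50),
        "FP75": naive_edge(f, p, 75),
    }


def naive_acc_features(x, y, z, norm, fs=32.0):
    out = {}
    for axis, seg in zip(("x", "y", "z", "n"), (x, y, z, norm)):
        vals = {**naive_time_stats(seg), **naive_spectral_stats(seg, fs)}
        for k, v in vals.items():
            out[f"acc_{k}_{axis}"] = v
    return out


def naive_temp_features(seg, fs=4.0, times_s=None):
    seg = [float(v) for v in seg]
    n = len(seg)
    t = list(times_s) if times_s is not None else [k / fs for k in range(n)]
    # closed-form least squares line
    tm, ym = _mean(t), _mean(seg)
    sxx = sum((v - tm) ** 2 for v in t)
    sxy = sum((a - tm) * (b - ym) for a, b in zip(t, seg))
    slope = sxy / sxx if sxx > 0 else 0.0
    out = {
        "temp_MT": ym,
        "temp_SRL": slope,
        "temp_IRL": ym - slope * tm,
        "temp_STD": _std(seg),
    }
    out.update({f"temp_{k}": v for k, v in _mavfd_family(seg).items()})
    out.update({f"temp_{k}": v for k, v in naive_spectral_stats(seg, fs).items()})
    return out


def naive_hr_features(seg, fs=1.0):
    seg = [float(v) for v in seg]
    ax = [abs(v) for v in seg]
    m = _mean(seg)
    out = {
        "hr_MAXHR": max(ax),
        "hr_P90HR": naive_percentile(ax, 90),
        "hr_VARHR": _std(seg) ** 2,
        "hr_MADHR": _mean([abs(v - m) for v in seg]),
        "hr_normHR": math.sqrt(sum(v * v for v in seg)),
        "hr_Mean": m,
        "hr_MIN": min(seg),
        "hr_STD": _std(seg),
    }
    out.update({f"hr_{k}": v for k, v in _mavfd_family(seg).items()})
    # centered 5-sample moving average with shrinking edge windows
    k = int(round(5 * fs))
    half_lo, half_hi = (k - 1) // 2, k // 2
    sm = []
    for i in range(len(seg)):
        lo, hi = max(0, i - half_lo), min(len(seg), i + half_hi + 1)
        sm.append(_mean(seg[lo:hi]))
    out["hr_SM"] = _mean(sm)
    d1 = _diffs(seg)
    out["hr_MFD"] = _mean(d1) if d1 else 0.0

    f, p = naive_welch(seg, fs)
    powers = {k: naive_band_power(f, p, lo, hi) for k, (lo, hi) in HRV_BANDS.items()}
    total = sum(powers.values())
    lf, hf = powers["LF"], powers["HF"]
    out.update(
        {
            "hr_aVLF": powers["VLF"],
            "hr_aLF": lf,
            "hr_aHF": hf,
            "hr_aTotal": total,
            "hr_pVLF": 100 * powers["VLF"] / total if total > 0 else 0.0,
            "hr_pLF": 100 * lf / total if total > 0 else 0.0,
            "hr_pHF": 100 * hf / total if total > 0 else 0.0,
            "hr_nLF": lf / (lf + hf) if lf + hf > 0 else 0.0,
            "hr_nHF": hf / (lf + hf) if lf + hf > 0 else 0.0,
            "hr_LFHF": lf / hf if hf > 0 else 0.0,
            "hr_peakVLF": naive_band_peak(f, p, *HRV_BANDS["VLF"]),
            "hr_peakLF": naive_band_peak(f, p, *HRV_BANDS["LF"]),
            "hr_peakHF": naive_band_peak(f, p, *HRV_BANDS["HF"]),
        }
    )
    return out


def _naive_eda_time(x):
    x = [float(v) for v in x]
    n = len(x)
    d1, d2 = _diffs(x), _diffs(x, 2)
    alsc = sum(math.sqrt(1 + v * v) for v in d1)
    insc = sum(abs(v) for v in x)
    sumsq = sum(v * v for v in x)
    m, sd = _mean(x), _std(x)
    if sd > 0:
        z = [(v - m) / sd for v in x]
        sksc = _mean([v**3 for v in z])
        kusc = _mean([v**4 for v in z])
    else:
        sksc = kusc = 0.0
    return {
        "MSC": m,
        "SDSC": sd,
        "MASC": max(x),
        "MISC": min(x),
        "DRSC": max(x) - min(x),
        "FMSC": _mean(d1) if d1 else 0.0,
        "FDSC": _std(d1) if d1 else 0.0,
        "SMSC": _mean(d2) if d2 else 0.0,
        "SDSC2": _std(d2) if d2 else 0.0,
        "ALSC": alsc,
        "INSC": insc,
        "APSC": sumsq / n,
        "RMSC": math.sqrt(sumsq / n),
        "ILSC": insc / alsc if alsc > 0 else 0.0,
        "ELSC": sumsq / alsc if alsc > 0 else 0.0,
        "SKSC": sksc,
        "KUSC": kusc,
        "MOSC": _mean([(v - m) ** 5 for v in x]),
    }


def naive_eda_features(eda, scl, scr, fs=4.0):
    out = {}
    segs = {"eda": eda, "scl": scl, "scr": scr}
    for comp, seg in segs.items():
        for k, v in _naive_eda_time(seg).items():
            out[f"eda_{k}_{comp}"] = v
    for k, v in _mavfd_family([float(v) for v in eda]).items():
        out[f"eda_{k}_eda"] = v
    for comp, seg in segs.items():
        f, p = naive_welch(seg, fs)
        vals = {k: naive_band_power(f, p, lo, hi) for k, (lo, hi) in EDA_BANDS.items()}
        vals["FMSCR"] = _mean(list(p))
        vals["FSTDSCR"] = _std(list(p))
        vals["FP25"] = naive_edge(f, p, 25)
        vals["FP50"] = naive_edge(f, p, 50)
        vals["FP75"] = naive_edge(f, p, 75)
        for k, v in vals.items():
            out[f"eda_{k}_{comp}"] = v
    return out
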