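"""Synthetic multi-day wristband recordings with known mood structure.

The generator emulates the shape of a free-living wearable mood study: a
participant wears the device roughly 9–15 days, about 12 h per day, and
answers around five two-item mood prompts a day whose notification times
jitter by ±10 min. A latent (valence, arousal) state steps through the day;
physiology couples to it through tunable effect sizes:

* heart rate — baseline 70 bpm plus ``hr_bpm_per_arousal`` per arousal unit,
  with AR(1) noise at 1 Hz;
* electrodermal activity — a slow tonic drift plus Poisson-timed phasic
  bumps (instant rise, ~4 s exponential decay) whose rate grows with
  arousal, at 4 Hz;
* skin temperature — 33 °C plus ``temp_C_per_valence`` per valence unit,
  drift, and occasional single-sample spike artifacts exceeding the 2 °C
  plausibility rule, at 4 Hz;
* accelerometer — gravity on z plus activity bursts whose rate grows with
  arousal, at 32 Hz in integer counts.

EMA answers are the latent state quantized to the 0–4 Likert grid at the
answer time, so labels are consistent with the ground truth by
construction. Setting every effect size to 0 yields a null generator whose
classes are physiologically indistinguishable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .e4_io import (
    ACC_COUNTS_PER_G,
    Channel,
    DayRecording,
    EMAAnswer,
    SignalRecording,
    read_channel_dir,
    read_ema_log,
    write_acc,
    write_e4_channel,
    write_ema_log,
)
from .ema_labeling import mood_from_answer

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedParticipant",
    "STUDY_PARTICIPANTS",
    "mean_daily_emas",
    "simulate_participant",
    "write_participant",
    "load_participant",
    "make_fixture",
    "FIXTURE_NAMES",
]


#: cohort shape of the emulated study: wear days, excluded days and total
#: answered prompts per participant (used for defaults and worked examples)
STUDY_PARTICIPANTS = {
    "P1": {"days": 9, "non_valid_days": 0, "total_emas": 42},
    "P2": {"days": 15, "non_valid_days": 0, "total_emas": 57},
    "P3": {"days": 14, "non_valid_days": 2, "total_emas": 64},
    "P4": {"days": 14, "non_valid_days": 1, "total_emas": 46},
}


def mean_daily_emas(participant: str) -> float:
    """Mean answered prompts per *valid* wear day for one cohort participant."""
    info = STUDY_PARTICIPANTS[participant]
    return info["total_emas"] / (info["days"] - info["non_valid_days"])


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the emulated study design."""

    participant_id: str = "P1"
    n_days: int = 14
    day_hours: float = 12.0
    day_start_hour: float = 8.0
    start_epoch: float = 1_600_000_000.0

    emas_per_day: int = 5
    notify_jitter_min: float = 10.0
    ema_slots_min: tuple[float, ...] | None = None  # explicit slots override
    reaction_mean_s: float = 30.0

    #: the latent states visited, as (happiness, activeness) Likert pairs
    mood_states: tuple[tuple[int, int], ...] = ((4, 2), (4, 4), (2, 0))
    mood_process: str = "ema_locked"  # or "markov"
    switch_rate_per_h: float = 1.0

    hr_bpm_per_arousal: float = 4.0
    scr_rate_per_arousal_hz: float = 0.01
    temp_C_per_valence: float = 0.15
    acc_bursts_per_h_per_arousal: float = 6.0

    hr_base_bpm: float = 70.0
    hr_noise_sd: float = 2.0
    hr_ar1_phi: float = 0.95
    tonic_base_uS: float = 2.0
    tonic_drift_uS: float = 0.5
    scr_base_rate_hz: float = 0.02
    scr_amp_uS: float = 0.3
    scr_tau_s: float = 4.0
    eda_noise_sd: float = 0.01
    temp_base_C: float = 33.0
    temp_drift_C: float = 0.1
    temp_noise_sd: float = 0.02
    temp_artifacts_per_h: float = 0.5
    acc_bursts_per_h: float = 10.0
    acc_burst_sd_counts: float = 12.0
    acc_noise_counts: float = 1.0

    def __post_init__(self) -> None:
        if self.emas_per_day < 1:
            raise ValueError("emas_per_day must be >= 1")
        if self.n_days < 1 or self.day_hours <= 0:
            raise ValueError("need at least one day of positive length")
        for name in ("hr_bpm_per_arousal", "scr_rate_per_arousal_hz",
                     "acc_bursts_per_h_per_arousal", "notify_jitter_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mood_process not in ("ema_locked", "markov"):
            raise ValueError("mood_process must be 'ema_locked' or 'markov'")


@dataclass
class GroundTruth:
    """Latent state segments per day plus the code behind each EMA answer."""

    #: per day: list of (seg_start_epoch, seg_end_epoch, mood_code)
    day_segments: dict[int, list[tuple[float, float, int]]]
    #: (answer_epoch, mood_code) in chronological order
    answer_states: list[tuple[float, int]]

    def label_at(self, epoch: float) -> int:
        for segs in self.day_segments.values():
            for s, e, code in segs:
                if s <= epoch < e:
                    return code
        return -1

    def to_json(self, path) -> None:
        payload = {
            "day_segments": {str(k): v for k, v in self.day_segments.items()},
            "answer_states": self.answer_states,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SimulatedParticipant:
    config: SimConfig
    days: list[DayRecording]
    ground_truth: GroundTruth

    @property
    def emas(self) -> list[EMAAnswer]:
        return sorted(a for d in self.days for a in d.emas)


# ---------------------------------------------------------------------------
# internals


def _ema_times(cfg: SimConfig, day_start: float, day_len: float, rng) -> list[tuple[float, float]]:
    """(notify, answer) epoch pairs for one day, sorted by answer time."""
    if cfg.ema_slots_min is not None:
        slots = [day_start + m * 60.0 for m in cfg.ema_slots_min]
    else:
        slots = [
            day_start + (i + 0.5) * day_len / cfg.emas_per_day
            for i in range(cfg.emas_per_day)
        ]
    pairs = []
    for slot in slots:
        notify = slot + rng.uniform(-cfg.notify_jitter_min, cfg.notify_jitter_min) * 60.0
        notify = min(max(notify, day_start), day_start + max(day_len - 120.0, 0.0))
        answer = notify + rng.exponential(cfg.reaction_mean_s)
        answer = min(answer, day_start + day_len - 1.0)
        pairs.append((notify, answer))
    return sorted(pairs, key=lambda p: p[1])


def _state_schedule(
    cfg: SimConfig, day_start: float, day_len: float, answers: list[float], rng
) -> list[tuple[float, float, int]]:
    """Latent state segments (start, end, state_index) covering the day."""
    n_states = len(cfg.mood_states)
    if cfg.mood_process == "ema_locked":
        # one segment per answer, switching at answer-time midpoints, with a
        # shuffled cycle so every state appears when there are enough prompts
        order = []
        while len(order) < len(answers):
            order.extend(rng.permutation(n_states).tolist())
        bounds = (
            [day_start]
            + [(a + b) / 2.0 for a, b in zip(answers[:-1], answers[1:])]
            + [day_start + day_len]
        )
        return [(bounds[i], bounds[i + 1], order[i]) for i in range(len(answers))]
    # markov: exponential sojourns, uniform jump to a different state
    segs = []
    t = day_start
    state = int(rng.integers(n_states))
    while t < day_start + day_len:
        sojourn = rng.exponential(3600.0 / cfg.switch_rate_per_h)
        end = min(t + sojourn, day_start + day_len)
        segs.append((t, end, state))
        t = end
        if n_states > 1:
            state = int((state + 1 + rng.integers(n_states - 1)) % n_states)
    return segs


def _per_second_latent(
    cfg: SimConfig, segs, day_start: float, n_sec: int
) -> tuple[np.ndarray, np.ndarray]:
    valence = np.zeros(n_sec)
    arousal = np.zeros(n_sec)
    for s, e, idx in segs:
        h, a = cfg.mood_states[idx]
        i0 = max(int(math.floor(s - day_start)), 0)
        i1 = min(int(math.ceil(e - day_start)), n_sec)
        valence[i0:i1] = h - 2
        arousal[i0:i1] = a - 2
    return valence, arousal


def _poisson_impulses(rate_per_s: np.ndarray, fs: float, rng, amp_fn) -> np.ndarray:
    """Impulse train at ``fs`` with per-second Poisson counts and drawn amplitudes."""
    n = int(rate_per_s.size * fs)
    impulses = np.zeros(n)
    counts = rng.poisson(np.clip(rate_per_s, 0.0, None))
    for sec in np.nonzero(counts)[0]:
        for _ in range(counts[sec]):
            k = int((sec + rng.uniform()) * fs)
            if k < n:
                impulses[k] += amp_fn()
    return impulses


def _simulate_day(cfg: SimConfig, day_index: int, rng) -> tuple[DayRecording, list, list]:
    day_start = cfg.start_epoch + day_index * 86400.0 + cfg.day_start_hour * 3600.0
    day_len = cfg.day_hours * 3600.0
    n_sec = int(round(day_len))

    times = _ema_times(cfg, day_start, day_len, rng)
    answers = [a for _, a in times]
    segs = _state_schedule(cfg, day_start, day_len, answers, rng)
    valence, arousal = _per_second_latent(cfg, segs, day_start, n_sec)

    # HR at 1 Hz: baseline + arousal coupling + AR(1) noise
    phi = cfg.hr_ar1_phi
    innov_sd = cfg.hr_noise_sd * math.sqrt(max(1.0 - phi**2, 1e-12))
    noise = np.empty(n_sec)
    noise[0] = rng.normal(0.0, cfg.hr_noise_sd)
    eps = rng.normal(0.0, innov_sd, size=n_sec)
    for k in range(1, n_sec):
        noise[k] = phi * noise[k - 1] + eps[k]
    hr = cfg.hr_base_bpm + cfg.hr_bpm_per_arousal * arousal + noise
    hr = np.clip(hr, 30.0, 220.0)

    # EDA at 4 Hz: tonic drift + Poisson SCR bumps with exponential decay
    fs_eda = 4.0
    n_eda = int(n_sec * fs_eda)
    t4 = np.arange(n_eda) / fs_eda
    phase = rng.uniform(0, 2 * np.pi)
    tonic = cfg.tonic_base_uS + cfg.tonic_drift_uS * np.sin(
        2 * np.pi * t4 / day_len + phase
    )
    scr_rate = cfg.scr_base_rate_hz + cfg.scr_rate_per_arousal_hz * arousal
    impulses = _poisson_impulses(
        scr_rate, fs_eda, rng,
        lambda: rng.lognormal(math.log(cfg.scr_amp_uS), 0.4),
    )
    decay = math.exp(-1.0 / (cfg.scr_tau_s * fs_eda))
    from scipy.signal import lfilter

    scr = lfilter([1.0], [1.0, -decay], impulses)
    eda = np.clip(tonic + scr + rng.normal(0, cfg.eda_noise_sd, n_eda), 0.01, None)

    # TEMP at 4 Hz: valence coupling + drift + injected spike artifacts
    temp = (
        cfg.temp_base_C
        + cfg.temp_C_per_valence * np.repeat(valence, int(fs_eda))
        + cfg.temp_drift_C * np.sin(2 * np.pi * t4 / day_len * 2.0 + phase)
        + rng.normal(0, cfg.temp_noise_sd, n_eda)
    )
    n_artifacts = rng.poisson(cfg.temp_artifacts_per_h * cfg.day_hours)
    for _ in range(n_artifacts):
        k = int(rng.integers(n_eda))
        temp[k] += rng.choice([-1.0, 1.0]) * rng.uniform(2.5, 5.0)

    # ACC at 32 Hz in integer counts: gravity on z + activity bursts
    fs_acc = 32.0
    n_acc = int(n_sec * fs_acc)
    acc = rng.normal(0.0, cfg.acc_noise_counts, size=(n_acc, 3))
    acc[:, 2] += ACC_COUNTS_PER_G
    burst_rate = (cfg.acc_bursts_per_h + cfg.acc_bursts_per_h_per_arousal * arousal) / 3600.0
    counts = rng.poisson(np.clip(burst_rate, 0.0, None))
    for sec in np.nonzero(counts)[0]:
        for _ in range(counts[sec]):
            k0 = int((sec + rng.uniform()) * fs_acc)
            dur = int(rng.uniform(2.0, 8.0) * fs_acc)
            k1 = min(k0 + dur, n_acc)
            acc[k0:k1] += rng.normal(0.0, cfg.acc_burst_sd_counts, size=(k1 - k0, 3))
    acc = np.clip(np.rint(acc), -127, 127)

    channels = {
        Channel.ACC_X: SignalRecording(Channel.ACC_X, day_start, fs_acc, acc[:, 0] / ACC_COUNTS_PER_G),
        Channel.ACC_Y: SignalRecording(Channel.ACC_Y, day_start, fs_acc, acc[:, 1] / ACC_COUNTS_PER_G),
        Channel.ACC_Z: SignalRecording(Channel.ACC_Z, day_start, fs_acc, acc[:, 2] / ACC_COUNTS_PER_G),
        Channel.TEMP: SignalRecording(Channel.TEMP, day_start, fs_eda, temp),
        Channel.EDA: SignalRecording(Channel.EDA, day_start, fs_eda, eda),
        Channel.HR: SignalRecording(Channel.HR, day_start, 1.0, hr),
    }

    def state_at(t: float) -> int:
        for s, e, idx in segs:
            if s <= t < e:
                return idx
        return segs[-1][2]

    emas, answer_states = [], []
    for notify, answer in times:
        idx = state_at(min(answer, day_start + day_len - 1e-6))
        h, a = cfg.mood_states[idx]
        ema = EMAAnswer(
            participant_id=cfg.participant_id,
            notify_epoch=notify,
            answer_epoch=answer,
            happiness=int(h),
            activeness=int(a),
        )
        emas.append(ema)
        answer_states.append((answer, int(mood_from_answer(h, a))))

    day = DayRecording(
        participant_id=cfg.participant_id,
        day_index=day_index,
        channels=channels,
        emas=sorted(emas),
        valid=day_len >= 600.0,
    )
    truth_segs = [
        (s, e, int(mood_from_answer(*cfg.mood_states[idx]))) for s, e, idx in segs
    ]
    return day, truth_segs, answer_states


def simulate_participant(config: SimConfig, seed: int = 0) -> SimulatedParticipant:
    """Generate every wear day of one participant, reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    days, day_segments, answer_states = [], {}, []
    for j in range(config.n_days):
        day, segs, states = _simulate_day(config, j, rng)
        days.append(day)
        day_segments[j] = segs
        answer_states.extend(states)
    truth = GroundTruth(day_segments=day_segments, answer_states=sorted(answer_states))
    return SimulatedParticipant(config=config, days=days, ground_truth=truth)


# ---------------------------------------------------------------------------
# file round-trip


def write_participant(participant: SimulatedParticipant, out_dir: str | Path) -> Path:
    """Serialize a participant as ``day<j>/{ACC,TEMP,EDA,HR}.csv`` + EMA log."""
    root = Path(out_dir) / participant.config.participant_id
    root.mkdir(parents=True, exist_ok=True)
    for day in participant.days:
        d = root / f"day{day.day_index}"
        d.mkdir(exist_ok=True)
        ch = day.channels
        write_acc(d / "ACC.csv", ch[Channel.ACC_X], ch[Channel.ACC_Y], ch[Channel.ACC_Z])
        for c in (Channel.TEMP, Channel.EDA, Channel.HR):
            write_e4_channel(d / f"{c.value}.csv", ch[c])
    write_ema_log(root / "ema_log.csv", participant.emas)
    participant.ground_truth.to_json(root / "ground_truth.json")
    return root


def load_participant(root: str | Path) -> list[DayRecording]:
    """Read a participant directory written by :func:`write_participant`."""
    root = Path(root)
    emas = read_ema_log(root / "ema_log.csv") if (root / "ema_log.csv").exists() else []
    days = []
    day_dirs = sorted(
        (p for p in root.iterdir() if p.is_dir() and p.name.startswith("day")),
        key=lambda p: int(p.name[3:]),
    )
    for p in day_dirs:
        channels = read_channel_dir(p)
        starts = [r.start_epoch for r in channels.values()]
        ends = [r.end_epoch for r in channels.values()]
        day_emas = [a for a in emas if min(starts) <= a.answer_epoch < max(ends)]
        days.append(
            DayRecording(
                participant_id=root.name,
                day_index=int(p.name[3:]),
                channels=channels,
                emas=day_emas,
                valid=all(r.duration_s >= 600.0 for r in channels.values()),
            )
        )
    return days


# ---------------------------------------------------------------------------
# named fixtures

FIXTURE_NAMES = ("separable3", "null", "collision", "tiny")


def make_fixture(name: str, seed: int = 0) -> SimulatedParticipant:
    """Deterministic scenario generators used across the test suite.

    * ``separable3`` — three moods with strong physiological coupling over
      two 6-h days; classifiers should separate them well.
    * ``null`` — identical design with every effect size 0: labels carry no
      physiological signal and accuracy should sit at chance.
    * ``collision`` — prompts scheduled 15 min apart so extrapolation
      windows overlap and the midpoint split is exercised.
    * ``tiny`` — a 12-s recording for short-input error paths.
    """
    if name == "separable3":
        cfg = SimConfig(
            participant_id="SIM-SEP3",
            n_days=2,
            day_hours=6.0,
            emas_per_day=6,
            mood_states=((4, 2), (4, 4), (2, 0)),
            hr_bpm_per_arousal=6.0,
            scr_rate_per_arousal_hz=0.02,
            temp_C_per_valence=0.4,
            acc_bursts_per_h_per_arousal=30.0,
        )
    elif name == "null":
        cfg = SimConfig(
            participant_id="SIM-NULL",
            n_days=2,
            day_hours=6.0,
            emas_per_day=6,
            mood_states=((4, 2), (4, 4), (2, 0)),
            hr_bpm_per_arousal=0.0,
            scr_rate_per_arousal_hz=0.0,
            temp_C_per_valence=0.0,
            acc_bursts_per_h_per_arousal=0.0,
            # drift terms off too: slow within-day trends would give each
            # EMA segment a memorizable signature and break exchangeability
            tonic_drift_uS=0.0,
            temp_drift_C=0.0,
        )
    elif name == "collision":
        cfg = SimConfig(
            participant_id="SIM-COLL",
            n_days=1,
            day_hours=4.0,
            ema_slots_min=(30.0, 45.0, 120.0, 135.0, 200.0),
            emas_per_day=5,
            notify_jitter_min=0.0,
            reaction_mean_s=5.0,
            mood_states=((4, 2), (2, 0)),
        )
    elif name == "tiny":
        cfg = SimConfig(
            participant_id="SIM-TINY",
            n_days=1,
            day_hours=12.0 / 3600.0,
            emas_per_day=1,
            notify_jitter_min=0.0,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return simulate_participant(cfg, seed=seed)
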