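"""Synthetic longitudinal EEG seizure studies.

Emulates a within-animal senolytic trial: each animal carries its own
baseline daily seizure rate; counts per day are Poisson at that rate,
multiplied by a treatment factor from the end of dosing onward.  Raw
traces (band-limited background with large-amplitude ictal bursts at
the true event times) can be rendered for detector testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ..errors import ConfigurationError, InputError


def default_phase_schedule() -> tuple[tuple[str, int], ...]:
    # two weeks baseline, nine days of dosing, a 48-h endpoint window,
    # then a month of follow-up
    return (("pre", 14), ("treat", 9), ("end", 2), ("post", 28))


@dataclass(frozen=True)
class EEGSimConfig:
    seed: int = 0
    n_animals: int = 6
    fs_hz: float = 2048.0
    band_hz: tuple[float, float] = (0.5, 70.0)
    session_hours: float = 24.0
    phase_schedule: tuple[tuple[str, int], ...] = field(
        default_factory=default_phase_schedule)
    baseline_rate_per_day: float = 3.0
    rate_dispersion: float = 0.5  # lognormal sigma of per-animal baselines
    treatment_multiplier: float = 1.0
    treated_from_phase: str = "end"  # multiplier applies from this phase on
    ictal_dur_s: float = 20.0
    ictal_gain: float = 6.0

    def __post_init__(self) -> None:
        if not self.phase_schedule:
            raise ConfigurationError("phase schedule is empty")
        labels = [p[0] for p in self.phase_schedule]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("phase labels must be unique")
        if any(d <= 0 for _, d in self.phase_schedule):
            raise ConfigurationError("phase durations must be positive days")
        if self.baseline_rate_per_day < 0 or self.treatment_multiplier < 0:
            raise ConfigurationError("rates and multipliers must be non-negative")
        if self.n_animals < 1:
            raise ConfigurationError("need at least one animal")


@dataclass
class StudyData:
    """True per-animal daily seizure counts and event times."""

    counts: pd.DataFrame  # animal, day, phase, n_seizures
    event_times: dict[tuple[int, int], np.ndarray]  # (animal, day) -> seconds
    animal_rates: dict[int, float]  # baseline rate per day

    def phase_daily_frequency(self) -> pd.DataFrame:
        """Mean daily seizure frequency per animal and phase."""
        return (self.counts.groupby(["animal", "phase"], sort=False)
                ["n_seizures"].mean().rename("daily_frequency").reset_index())


def gen_eeg_study(cfg: EEGSimConfig) -> StudyData:
    """Simulate the longitudinal study's true seizure counts and times.

    Per animal and day the count is Poisson(baseline x phase
    multiplier), where the multiplier is ``treatment_multiplier`` from
    ``treated_from_phase`` onward and 1 before.  Event times within a
    day are uniform over the session.
    """
    rng = np.random.default_rng(cfg.seed)
    base = cfg.baseline_rate_per_day * rng.lognormal(
        -cfg.rate_dispersion**2 / 2, cfg.rate_dispersion, size=cfg.n_animals)
    labels = [p[0] for p in cfg.phase_schedule]
    treated = set()
    if cfg.treated_from_phase in labels:
        treated = set(labels[labels.index(cfg.treated_from_phase):])

    session_s = cfg.session_hours * 3600.0
    rows = []
    times: dict[tuple[int, int], np.ndarray] = {}
    for a in range(cfg.n_animals):
        day = 0
        for phase, n_days in cfg.phase_schedule:
            mult = cfg.treatment_multiplier if phase in treated else 1.0
            lam = base[a] * mult * (cfg.session_hours / 24.0)
            for _ in range(n_days):
                n = int(rng.poisson(lam))
                rows.append((a, day, phase, n))
                times[(a, day)] = np.sort(rng.uniform(0, session_s, size=n))
                day += 1
    counts = pd.DataFrame(rows, columns=["animal", "day", "phase", "n_seizures"])
    return StudyData(counts, times, {a: float(base[a]) for a in range(cfg.n_animals)})


def gen_eeg_trace(duration_s: float, fs_hz: float, event_times,
                  ictal_dur_s: float = 20.0, ictal_gain: float = 6.0,
                  band_hz: tuple[float, float] = (0.5, 70.0),
                  noise_sd_uv: float = 50.0,
                  seed: int | None = None) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render a raw EEG trace with ictal bursts at the given onset times.

    Background is white noise band-passed to ``band_hz``.  Each burst is
    a frequency-gliding oscillation (8 -> 4 Hz) at ``ictal_gain`` times
    the background amplitude under a Hann envelope — a sustained sharp
    increase in amplitude and frequency content, as electrographic
    seizures appear on a spectrogram.  Returns (trace_uv, list of true
    (onset_s, offset_s) intervals actually inserted).
    """
    if duration_s <= 0:
        raise InputError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    x = rng.normal(0.0, noise_sd_uv, size=n)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    x = signal.sosfiltfilt(sos, x)
    bg_sd = x.std()

    intervals = []
    m = int(round(ictal_dur_s * fs_hz))
    t = np.arange(m) / fs_hz
    for t0 in np.asarray(event_times, dtype=float):
        a = int(round(t0 * fs_hz))
        if a < 0 or a + m > n:
            continue
        freq = np.linspace(8.0, 4.0, m)  # spike-train slowing through the seizure
        phase = 2 * np.pi * np.cumsum(freq) / fs_hz
        env = np.hanning(m)
        burst = ictal_gain * bg_sd * env * np.sin(phase)
        burst += 0.3 * ictal_gain * bg_sd * env * rng.normal(size=m)
        x[a:a + m] += burst
        intervals.append((a / fs_hz, (a + m) / fs_hz))
    return x, intervals
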