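"""Ictal-event detection and longitudinal seizure-frequency analysis.

Electrographic seizures appear on cortical EEG as sustained, sharp
increases in amplitude and frequency content.  Detection integrates
Morlet wavelet power over 1-50 Hz, bins it, normalizes it robustly
over the recording (median/MAD, so the seizures themselves do not
inflate the baseline), and keeps long-enough supra-threshold runs.
Phase comparisons (pre-treatment / end of dosing / follow-up) use the
exact two-tailed Mann-Whitney test from :mod:`epimap.stats`, the test
the small group sizes call for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .stats import MWResult, SummaryStats, mann_whitney_exact, summary_stats

_MAD_TO_SD = 0.6744897501960817


@dataclass(frozen=True)
class MorletParams:
    freq_lo_hz: float = 1.0
    freq_hi_hz: float = 50.0
    n_freqs: int = 50
    n_cycles: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.freq_lo_hz < self.freq_hi_hz:
            raise ParameterError("need 0 < freq_lo < freq_hi")
        if self.n_cycles < 3:
            raise ParameterError("n_cycles must be >= 3")

    @property
    def freqs(self) -> np.ndarray:
        return np.geomspace(self.freq_lo_hz, self.freq_hi_hz, self.n_freqs)


@dataclass(frozen=True)
class SeizureDetectParams:
    bin_s: float = 1.0
    power_threshold_sd: float = 6.0
    min_dur_s: float = 10.0
    merge_gap_s: float = 5.0

    def __post_init__(self) -> None:
        if min(self.bin_s, self.power_threshold_sd, self.min_dur_s,
               self.merge_gap_s) <= 0:
            raise ParameterError("all seizure-detection parameters must be > 0")


@dataclass(frozen=True)
class IctalEvent:
    t_onset_s: float
    t_offset_s: float
    peak_z: float

    @property
    def duration_s(self) -> float:
        return self.t_offset_s - self.t_onset_s


@dataclass(frozen=True)
class SessionSummary:
    animal_id: int | str
    phase: str
    hours_recorded: float
    n_seizures: int
    daily_frequency: float


@dataclass(frozen=True)
class PhaseComparison:
    stats: dict[str, SummaryStats]
    tests: dict[tuple[str, str], MWResult]
    seizure_free: dict[str, list[bool]]


def morlet_power(x, fs_hz: float, params: MorletParams | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency power via Morlet wavelets.

    Returns (power, freqs) with power of shape (n_freqs, n_times).
    Frequencies are log-spaced over the configured band; each wavelet
    carries ``n_cycles`` cycles.
    """
    from mne.time_frequency import tfr_array_morlet

    params = params or MorletParams()
    x = np.asarray(x, dtype=float)
    if params.freq_hi_hz >= fs_hz / 2:
        raise ParameterError("band exceeds Nyquist frequency")
    longest = params.n_cycles / params.freq_lo_hz
    if x.size <= longest * fs_hz:
        raise InputError(f"trace shorter than the longest wavelet ({longest:g} s)")
    power = tfr_array_morlet(x[np.newaxis, np.newaxis, :], sfreq=fs_hz,
                             freqs=params.freqs, n_cycles=params.n_cycles,
                             output="power", zero_mean=True, verbose="error")
    return power[0, 0], params.freqs


def detect_seizures(x, fs_hz: float, mp: MorletParams | None = None,
                    sp: SeizureDetectParams | None = None) -> list[IctalEvent]:
    """Detect ictal events from integrated 1-50 Hz Morlet power.

    Total band power per ``bin_s`` bin is normalized over the recording
    with a median/MAD z-score; runs above ``power_threshold_sd`` are
    merged across gaps shorter than ``merge_gap_s`` and kept when at
    least ``min_dur_s`` long.
    """
    mp = mp or MorletParams()
    sp = sp or SeizureDetectParams()
    x = np.asarray(x, dtype=float)
    if x.size < sp.min_dur_s * fs_hz:
        raise InputError("trace shorter than the minimum event duration")
    power, _ = morlet_power(x, fs_hz, mp)
    total = power.sum(axis=0)

    bin_n = max(1, int(round(sp.bin_s * fs_hz)))
    n_bins = total.size // bin_n
    if n_bins < 2:
        raise InputError("trace too short for the chosen bin size")
    binned = total[:n_bins * bin_n].reshape(n_bins, bin_n).mean(axis=1)

    med = np.median(binned)
    mad = np.median(np.abs(binned - med))
    if mad == 0:
        return []
    z = (binned - med) / (mad / _MAD_TO_SD)

    supra = z >= sp.power_threshold_sd
    runs = _runs(supra)
    # merge across short gaps
    merged = []
    gap_bins = sp.merge_gap_s / sp.bin_s
    for a, b in runs:
        if merged and a - merged[-1][1] < gap_bins:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = []
    for a, b in merged:
        if (b - a) * sp.bin_s >= sp.min_dur_s:
            events.append(IctalEvent(a * sp.bin_s, b * sp.bin_s,
                                     float(z[a:b].max())))
    return events


def _runs(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [list(p) for p in zip(idx[::2], idx[1::2])]


def daily_frequency(sessions) -> tuple[list[SessionSummary], dict[object, SummaryStats]]:
    """Per-session daily seizure frequency and per-animal summaries.

    ``sessions`` is a table (or records) with columns ``animal``,
    ``phase``, ``hours_recorded`` and ``n_seizures``.  Frequency is the
    count normalized to 24 h; discontinuous sessions are each
    normalized, then summarized per animal.
    """
    df = pd.DataFrame(sessions)
    required = {"animal", "phase", "hours_recorded", "n_seizures"}
    if missing := required - set(df.columns):
        raise InputError(f"sessions lack columns: {sorted(missing)}")
    if (df["hours_recorded"] <= 0).any():
        raise InputError("every session needs positive recorded hours")
    out = [SessionSummary(r.animal, r.phase, float(r.hours_recorded),
                          int(r.n_seizures),
                          r.n_seizures / r.hours_recorded * 24.0)
           for r in df.itertuples()]
    per_animal = {
        a: summary_stats([s.daily_frequency for s in out if s.animal_id == a])
        for a in df["animal"].unique()
    }
    return out, per_animal


def compare_phases(freq_pre, freq_end, freq_post) -> PhaseComparison:
    """Pre / end-of-treatment / post phase comparison of daily frequencies.

    Each argument is the per-animal mean daily seizure frequency in that
    phase (>= 2 animals).  Returns pairwise exact two-tailed
    Mann-Whitney p-values, per-phase summaries, and a per-animal
    seizure-free flag (frequency exactly zero) in each phase.
    """
    phases = {"pre": np.asarray(freq_pre, dtype=float),
              "end": np.asarray(freq_end, dtype=float),
              "post": np.asarray(freq_post, dtype=float)}
    for name, v in phases.items():
        if v.size < 2:
            raise InputError(f"phase {name!r} needs at least 2 values")
    stats = {name: summary_stats(v) for name, v in phases.items()}
    tests = {}
    for a, b in (("pre", "end"), ("pre", "post"), ("end", "post")):
        tests[(a, b)] = mann_whitney_exact(phases[a], phases[b], seed=0)
    free = {name: [x == 0.0 for x in v] for name, v in phases.items()}
    return PhaseComparison(stats, tests, free)
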