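"""Ground-truth-annotated synthetic MEA slice recordings.

The generator emulates the activity topography seen in dysplastic
cortical slices: a small *core* of grid-adjacent electrodes bearing
both synchronous interictal-like discharges (IILDs) and elevated
multi-unit activity (MUA), a *surround* with sparse MUA only, and a
silent remainder.  A high-potassium condition scales every channel's
MUA rate without extending the IILD zone.

Waveforms (free parameters; the source recordings are not deposited):
MUA spikes are 1 ms negative-dominant biphasic wavelets; IILDs are
biphasic raised-cosine-windowed slow deflections (default 300 ms,
energy < 40 Hz) carrying an amplitude-modulated ripple burst drawn from
the 100-500 Hz band.  Background is white Gaussian noise.

All randomness flows from one seed, split into independent substreams
for IILD placement, MUA placement and noise — so the high-K variant of
a seed shares its IILD times exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..ephys import Recording
from ..spatial import MEALayout

#: Default activity topography on the 10 x 12 grid: a 2 x 2 core block
#: (rows 4-5, cols 5-6) and its 8-neighborhood ring as surround.
DEFAULT_CORE = frozenset({53, 54, 65, 66})
DEFAULT_SURROUND = frozenset(
    r * 12 + c for r in range(3, 7) for c in range(4, 8)
) - DEFAULT_CORE


def _default_amplitudes() -> dict[str, float]:
    return {"spike_uv": 60.0, "iild_slow_uv": 150.0, "iild_ripple_uv": 15.0}


@dataclass(frozen=True)
class MEASimConfig:
    seed: int = 0
    duration_s: float = 600.0
    fs_hz: float = 10_000.0
    noise_sd_uv: float = 5.0
    layout: MEALayout = field(default_factory=MEALayout)
    core_electrodes: frozenset[int] = DEFAULT_CORE
    surround_electrodes: frozenset[int] = DEFAULT_SURROUND
    silent_electrodes: frozenset[int] | None = None  # None: complement
    mua_rate_core_hz: float = 0.74
    mua_rate_surround_hz: float = 0.05
    iild_rate_per_min: float = 2.0
    iild_slow_dur_ms: float = 300.0
    iild_ripple_band_hz: tuple[float, float] = (100.0, 500.0)
    iild_jitter_ms: float = 10.0
    spike_width_ms: float = 1.0
    amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    high_k: bool = False
    high_k_mua_multiplier: float = 5.0

    def __post_init__(self) -> None:
        n = self.layout.n_channels
        core = frozenset(self.core_electrodes)
        surr = frozenset(self.surround_electrodes)
        if core & surr:
            raise ConfigurationError("core and surround electrode sets overlap")
        sil = self.silent_electrodes
        if sil is None:
            sil = frozenset(range(n)) - core - surr
        else:
            sil = frozenset(sil)
            if sil & (core | surr):
                raise ConfigurationError("silent set overlaps core/surround")
        for s in (core, surr, sil):
            if any(ch < 0 or ch >= n for ch in s):
                raise ConfigurationError("electrode set outside layout")
        object.__setattr__(self, "core_electrodes", core)
        object.__setattr__(self, "surround_electrodes", surr)
        object.__setattr__(self, "silent_electrodes", sil)
        if min(self.mua_rate_core_hz, self.mua_rate_surround_hz,
               self.iild_rate_per_min) < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.fs_hz <= 2 * self.iild_ripple_band_hz[1]:
            raise ConfigurationError("fs too low for the ripple band")
        if self.duration_s <= 0:
            raise ConfigurationError("duration must be positive")

    def mua_rate(self, channel: int) -> float:
        if channel in self.core_electrodes:
            r = self.mua_rate_core_hz
        elif channel in self.surround_electrodes:
            r = self.mua_rate_surround_hz
        else:
            r = 0.0
        return r * (self.high_k_mua_multiplier if self.high_k else 1.0)


@dataclass
class GroundTruth:
    """True event times and rates behind a simulated recording."""

    events: pd.DataFrame  # columns: channel, t_s, kind
    rates_hz: dict[int, float]  # true MUA rate per channel
    network_iilds: list[tuple[float, tuple[int, ...]]]
    duration_s: float

    def channel_events(self, channel: int, kind: str | None = None) -> np.ndarray:
        df = self.events
        m = df["channel"] == channel
        if kind is not None:
            m &= df["kind"] == kind
        return df.loc[m, "t_s"].to_numpy()


def spike_waveform(fs_hz: float, width_ms: float, amp_uv: float) -> np.ndarray:
    """Negative-dominant biphasic extracellular spike, peak at -amp_uv."""
    n = max(4, int(round(width_ms * 1e-3 * fs_hz)))
    t = np.arange(n) / n
    w = -np.sin(2 * np.pi * t) * np.exp(-2.5 * t)
    return amp_uv * w / np.max(np.abs(w))


def iild_waveform(fs_hz: float, slow_dur_ms: float, slow_amp_uv: float,
                  ripple_freq_hz: float, ripple_amp_uv: float) -> np.ndarray:
    """Biphasic raised-cosine slow deflection plus a windowed ripple burst."""
    n = max(8, int(round(slow_dur_ms * 1e-3 * fs_hz)))
    t = np.arange(n) / n
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * t)
    # decaying envelope makes the leading lobe dominant, so the moment of
    # peak deflection is unambiguous for both truth and detection
    slow = -np.sin(2 * np.pi * t) * hann * np.exp(-1.5 * t)
    slow = slow_amp_uv * slow / np.max(np.abs(slow))
    # ripple burst over the middle third, amplitude-modulated
    rn = n // 3
    rt = np.arange(rn) / fs_hz
    renv = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(rn) / rn)
    ripple = ripple_amp_uv * renv * np.sin(2 * np.pi * ripple_freq_hz * rt)
    out = slow.copy()
    a = n // 3
    out[a:a + rn] += ripple
    return out


def _add(trace: np.ndarray, wave: np.ndarray, start: int) -> None:
    a = max(0, start)
    b = min(trace.size, start + wave.size)
    if b > a:
        trace[a:b] += wave[a - start:b - start]


def gen_mea_recording(cfg: MEASimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one MEA recording with its ground truth.

    Per channel, true MUA spikes follow a homogeneous Poisson process at
    the zone rate; IILDs occur only on core channels, synchronously
    (one shared network time, +/- ``iild_jitter_ms`` per channel).  The
    high-K condition multiplies all MUA rates by
    ``high_k_mua_multiplier`` and leaves IILD placement untouched.
    Truth times are the moment of peak absolute deflection of each
    inserted waveform.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_iild, rng_mua, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    n_ch = cfg.layout.n_channels
    n_samp = int(round(cfg.duration_s * cfg.fs_hz))
    # fill per channel: keeps peak memory at one float64 row over the
    # float32 trace matrix even for the full 120-channel, 10-min default
    traces = np.empty((n_ch, n_samp), dtype=np.float32)
    for ch in range(n_ch):
        traces[ch] = rng_noise.normal(0.0, cfg.noise_sd_uv, size=n_samp)

    amp = cfg.amplitudes
    rows: list[tuple[int, float, str]] = []
    network: list[tuple[float, tuple[int, ...]]] = []

    # --- IILDs: shared network times on the core, jittered per channel ---
    core = tuple(sorted(cfg.core_electrodes))
    iild_rate_hz = cfg.iild_rate_per_min / 60.0
    n_net = rng_iild.poisson(iild_rate_hz * cfg.duration_s) if core else 0
    # keep discharges clear of the detector's edge-guard band
    margin = cfg.iild_slow_dur_ms * 1e-3 + 0.7
    net_times = np.sort(rng_iild.uniform(margin, cfg.duration_s - margin,
                                         size=n_net)) if n_net else np.empty(0)
    slow_n = max(8, int(round(cfg.iild_slow_dur_ms * 1e-3 * cfg.fs_hz)))
    for t_net in net_times:
        members = []
        for ch in core:
            jit = rng_iild.uniform(-cfg.iild_jitter_ms, cfg.iild_jitter_ms) * 1e-3
            f_rip = rng_iild.uniform(*cfg.iild_ripple_band_hz)
            wave = iild_waveform(cfg.fs_hz, cfg.iild_slow_dur_ms,
                                 amp["iild_slow_uv"], f_rip, amp["iild_ripple_uv"])
            start = int(round((t_net + jit) * cfg.fs_hz)) - slow_n // 2
            _add(traces[ch], wave.astype(np.float32), start)
            t_true = (start + int(np.argmax(np.abs(wave)))) / cfg.fs_hz
            rows.append((ch, t_true, "IILD"))
            members.append(ch)
        network.append((float(t_net), tuple(members)))

    # --- MUA: independent Poisson trains per channel at the zone rate ---
    spike = spike_waveform(cfg.fs_hz, cfg.spike_width_ms, amp["spike_uv"])
    pk_off = int(np.argmax(np.abs(spike)))
    rates = {}
    lo = 2e-3
    hi = cfg.duration_s - cfg.spike_width_ms * 1e-3 - 2e-3
    for ch in range(n_ch):
        rate = cfg.mua_rate(ch)
        rates[ch] = rate
        n_spk = rng_mua.poisson(rate * cfg.duration_s)
        if n_spk == 0 or hi <= lo:
            continue
        t_spk = np.sort(rng_mua.uniform(lo, hi, size=n_spk))
        for t in t_spk:
            start = int(round(t * cfg.fs_hz))
            _add(traces[ch], spike.astype(np.float32), start)
            rows.append((ch, (start + pk_off) / cfg.fs_hz, "MUA_SPIKE"))

    events = pd.DataFrame(rows, columns=["channel", "t_s", "kind"])
    events = events.sort_values(["channel", "t_s"], ignore_index=True)
    condition = "high_K" if cfg.high_k else "control_ACSF"
    rec = Recording(traces, cfg.fs_hz, list(range(n_ch)), condition)
    return rec, GroundTruth(events, rates, network, cfg.duration_s)


def high_k_variant(cfg: MEASimConfig) -> MEASimConfig:
    """Same seed and topography under the pro-convulsive high-K condition."""
    return replace(cfg, high_k=True)
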