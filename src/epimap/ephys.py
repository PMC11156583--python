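"""Interictal-like discharge (IILD) and multi-unit activity (MUA) detection.

Acute-slice MEA recordings show two signatures of hyperexcitability:
slow, often biphasic field-potential deflections carrying superimposed
100-500 Hz ripples (IILDs), and brief (~1 ms) extracellular spikes from
nearby units (MUA).  Both are detected with the same scheme: band-pass
the trace (1-40 Hz for IILDs, >250 Hz for MUA), square it, z-normalize
the squared signal over the whole recording, and mark supra-threshold
regions.  Thresholds are expressed in robust standard deviations of the
*band-filtered amplitude* (median-absolute-deviation scale estimate),
the convention of extracellular spike detection; on the normalized
squared signal this corresponds to a cut of ((k*sigma_r)^2 - mean)/sd.

Filters are second-order Bessel, applied forward-backward so event
times are not biased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InputError, ParameterError
from .spatial import MEALayout

_MAD_TO_SD = 0.6744897501960817  # Phi^-1(0.75): MAD of a Gaussian in sigma units


class EventKind(str, Enum):
    IILD = "IILD"
    MUA_SPIKE = "MUA_SPIKE"


class ElectrodeClass(str, Enum):
    IILD_MUA = "IILD_MUA"
    MUA_ONLY = "MUA_ONLY"
    SILENT = "SILENT"
    DEFECTIVE = "DEFECTIVE"


@dataclass
class Recording:
    """Multichannel extracellular recording in microvolts."""

    traces: np.ndarray  # (n_channels, n_samples) float32
    fs_hz: float
    channel_ids: list[int]
    condition: str = "control_ACSF"

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces))
        if self.fs_hz <= 0:
            raise InputError("sampling rate must be positive")
        if len(self.channel_ids) != self.traces.shape[0]:
            raise InputError("channel_ids length != number of traces")

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs_hz


@dataclass(frozen=True)
class DetectionParams:
    """Detection settings; thresholds are in robust SDs of the filtered amplitude."""

    iild_band_hz: tuple[float, float] = (1.0, 40.0)
    mua_highpass_hz: float = 250.0
    display_band_hz: tuple[float, float] = (100.0, 500.0)
    filter_order: int = 2
    iild_threshold_sd: float = 3.0
    mua_threshold_sd: float = 5.0
    iild_min_sep_ms: float = 200.0
    iild_min_dur_ms: float = 40.0
    edge_guard_s: float = 0.5  # ignore IILDs here: filter edge artifacts
    mua_refractory_ms: float = 1.0
    slow_fraction_cut: float = 0.5
    detrend: bool = True
    notch_hz: float | None = None  # e.g. 50.0 for line-noise removal
    spike_polarity: str = "neg"  # "neg": count negative-going crossings only

    def __post_init__(self) -> None:
        if self.iild_threshold_sd <= 0 or self.mua_threshold_sd <= 0:
            raise ParameterError("thresholds must be positive")
        if self.spike_polarity not in ("neg", "both"):
            raise ParameterError("spike_polarity must be 'neg' or 'both'")


@dataclass
class Event:
    """A detected event with half-open time bounds [onset, offset)."""

    channel: int
    t_onset_s: float
    t_peak_s: float
    t_offset_s: float
    kind: EventKind
    peak_z: float
    slow_energy: float | None = None
    fast_energy: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_onset_s <= self.t_peak_s < self.t_offset_s):
            raise InputError("event bounds must satisfy onset <= peak < offset")


@dataclass(frozen=True)
class ElectrodeActivity:
    channel: int
    mua_rate_hz: float
    iild_count: int
    cls: ElectrodeClass

    def __post_init__(self) -> None:
        if self.mua_rate_hz < 0:
            raise ParameterError("rates must be non-negative")


@dataclass(frozen=True)
class NetworkEvent:
    """Synchronous IILD shared across grid-adjacent channels."""

    t_s: float
    channels: tuple[int, ...]
    n_members: int


@dataclass
class EventClassification:
    kind: EventKind
    slow_energy: float
    fast_energy: float
    slow_fraction: float
    spectrogram_f: np.ndarray
    spectrogram_t: np.ndarray
    spectrogram_power: np.ndarray


def bandpass_filter(x, fs_hz: float, low_hz: float, high_hz: float, order: int = 2):
    """Zero-phase Bessel band-pass.

    ``low_hz = 0`` gives a pure low-pass; ``high_hz = fs/2`` a pure
    high-pass.  Applied forward-backward (sosfiltfilt), so the effective
    magnitude response is the square of a single order-``order`` pass.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs_hz / 2.0
    if not (0 <= low_hz < high_hz <= nyq):
        raise ParameterError(f"invalid band ({low_hz}, {high_hz}) for fs={fs_hz}")
    if low_hz == 0 and high_hz >= nyq:
        return x.copy()
    if low_hz == 0:
        sos = signal.bessel(order, high_hz, btype="lowpass", fs=fs_hz, output="sos")
    elif high_hz >= nyq:
        sos = signal.bessel(order, low_hz, btype="highpass", fs=fs_hz, output="sos")
    else:
        sos = signal.bessel(order, [low_hz, high_hz], btype="bandpass",
                            fs=fs_hz, output="sos")
    # pad by a few periods of the lowest corner so start/end transients
    # (severe for the 1 Hz corner) do not masquerade as events
    f_min = low_hz if low_hz > 0 else high_hz
    padlen = int(min(x.size - 1, max(24, 3 * fs_hz / f_min)))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def _preprocess(x, fs_hz, params: DetectionParams):
    y = np.asarray(x, dtype=float)
    if params.detrend:
        y = signal.detrend(y, type="linear")
    if params.notch_hz is not None:
        b, a = signal.iirnotch(params.notch_hz, Q=30.0, fs=fs_hz)
        y = signal.filtfilt(b, a, y)
    return y


def normalized_power(x, fs_hz, low_hz, high_hz, params: DetectionParams):
    """Filter, square and z-normalize; returns (filtered, z, sigma_robust).

    The returned ``z`` has mean 0 and SD 1 over the full trace (the
    normalization contract); ``sigma_robust`` is the MAD-based scale of
    the filtered amplitude used to place thresholds.
    """
    y = bandpass_filter(_preprocess(x, fs_hz, params), fs_hz, low_hz, high_hz,
                        params.filter_order)
    s = y * y
    sd = s.std()
    if sd == 0:
        return y, np.zeros_like(s), 0.0
    z = (s - s.mean()) / sd
    sigma_r = np.median(np.abs(y)) / _MAD_TO_SD
    return y, z, sigma_r


def _amp_cut_to_z(amp_cut: float, s_mean: float, s_sd: float) -> float:
    return ((amp_cut * amp_cut) - s_mean) / s_sd


def _contiguous_regions(mask: np.ndarray):
    """(start, stop) index pairs of True runs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_iilds(x, fs_hz: float, params: DetectionParams | None = None,
                 channel: int = 0) -> list[Event]:
    """Detect interictal-like discharges on one channel.

    Pipeline: detrend (+ optional notch) -> 1-40 Hz band-pass -> square
    -> z-normalize over the full trace -> mark regions above the
    threshold -> drop regions shorter than ``iild_min_dur_ms`` -> merge
    regions closer than ``iild_min_sep_ms`` -> extend bounds to the
    half-threshold crossings.  Events are returned sorted by onset.
    """
    params = params or DetectionParams()
    x = np.asarray(x, dtype=float)
    if x.size < fs_hz:
        raise InputError("trace must be at least 1 s long")
    y, z, sigma_r = normalized_power(x, fs_hz, *params.iild_band_hz, params)
    if sigma_r == 0:
        return []
    s = y * y
    cut = (params.iild_threshold_sd * sigma_r) ** 2
    regions = _contiguous_regions(s >= cut)
    # gate before merging: brief chance crossings of band-limited noise must
    # not chain into long spurious events through the merge window
    min_len = int(round(params.iild_min_dur_ms * 1e-3 * fs_hz))
    regions = [r for r in regions if r[1] - r[0] >= min_len]
    # the reflection padding of the zero-phase filter leaves residual
    # low-frequency power at the trace edges; exclude a guard band there
    guard = int(round(params.edge_guard_s * fs_hz))
    regions = [r for r in regions if r[0] >= guard and r[1] <= s.size - guard]
    regions = _merge_regions(regions, int(round(params.iild_min_sep_ms * 1e-3 * fs_hz)))

    half = cut / 2.0
    events = []
    for a, b in regions:
        while a > 0 and s[a - 1] >= half:
            a -= 1
        while b < s.size and s[b] >= half:
            b += 1
        pk = a + int(np.argmax(z[a:b]))
        ev = Event(channel, a / fs_hz, pk / fs_hz, b / fs_hz,
                   EventKind.IILD, float(z[pk]))
        ev.slow_energy, ev.fast_energy = _band_energies(x, fs_hz, a, b, params)
        events.append(ev)
    return events


def _merge_regions(regions, gap_samples: int):
    if not regions:
        return []
    merged = [list(regions[0])]
    for a, b in regions[1:]:
        if a - merged[-1][1] < gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def detect_mua(x, fs_hz: float, params: DetectionParams | None = None,
               channel: int = 0) -> list[Event]:
    """Detect multi-unit spikes on one channel (>250 Hz band).

    Same square/normalize/threshold scheme as IILD detection; supra-
    threshold crossings within ``mua_refractory_ms`` collapse into one
    spike.  With ``spike_polarity='neg'`` (default) only negative-going
    deflections count, matching the dominant trough of extracellular
    spikes and halving the chance-crossing rate.
    """
    params = params or DetectionParams()
    x = np.asarray(x, dtype=float)
    if x.size < fs_hz:
        raise InputError("trace must be at least 1 s long")
    y, z, sigma_r = normalized_power(x, fs_hz, params.mua_highpass_hz, fs_hz / 2,
                                     params)
    if sigma_r == 0:
        return []
    s = y * y
    cut = (params.mua_threshold_sd * sigma_r) ** 2
    supra = s >= cut
    if params.spike_polarity == "neg":
        supra &= y < 0
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    refr = max(1, int(round(params.mua_refractory_ms * 1e-3 * fs_hz)))
    breaks = np.flatnonzero(np.diff(idx) > refr)
    groups = np.split(idx, breaks + 1)
    events = []
    for g in groups:
        a, b = int(g[0]), int(g[-1]) + 1
        pk = g[int(np.argmax(z[g]))]
        events.append(Event(channel, a / fs_hz, pk / fs_hz, b / fs_hz,
                            EventKind.MUA_SPIKE, float(z[pk])))
    return events


def _band_energies(x, fs_hz, a, b, params: DetectionParams,
                   pad_s: float = 0.128):
    """(slow, fast) energy of samples [a, b) using a padded filter window."""
    pad = int(round(pad_s * fs_hz))
    lo = max(0, a - pad)
    hi = min(len(x), b + pad)
    seg = np.asarray(x[lo:hi], dtype=float)
    if seg.size == 0:
        raise InputError("empty event window")
    slow = bandpass_filter(seg, fs_hz, *params.iild_band_hz, params.filter_order)
    fast = bandpass_filter(seg, fs_hz, *params.display_band_hz, params.filter_order)
    sl = slice(a - lo, b - lo)
    return float(np.sum(slow[sl] ** 2)), float(np.sum(fast[sl] ** 2))


def classify_event(x, fs_hz: float, event: Event,
                   params: DetectionParams | None = None) -> EventClassification:
    """IILD-versus-spike call from spectral content of the event window.

    An event is an IILD when the <40 Hz band holds at least
    ``slow_fraction_cut`` of its (slow + 100-500 Hz) energy — a
    discharge rides on a slow deflection, whereas an isolated spike has
    only a sharp high-frequency component.  A short-time power
    spectrogram of the window is returned for display.
    """
    params = params or DetectionParams()
    x = np.asarray(x, dtype=float)
    a = int(round(event.t_onset_s * fs_hz))
    b = int(round(event.t_offset_s * fs_hz))
    if not (0 <= a < b <= x.size):
        raise InputError("event window outside trace")
    slow, fast = _band_energies(x, fs_hz, a, b, params)
    total = slow + fast
    frac = slow / total if total > 0 else 1.0
    kind = EventKind.IILD if frac >= params.slow_fraction_cut else EventKind.MUA_SPIKE

    pad = int(round(0.128 * fs_hz))
    seg = x[max(0, a - pad):min(x.size, b + pad)]
    nper = min(256, seg.size)
    f, t, p = signal.spectrogram(seg, fs_hz, nperseg=nper,
                                 noverlap=nper // 2)
    return EventClassification(kind, slow, fast, frac, f, t, p)


def summarize_electrode(iild_events, mua_events, duration_s: float,
                        min_spikes: int = 10, min_iilds: int = 2,
                        channel: int | None = None,
                        defective: bool = False) -> ElectrodeActivity:
    """Per-electrode activity class and MUA rate.

    Classes: IILD_MUA when the channel bears at least ``min_iilds``
    discharges, else MUA_ONLY when it bears at least ``min_spikes``
    spikes, else SILENT.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    iild_events = list(iild_events)
    mua_events = list(mua_events)
    if channel is None:
        channel = next((e.channel for e in iild_events + mua_events), -1)
    n_spikes = len(mua_events)
    n_iilds = len(iild_events)
    if defective:
        cls = ElectrodeClass.DEFECTIVE
    elif n_iilds >= min_iilds:
        cls = ElectrodeClass.IILD_MUA
    elif n_spikes >= min_spikes:
        cls = ElectrodeClass.MUA_ONLY
    else:
        cls = ElectrodeClass.SILENT
    return ElectrodeActivity(channel, n_spikes / duration_s, n_iilds, cls)


def group_network_iilds(events_by_channel: dict[int, list[Event]],
                        layout: MEALayout, window_ms: float = 50.0) -> list[NetworkEvent]:
    """Group IILDs into network events by single-linkage over grid neighbors.

    Two discharges join the same network event when their channels are
    8-neighbors on the grid and their peaks differ by at most
    ``window_ms``.  Discharges that link to nothing form singleton
    events.
    """
    flat = []
    for ch, evs in events_by_channel.items():
        if not 0 <= ch < layout.n_channels:
            raise InputError(f"unknown channel {ch}")
        for e in evs:
            if e.kind != EventKind.IILD:
                raise InputError("group_network_iilds expects IILD events only")
            flat.append(e)
    if not flat:
        return []
    flat.sort(key=lambda e: e.t_peak_s)
    parent = list(range(len(flat)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    win = window_ms * 1e-3
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if flat[j].t_peak_s - flat[i].t_peak_s > win:
                break
            if layout.are_adjacent(flat[i].channel, flat[j].channel):
                parent[find(i)] = find(j)

    groups: dict[int, list[Event]] = {}
    for i, e in enumerate(flat):
        groups.setdefault(find(i), []).append(e)
    out = []
    for members in groups.values():
        t = float(np.median([e.t_peak_s for e in members]))
        chans = tuple(sorted({e.channel for e in members}))
        out.append(NetworkEvent(t, chans, len(members)))
    out.sort(key=lambda ne: ne.t_s)
    return out


def events_to_frame(events) -> pd.DataFrame:
    """Flatten events into the standard CSV-ready table."""
    return pd.DataFrame([{
        "channel": e.channel,
        "t_onset_s": e.t_onset_s,
        "t_peak_s": e.t_peak_s,
        "t_offset_s": e.t_offset_s,
        "kind": e.kind.value,
        "peak_z": e.peak_z,
    } for e in events])


def detect_recording(rec: Recording, params: DetectionParams | None = None,
                     min_spikes: int = 10, min_iilds: int = 2):
    """Run both detectors on every channel of a recording.

    Returns (iild_events_by_channel, mua_events_by_channel, activities).
    """
    params = params or DetectionParams()
    iilds: dict[int, list[Event]] = {}
    muas: dict[int, list[Event]] = {}
    acts = []
    for row, ch in enumerate(rec.channel_ids):
        x = rec.traces[row]
        iilds[ch] = detect_iilds(x, rec.fs_hz, params, channel=ch)
        muas[ch] = detect_mua(x, rec.fs_hz, params, channel=ch)
        acts.append(summarize_electrode(iilds[ch], muas[ch], rec.duration_s,
                                        min_spikes, min_iilds, channel=ch))
    return iilds, muas, acts
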