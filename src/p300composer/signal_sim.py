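"""Synthetic multichannel EEG time-locked to a flash schedule, plus preprocessing.

The simulator stands in for the amplifier: it emits 6-channel, 250 Hz signals
in microvolts with event markers.  Flashes of the row or column containing the
attended element add a positive half-cosine (Hann-shaped) deflection peaking
~300 ms after flash onset — the P300 — with a parietal-maximal topography;
everything else is background noise (AR(1) by default, white optionally).
Preprocessing follows the online system: a 4th-order Butterworth band-pass at
1–15 Hz (causal on the decoding path, zero-phase available offline) and
fixed-window epoching around each flash with optional pre-stimulus baseline
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .matrix_engine import FlashSchedule, StimulusEvent

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "PO7", "PO8", "Oz")

#: Per-channel weight of the P300 template; parietal maximum (Pz/Cz) is the
#: defining property, occipito-parietal sites intermediate, frontal weakest.
DEFAULT_TOPOGRAPHY = {"Fz": 0.4, "Cz": 1.0, "Pz": 1.0, "PO7": 0.6, "PO8": 0.6, "Oz": 0.6}


@dataclass(frozen=True)
class RecordingParams:
    """Generator settings. Amplitudes in microvolts, times in seconds."""

    fs: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_sd: float = 4.0
    noise_model: str = "ar1"  # 'ar1' | 'white'
    ar_coefficient: float = 0.95
    p300_amplitude: float = 5.0
    p300_latency: float = 0.30
    p300_width: float = 0.30
    channel_topography: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOPOGRAPHY)
    )
    seed: int | None = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("ar1", "white"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def topography_vector(self) -> np.ndarray:
        return np.array([self.channel_topography.get(ch, 1.0) for ch in self.channels])


@dataclass
class Recording:
    """Multichannel signal in microvolts with flash markers."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: tuple[str, ...]
    markers: list[tuple[int, StimulusEvent]]  # (sample index, event)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        n = self.samples.shape[1]
        for idx, _ in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker sample {idx} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def p300_template(fs: float, width: float, amplitude: float) -> np.ndarray:
    """Positive half-cosine (Hann) bump of the given width, peak = amplitude."""
    n = max(int(round(width * fs)), 1)
    t = np.arange(n) / fs
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / width))


def _background_noise(rng: np.random.Generator, params: RecordingParams, n: int) -> np.ndarray:
    n_ch = len(params.channels)
    if params.noise_sd == 0:
        return np.zeros((n_ch, n))
    if params.noise_model == "white":
        return rng.normal(0.0, params.noise_sd, size=(n_ch, n))
    # AR(1): innovation SD scaled so the stationary process SD equals noise_sd
    rho = params.ar_coefficient
    innov_sd = params.noise_sd * np.sqrt(1.0 - rho**2)
    innov = rng.normal(0.0, innov_sd, size=(n_ch, n))
    return signal.lfilter([1.0], [1.0, -rho], innov, axis=1)


def synthesize_recording(
    schedule: FlashSchedule,
    attended: tuple[int, int],
    params: RecordingParams,
    lead_in: float = 0.5,
    tail: float = 1.0,
) -> Recording:
    """Generate a recording for one stimulation run.

    Every flash of a group containing the attended element adds the P300
    template, centered ``p300_latency`` after flash onset and scaled by the
    per-channel topography.  ``lead_in`` seconds of plain background precede
    the first flash so that pre-stimulus baselines exist for every marker.
    Deterministic given ``params.seed``.
    """
    if not schedule.events:
        raise ValueError("schedule is empty")
    row, col = attended
    if not (0 <= row < schedule.n_rows and 0 <= col < schedule.n_cols):
        raise IndexError(f"attended element {attended} outside matrix")

    fs = params.fs
    lead = int(round(lead_in * fs))
    n = lead + int(np.ceil((schedule.duration + tail) * fs))
    rng = np.random.default_rng(params.seed)
    data = _background_noise(rng, params, n)

    template = p300_template(fs, params.p300_width, params.p300_amplitude)
    topo = params.topography_vector()
    start_offset = int(round((params.p300_latency - params.p300_width / 2.0) * fs))

    markers: list[tuple[int, StimulusEvent]] = []
    for ev in schedule.events:
        idx = lead + int(round(ev.onset * fs))
        markers.append((idx, ev))
        if ev.contains(row, col) and params.p300_amplitude != 0.0:
            a = idx + start_offset
            b = min(a + template.size, n)
            if a < 0 or b <= a:
                raise ValueError("P300 template does not fit in the recording")
            data[:, a:b] += topo[:, None] * template[: b - a]

    return Recording(data, fs, params.channels, markers, meta={"attended": attended})


def bandpass(
    recording: Recording,
    order: int = 4,
    band: tuple[float, float] = (1.0, 15.0),
    mode: str = "causal",
) -> Recording:
    """Butterworth band-pass filter each channel independently.

    ``mode='causal'`` mimics the online system (single forward pass);
    ``mode='zero-phase'`` applies forward-backward filtering for offline use.
    """
    lo, hi = band
    nyq = recording.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=recording.fs, output="sos")
    if mode == "causal":
        filtered = signal.sosfilt(sos, recording.samples, axis=1)
    elif mode == "zero-phase":
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    meta = dict(recording.meta)
    meta["filter"] = {"order": order, "band": band, "mode": mode}
    return Recording(np.asarray(filtered), recording.fs, recording.channels,
                     list(recording.markers), meta)


@dataclass
class EpochSet:
    """Per-flash epochs with target/non-target labels.

    ``epochs`` has shape (n_epochs, n_channels, n_samples); the label is True
    for flashes whose group contains the attended element.
    """

    epochs: np.ndarray
    window: tuple[float, float]
    labels: np.ndarray  # bool
    group_kinds: np.ndarray  # 'row' | 'column'
    group_indices: np.ndarray
    sequence_indices: np.ndarray
    fs: float
    channels: tuple[str, ...]
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def sequence(self, s: int) -> "EpochSet":
        """Epochs of one flashing sequence."""
        m = self.sequence_indices == s
        return EpochSet(self.epochs[m], self.window, self.labels[m],
                        self.group_kinds[m], self.group_indices[m],
                        self.sequence_indices[m], self.fs, self.channels)

    def concat(self, other: "EpochSet") -> "EpochSet":
        if self.window != other.window or self.fs != other.fs:
            raise ValueError("incompatible epoch sets")
        return EpochSet(
            np.concatenate([self.epochs, other.epochs]),
            self.window,
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.group_kinds, other.group_kinds]),
            np.concatenate([self.group_indices, other.group_indices]),
            np.concatenate([self.sequence_indices, other.sequence_indices]),
            self.fs,
            self.channels,
        )


def extract_epochs(
    recording: Recording,
    attended: tuple[int, int],
    window: tuple[float, float] = (0.0, 0.8),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
) -> EpochSet:
    """Cut one epoch per flash marker and label it target/non-target.

    ``window`` is relative to flash onset; the number of samples is
    ``round((t_end - t_start) * fs)``.  With ``baseline=(a, b)`` the mean of
    the pre-stimulus interval is subtracted per channel.  Epochs that run past
    either edge of the recording are dropped with a warning and counted in
    ``n_dropped``.
    """
    row, col = attended
    fs = recording.fs
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    a_off = int(round(t0 * fs))
    n_samp = int(round((t1 - t0) * fs))
    if baseline is not None:
        b0 = int(round(baseline[0] * fs))
        b1 = int(round(baseline[1] * fs))
        if b1 <= b0:
            raise ValueError("baseline end must exceed baseline start")

    epochs, labels, kinds, gidx, sidx = [], [], [], [], []
    n_dropped = 0
    n_total = recording.n_samples
    for idx, ev in recording.markers:
        lo = idx + a_off
        hi = lo + n_samp
        blo, bhi = (idx + b0, idx + b1) if baseline is not None else (lo, hi)
        if min(lo, blo) < 0 or max(hi, bhi) > n_total:
            n_dropped += 1
            continue
        ep = recording.samples[:, lo:hi].copy()
        if baseline is not None:
            ep -= recording.samples[:, blo:bhi].mean(axis=1, keepdims=True)
        epochs.append(ep)
        labels.append(ev.contains(row, col))
        kinds.append(ev.group_kind)
        gidx.append(ev.group_index)
        sidx.append(ev.sequence_index)

    if n_dropped:
        warnings.warn(f"dropped {n_dropped} epochs at recording edges", stacklevel=2)
    return EpochSet(
        np.array(epochs) if epochs else np.empty((0, len(recording.channels), n_samp)),
        window,
        np.array(labels, dtype=bool),
        np.array(kinds),
        np.array(gidx, dtype=int),
        np.array(sidx, dtype=int),
        fs,
        recording.channels,
        n_dropped,
    )


def relabel(epochs: EpochSet, schedule_like_attended: tuple[int, int]) -> EpochSet:
    """Same epochs, labels recomputed for a different attended element."""
    row, col = schedule_like_attended
    labels = np.where(
        epochs.group_kinds == "row",
        epochs.group_indices == row,
        epochs.group_indices == col,
    )
    return replace(epochs, labels=labels.astype(bool))
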