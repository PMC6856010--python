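"""Filtering, downsampling, epoching and sliding-window extraction.

All filters are zero-phase (forward-backward) so that window features are
not phase-shifted relative to the event markers. Event times are kept in
seconds throughout, which makes them invariant to resampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "TrialSet",
    "AnalysisWindow",
    "bandpass_filter",
    "notch_filter",
    "downsample",
    "epoch_trials",
    "sliding_windows",
]


@dataclass
class EEGRecording:
    """Continuous multichannel signal with co-registered event markers.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitude in microvolts (or arbitrary units for synthetic data).
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Unique channel labels, e.g. ``["C3", "Cz", "C4"]``.
    events : list of (float, str)
        ``(onset_seconds, condition)`` pairs; onsets must lie inside the
        recording span.
    """

    signal: np.ndarray
    fs: float
    channels: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channels)} channel labels were given"
            )
        dur = self.duration
        for onset, _ in self.events:
            if not 0 <= onset <= dur:
                raise ValueError(f"event at {onset} s outside recording span [0, {dur}] s")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialSet:
    """Epochs time-locked to event onsets.

    ``data`` has shape (n_trials, n_channels, n_samples); ``times`` is the
    common time axis in seconds relative to onset.
    """

    data: np.ndarray
    conditions: list[str]
    channels: list[str]
    fs: float
    times: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("trial data must be 3-D (trials, channels, samples)")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def select(self, condition: str) -> "TrialSet":
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return TrialSet(
            self.data[idx],
            [self.conditions[i] for i in idx],
            self.channels,
            self.fs,
            self.times,
        )


@dataclass
class AnalysisWindow:
    """One causal single-channel analysis segment ending at time ``t_end``.

    ``t_end`` is in seconds relative to movement onset: the window covers
    ``[t_end - duration, t_end]``.
    """

    samples: np.ndarray
    fs: float
    t_end: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


def _check_band(fs: float, *edges: float) -> None:
    nyq = fs / 2.0
    for e in edges:
        if not 0 < e < nyq:
            raise ValueError(f"band edge {e} Hz outside (0, {nyq}) Hz at fs={fs}")


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # reflect-pad 3 filter lengths to suppress edge transients
    padlen = min(x.shape[-1] - 1, 3 * 2 * sos.shape[0] * 3)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def bandpass_filter(
    rec: EEGRecording, low: float = 0.5, high: float = 45.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass; ``order`` is the design order
    before the forward-backward pass doubles it."""
    _check_band(rec.fs, low, high)
    if low >= high:
        raise ValueError("low edge must be below high edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, signal=_filtfilt(sos, rec.signal))


def notch_filter(rec: EEGRecording, freq: float = 50.0, quality: float = 25.0) -> EEGRecording:
    """Zero-phase IIR notch (default Q=25 gives a ~2 Hz stopband at 50 Hz)."""
    _check_band(rec.fs, freq)
    b, a = signal.iirnotch(freq, quality, fs=rec.fs)
    sos = signal.tf2sos(b, a)
    return replace(rec, signal=_filtfilt(sos, rec.signal))


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased decimation to ``target_fs``; events stay in seconds."""
    if target_fs >= rec.fs:
        raise ValueError(f"target fs {target_fs} must be below current fs {rec.fs}")
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = signal.decimate(rec.signal, int(round(ratio)), axis=-1, zero_phase=True)
    else:
        n_out = int(round(rec.n_samples * target_fs / rec.fs))
        out = signal.resample(rec.signal, n_out, axis=-1)
    return replace(rec, signal=out, fs=target_fs)


def epoch_trials(rec: EEGRecording, span: tuple[float, float] = (-3.0, 3.0)) -> TrialSet:
    """Cut one fixed-length trial per event, time-locked to the onset.

    Events too close to the recording edges are dropped with a warning.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must be increasing")
    n_pre = int(round(-t0 * rec.fs))
    n_post = int(round(t1 * rec.fs))
    n_len = n_pre + n_post
    trials, conds = [], []
    for onset, cond in rec.events:
        i = int(round(onset * rec.fs))
        if i - n_pre < 0 or i + n_post > rec.n_samples:
            warnings.warn(
                f"event at {onset:.3f} s too close to recording edge; trial dropped",
                stacklevel=2,
            )
            continue
        trials.append(rec.signal[:, i - n_pre : i + n_post])
        conds.append(cond)
    data = (
        np.stack(trials) if trials else np.empty((0, len(rec.channels), n_len))
    )
    times = (np.arange(n_len) - n_pre) / rec.fs + 0.0
    return TrialSet(data, conds, list(rec.channels), rec.fs, times)


def sliding_windows(
    trial: np.ndarray,
    fs: float,
    length: float = 2.0,
    step: float = 0.1,
    t_start: float = -3.0,
    channel: str = "",
) -> list[AnalysisWindow]:
    """Causal sliding windows over a single-channel trial.

    The window labeled ``t`` covers ``[t - length, t]``; the first label is
    ``t_start + length``. With a 6 s trial, 2 s windows and 100 ms steps
    this yields 41 windows labeled -1.0 ... +3.0 s.
    """
    x = np.asarray(trial, dtype=float).ravel()
    n_win = int(round(length * fs))
    if n_win > x.size:
        raise ValueError(f"trial of {x.size} samples shorter than {length} s window")
    if step * fs < 1:
        raise ValueError("step below one sample")
    # step*fs need not be an integer (100 ms at 128 Hz is 12.8 samples):
    # start indices accumulate on the exact time grid and labels stay on
    # the nominal step grid, so a 6 s trial yields 41 windows -1.0..+3.0 s.
    out = []
    i = 0
    while True:
        start = int(round(i * step * fs))
        if start + n_win > x.size:
            break
        t_end = t_start + length + i * step
        out.append(AnalysisWindow(x[start : start + n_win], fs, t_end, channel))
        i += 1
    return out
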