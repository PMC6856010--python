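"""Synthetic EEG with programmed LRTC and ERD dynamics.

Ground-truth generators for estimator validation (exact fractional
Gaussian noise, ARFIMA processes) and a full synthetic movement
experiment: three channels at 128 Hz, 6 s trials, a broadband background
whose fractional-integration parameter d ramps up around movement onset,
and a 10 Hz oscillation whose amplitude drops around onset.

Time-varying d is realized by fractionally integrating one shared
innovation stream at a small grid of d values and interpolating between
the grid outputs sample by sample according to the programmed d(t); this
preserves local scaling without seams.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import lfilter

from broadlrtc.arfima import fractional_integrate
from broadlrtc.preprocessing import EEGRecording

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_fgn",
    "simulate_arfima",
    "synthesize_movement_dataset",
]

#: samples discarded from the start of every simulation to remove transients
BURN_IN = 1024

CONDITIONS = ("right", "left", "rest")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic movement experiment."""

    n_participants: int = 1
    n_trials_per_condition: int = 40
    fs: float = 128.0
    trial_span: tuple[float, float] = (-3.0, 3.0)
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    d_baseline: float = 0.05
    d_peak: float = 0.35
    d_ramp_window: tuple[float, float] = (-1.0, 0.0)
    alpha_freq: float = 10.0
    alpha_amplitude: float = 1.0
    alpha_suppression: float = 0.3
    erd_ramp_window: tuple[float, float] = (-0.5, 0.5)
    innovation_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.d_baseline <= self.d_peak < 0.5:
            raise ValueError("require 0 <= d_baseline <= d_peak < 0.5")
        if not 0 <= self.alpha_suppression <= 1:
            raise ValueError("alpha_suppression must lie in [0, 1]")
        n = (self.trial_span[1] - self.trial_span[0]) * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs x trial length must be an integer sample count")

    @property
    def n_trial_samples(self) -> int:
        return int(round((self.trial_span[1] - self.trial_span[0]) * self.fs))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Programmed per-trial dynamics of one participant's recording.

    ``d_profiles`` and ``alpha_scales`` have shape (n_trials, n_samples)
    on the trial time axis ``times`` (seconds relative to onset).
    """

    conditions: list[str]
    onsets: np.ndarray
    times: np.ndarray
    d_profiles: np.ndarray
    alpha_scales: np.ndarray


def generate_fgn(H: float, n_samples: int, seed=None) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte).

    Mean 0, unit variance, autocovariance
    gamma(k) = 0.5 (|k+1|^2H - 2|k|^2H + |k-1|^2H) reproduced exactly, so
    this generator can serve as an independent oracle for DFA.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    n = int(n_samples)
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1.0) ** (2 * H)
    )
    # circulant first row of size 2(n-1): gamma(0..n-1), gamma(n-2..1)
    row = np.r_[gamma, gamma[-2:0:-1]]
    m = row.size
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:
        raise RuntimeError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    w = np.empty(m, dtype=complex)
    u = rng.standard_normal(m // 2 + 1)
    v = rng.standard_normal(m // 2 + 1)
    w[0] = np.sqrt(lam[0] / m) * u[0]
    w[m // 2] = np.sqrt(lam[m // 2] / m) * u[m // 2]
    j = np.arange(1, m // 2)
    w[j] = np.sqrt(lam[j] / (2 * m)) * (u[j] + 1j * v[j])
    w[m - j] = np.conj(w[j])
    return np.fft.fft(w).real[:n]


def _check_ar_stationary(ar: np.ndarray) -> None:
    if len(ar) == 0:
        return
    # characteristic roots of z^p - phi_1 z^(p-1) - ... - phi_p must lie inside
    roots = np.roots(np.r_[1.0, -ar])
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError(
            "AR polynomial has a root on or inside the unit circle; "
            "the requested ARFIMA process is not stationary"
        )


def simulate_arfima(
    ar_coeffs=(),
    d: float = 0.0,
    ma_coeffs=(),
    n_samples: int = 1024,
    innovation_sd: float = 1.0,
    seed=None,
    burn_in: int = BURN_IN,
) -> np.ndarray:
    """Realization of ARFIMA(p, d, q) with normal innovations.

    Innovations pass through the ARMA recursion and are then fractionally
    integrated by d; a burn-in of ``burn_in`` samples is discarded.
    """
    ar = np.asarray(ar_coeffs, dtype=float)
    ma = np.asarray(ma_coeffs, dtype=float)
    if abs(d) >= 0.5:
        raise ValueError(f"|d| must be below 0.5 for stationarity, got {d}")
    _check_ar_stationary(ar)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, innovation_sd, n_samples + burn_in)
    x = lfilter(np.r_[1.0, ma], np.r_[1.0, -ar], eps)
    if d != 0:
        x = fractional_integrate(x, d)
    return x[burn_in:]


def _ramp(times: np.ndarray, window: tuple[float, float], lo: float, hi: float) -> np.ndarray:
    """lo before the window, linear rise inside, hi after (held)."""
    t0, t1 = window
    out = np.full(times.size, lo)
    if t1 > t0:
        inside = (times >= t0) & (times <= t1)
        out[inside] = lo + (hi - lo) * (times[inside] - t0) / (t1 - t0)
    out[times > t1] = hi
    return out


def _background_with_varying_d(
    eps: np.ndarray, d_profile: np.ndarray, d_grid: np.ndarray, burn_in: int
) -> np.ndarray:
    """Interpolate fractional integrations of shared innovations over a d grid."""
    n = d_profile.size
    layers = np.stack([fractional_integrate(eps, dg)[burn_in:] for dg in d_grid])
    if d_grid.size == 1:
        return layers[0][:n]
    idx = np.clip(np.searchsorted(d_grid, d_profile, side="right") - 1, 0, d_grid.size - 2)
    lo = d_grid[idx]
    frac = (d_profile - lo) / (d_grid[idx + 1] - lo)
    t = np.arange(n)
    return (1 - frac) * layers[idx, t] + frac * layers[idx + 1, t]


def _alpha_component(
    times: np.ndarray, scale: np.ndarray, freq: float, amplitude: float, rng
) -> np.ndarray:
    # random-walk phase jitter broadens the 10 Hz peak slightly
    dt = times[1] - times[0]
    jitter = np.cumsum(rng.normal(0.0, 0.05, times.size))
    phase = 2 * np.pi * freq * times + rng.uniform(0, 2 * np.pi) + jitter
    return amplitude * scale * np.sin(phase)


def synthesize_movement_dataset(
    config: SyntheticConfig,
) -> tuple[list[EEGRecording], list[GroundTruth]]:
    """Full synthetic experiment: one recording + ground truth per participant.

    Movement trials carry a d ramp (d_baseline -> d_peak inside
    d_ramp_window, held afterwards) in the broadband background and an
    alpha amplitude drop (scale 1 -> 1 - alpha_suppression inside
    erd_ramp_window); rest trials are stationary. Channels receive
    independent noise realizations with identical programmed dynamics.
    Identical config (including seed) gives identical output arrays.
    """
    root = np.random.SeedSequence(config.seed)
    participants_ss = root.spawn(config.n_participants)
    nt = config.n_trial_samples
    times = config.trial_span[0] + np.arange(nt) / config.fs
    d_grid = (
        np.linspace(config.d_baseline, config.d_peak, 7)
        if config.d_peak > config.d_baseline
        else np.array([config.d_baseline])
    )

    recordings, truths = [], []
    for p_ss in participants_ss:
        rng = np.random.default_rng(p_ss)
        conditions = [c for c in CONDITIONS for _ in range(config.n_trials_per_condition)]
        order = rng.permutation(len(conditions))
        conditions = [conditions[i] for i in order]

        d_rest = np.full(nt, config.d_baseline)
        s_rest = np.ones(nt)
        d_move = _ramp(times, config.d_ramp_window, config.d_baseline, config.d_peak)
        s_move = _ramp(
            times, config.erd_ramp_window, 1.0, 1.0 - config.alpha_suppression
        )

        trial_signals, d_profiles, alpha_scales = [], [], []
        for cond in conditions:
            d_prof = d_rest if cond == "rest" else d_move
            s_prof = s_rest if cond == "rest" else s_move
            chans = []
            for _ in config.channels:
                eps = rng.normal(0.0, config.innovation_sd, nt + BURN_IN)
                bg = _background_with_varying_d(eps, d_prof, d_grid, BURN_IN)
                alpha = _alpha_component(
                    times, s_prof, config.alpha_freq, config.alpha_amplitude, rng
                )
                chans.append(bg + alpha)
            trial_signals.append(np.stack(chans))
            d_profiles.append(d_prof)
            alpha_scales.append(s_prof)

        signal = np.concatenate(trial_signals, axis=1)
        pre = -config.trial_span[0]
        trial_dur = config.trial_span[1] - config.trial_span[0]
        onsets = pre + trial_dur * np.arange(len(conditions))
        rec = EEGRecording(
            signal,
            config.fs,
            list(config.channels),
            [(float(t), c) for t, c in zip(onsets, conditions)],
        )
        recordings.append(rec)
        truths.append(
            GroundTruth(
                conditions,
                onsets,
                times,
                np.stack(d_profiles),
                np.stack(alpha_scales),
            )
        )
    return recordings, truths
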