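"""Ablation experiments probing LRTC / ERD complementarity.

Two interventions: (1) suppress ERD by giving every window in a trial the
alpha-band Fourier magnitudes of one randomly chosen donor window (phases
kept, all other bins untouched); (2) remove LRTC by fractionally
differencing each window by its own d = H - 0.5. Condition contrasts use
the Mann-Whitney U test per window label; the ERD-LRTC relationship is
summarized by the lag-0 Pearson correlation and the lag of maximum
cross-correlation per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from broadlrtc.arfima import fractional_difference
from broadlrtc.dfa import estimate_hurst
from broadlrtc.erd import ALPHA_BAND

logger = logging.getLogger(__name__)

__all__ = [
    "AblationResult",
    "LagAnalysis",
    "suppress_erd",
    "remove_lrtc",
    "compare_conditions",
    "erd_lrtc_lag",
    "lag_analysis",
]


@dataclass
class AblationResult:
    """Original vs ablated traces on a shared time axis, with per-time
    Mann-Whitney p-values and the 0.05 significance mask."""

    times: np.ndarray
    original: np.ndarray
    ablated: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray


@dataclass
class LagAnalysis:
    """Per-trial ERD-LRTC correlation and best cross-correlation lag."""

    r: np.ndarray
    best_lag: np.ndarray
    lag_counts: dict[int, int]

    @property
    def mode_lag(self) -> int:
        return max(self.lag_counts, key=self.lag_counts.get)


def suppress_erd(
    windows: np.ndarray,
    fs: float,
    band: tuple[float, float] = ALPHA_BAND,
    rng_seed=None,
) -> tuple[np.ndarray, int]:
    """Fix the alpha-band magnitude spectrum of all windows in one trial.

    One donor window is drawn uniformly at random; every window's Fourier
    magnitudes in bins with 8 <= f <= 13 Hz (inclusive; 11 bins for 2 s
    windows at 128 Hz) are replaced by the donor's while each window keeps
    its own phases. Bins outside the band are untouched and the output is
    exactly real. Returns (modified windows, donor index).
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2:
        raise ValueError("windows must be a (n_windows, n_samples) array")
    if w.shape[0] < 2:
        raise ValueError("need at least 2 windows per trial")
    rng = np.random.default_rng(rng_seed)
    donor = int(rng.integers(w.shape[0]))
    spec = np.fft.rfft(w, axis=1)
    freqs = np.fft.rfftfreq(w.shape[1], d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    donor_mag = np.abs(spec[donor, mask])
    phase = np.angle(spec[:, mask])
    spec[:, mask] = donor_mag[None, :] * np.exp(1j * phase)
    return np.fft.irfft(spec, n=w.shape[1], axis=1), donor


def remove_lrtc(windows: np.ndarray, taper: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Fractionally difference each window by its own DFA-derived d.

    Returns (differenced windows, d values). Windows whose DFA is
    degenerate are passed through unchanged with d = NaN.
    """
    w = np.atleast_2d(np.asarray(windows, dtype=float))
    out = np.empty_like(w)
    ds = np.full(w.shape[0], np.nan)
    for i, x in enumerate(w):
        res = estimate_hurst(x, taper=taper)
        if res.H is None:
            logger.warning("window %d degenerate; LRTC removal skipped", i)
            out[i] = x
            continue
        ds[i] = res.H - 0.5
        out[i] = fractional_difference(x - x.mean(), ds[i])
    return out, ds


def compare_conditions(
    traces_a: np.ndarray, traces_b: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney U per window label.

    Rows are the unit of observation (participants for grand-average
    analysis, trials within a participant). All-tied columns get p = 1.
    Returns (p_values, significance mask at ``alpha``).
    """
    a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("traces must share window labels")
    if min(a.shape[0], b.shape[0]) < 3:
        raise ValueError("need at least 3 observations per group")
    p = np.ones(a.shape[1])
    for j in range(a.shape[1]):
        col_a, col_b = a[:, j], b[:, j]
        pooled = np.concatenate([col_a, col_b])
        if np.ptp(pooled) == 0:
            logger.info("all-tied data at column %d; p set to 1", j)
            continue
        p[j] = stats.mannwhitneyu(col_a, col_b, alternative="two-sided").pvalue
    return p, p < alpha


def erd_lrtc_lag(
    erd_trace: np.ndarray, lrtc_trace: np.ndarray, max_lag: int = 20
) -> tuple[float, int, np.ndarray] | None:
    """Lag-0 Pearson r and normalized cross-correlation of two demeaned
    traces over lags in [-max_lag, max_lag].

    Positive best lag means the LRTC trace lags the ERD trace. Returns
    None (trial excluded) when either trace is constant. The best lag
    maximizes |cross-correlation|.
    """
    e = np.asarray(erd_trace, dtype=float).ravel()
    h = np.asarray(lrtc_trace, dtype=float).ravel()
    if e.size != h.size:
        raise ValueError("traces must be aligned on the same window labels")
    if np.ptp(e) == 0 or np.ptp(h) == 0:
        logger.warning("constant trace; trial excluded from lag analysis")
        return None
    e = e - e.mean()
    h = h - h.mean()
    norm = np.sqrt((e**2).sum() * (h**2).sum())
    full = np.correlate(h, e, mode="full")  # index shift: h delayed by lag
    mid = e.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    valid = lags[(lags > -e.size) & (lags < e.size)]
    cc = full[mid + valid] / norm
    r = float(cc[valid == 0][0]) if 0 in valid else float("nan")
    best = int(valid[np.argmax(np.abs(cc))])
    return r, best, cc


def lag_analysis(
    erd_traces: np.ndarray, lrtc_traces: np.ndarray, max_lag: int = 20
) -> LagAnalysis:
    """Per-trial lag analysis over matched (n_trials, n_times) trace arrays."""
    rs, lags = [], []
    for e, h in zip(np.atleast_2d(erd_traces), np.atleast_2d(lrtc_traces)):
        res = erd_lrtc_lag(e, h, max_lag)
        if res is None:
            continue
        rs.append(res[0])
        lags.append(res[1])
    counts: dict[int, int] = {}
    for lag in lags:
        counts[lag] = counts.get(lag, 0) + 1
    return LagAnalysis(np.asarray(rs), np.asarray(lags), counts)
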