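"""Detrended fluctuation analysis on short windows.

Estimates the Hurst exponent of each 2 s window as the slope of the
log2-log2 plot of RMS fluctuations against box size, with forward/backward
averaging for box sizes that do not divide the window length. A
maximum-likelihood model comparison on the log-log plot (linear vs
polynomial, logarithmic and exponential alternatives) validates that a
single power law holds before the exponent is trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, signal

logger = logging.getLogger(__name__)

__all__ = [
    "DFAResult",
    "SpectralCharacterization",
    "select_box_sizes",
    "dfa_fluctuations",
    "estimate_hurst",
    "validate_mldfa",
    "smooth_hurst_series",
    "characterize_acf_spectrum",
]

#: H in this open interval declares long-range temporal correlation present.
LRTC_RANGE = (0.5, 1.0)


@dataclass
class DFAResult:
    """Hurst estimate with the per-box-size fluctuations that produced it."""

    H: float | None
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_r2: float = float("nan")
    mldfa_best_model: str | None = None
    valid: bool = False

    @property
    def lrtc_present(self) -> bool:
        return self.H is not None and LRTC_RANGE[0] < self.H < LRTC_RANGE[1]


@dataclass
class SpectralCharacterization:
    """Descriptive ACF / PACF / power-spectrum summary of one window."""

    acf: np.ndarray
    pacf: np.ndarray
    beta: float            # magnitude of the log-log spectral slope
    spectrum_B: float      # S(f) = B * f**-beta
    acf_alpha: float       # rho(t) = C * t**-alpha (power-law ACF fit)
    acf_C: float
    in_lrtc_slope_range: bool = field(init=False)

    def __post_init__(self) -> None:
        self.in_lrtc_slope_range = bool(0.5 <= self.beta <= 1.5)


def select_box_sizes(
    N: int, n_min: int = 10, count: int = 25, deduplicate: bool = True
) -> np.ndarray:
    """Box sizes log2-equidistant in [n_min, N/4].

    Rounding to integers can create duplicates for small N; these are
    removed unless ``deduplicate=False``.
    """
    n_max = N // 4
    if n_max < n_min:
        raise ValueError(
            f"series of length {N} cannot host box sizes in [{n_min}, N/4]"
        )
    sizes = np.round(
        2.0 ** np.linspace(np.log2(n_min), np.log2(n_max), count)
    ).astype(int)
    if deduplicate:
        sizes = np.unique(sizes)
    return sizes


@lru_cache(maxsize=32)
def _cached_box_sizes(N: int) -> np.ndarray:
    return select_box_sizes(N)


def _box_rms_sq(profile: np.ndarray, n: int) -> tuple[float, int]:
    """Sum of squared linear-detrend residuals over floor(N/n) boxes."""
    nb = profile.size // n
    seg = profile[: nb * n].reshape(nb, n)
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = (t_c**2).sum()
    slope = seg @ t_c / denom
    intercept = seg.mean(axis=1)
    resid = seg - slope[:, None] * t[None, :] - (intercept - slope * t.mean())[:, None]
    return float((resid**2).sum()), nb * n


def dfa_fluctuations(series: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """RMS fluctuation F(n) of the integrated, mean-subtracted series.

    Because N is in general not divisible by n, F(n) is the average of the
    fluctuation computed on the series and on its time reversal.
    """
    x = np.asarray(series, dtype=float).ravel()
    box_sizes = np.asarray(box_sizes, dtype=int)
    if x.size < box_sizes.max():
        raise ValueError("series shorter than the largest box size")
    out = np.empty(box_sizes.size)
    for direction, weight in ((x, 0.5), (x[::-1], 0.5)):
        profile = np.cumsum(direction - direction.mean())
        for j, n in enumerate(box_sizes):
            ss, m = _box_rms_sq(profile, int(n))
            f = np.sqrt(ss / m)
            if direction is x:
                out[j] = weight * f
            else:
                out[j] += weight * f
    return out


def estimate_hurst(window, taper: bool = True, validate: bool = False) -> DFAResult:
    """DFA Hurst exponent of one analysis window.

    A Hanning taper is applied to the raw window by default to reduce edge
    effects; disable it with ``taper=False`` (the taper measurably biases
    the estimate and is therefore toggleable). ``validate=True`` runs the
    ML model comparison on the resulting log-log plot.
    """
    x = np.asarray(getattr(window, "samples", window), dtype=float).ravel()
    if x.size < 40:
        raise ValueError(f"window of {x.size} samples too short for DFA")
    if taper:
        x = x * np.hanning(x.size)
    sizes = _cached_box_sizes(x.size)
    F = dfa_fluctuations(x, sizes)
    if np.any(F <= 1e-14):
        logger.warning("degenerate window (zero fluctuation); H undefined")
        return DFAResult(None, sizes, F, valid=False)
    logn, logF = np.log2(sizes), np.log2(F)
    H, intercept = np.polyfit(logn, logF, 1)
    pred = H * logn + intercept
    ss_res = float(((logF - pred) ** 2).sum())
    ss_tot = float(((logF - logF.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    result = DFAResult(float(H), sizes, F, fit_r2=r2, valid=H > 0)
    if validate:
        result = validate_mldfa(result)
    return result


# --- ML-DFA model comparison -------------------------------------------------

def _gauss_loglik(rss: float, n: int) -> float:
    rss = max(rss, n * 1e-24)  # exact fits: keep logL finite, ranking by k
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def _aicc(rss: float, n: int, k: int) -> float:
    # k counts regression parameters plus the noise variance
    k = k + 1
    if n - k - 1 <= 0:
        return np.inf
    return 2 * k - 2 * _gauss_loglik(rss, n) + 2 * k * (k + 1) / (n - k - 1)


def validate_mldfa(result: DFAResult) -> DFAResult:
    """Model comparison on (log2 n, log2 F): the Hurst exponent is valid
    only when the straight line beats polynomial (order 2-5), logarithmic
    and exponential alternatives under a small-sample information
    criterion (Gaussian ML residuals, AICc). Models within 2 AICc of the
    minimum are treated as equivalently supported and the most
    parsimonious of them wins, so a more complex model must show
    substantial support to displace the straight line."""
    x = np.log2(result.box_sizes.astype(float))
    y = np.log2(result.fluctuations)
    n = x.size
    if n < 6:
        raise ValueError(f"need at least 6 (n, F) pairs for ML-DFA, got {n}")
    scores: dict[str, float] = {}
    n_params: dict[str, int] = {}

    for order in range(1, 6):
        coef = np.polyfit(x, y, order)
        rss = float(((y - np.polyval(coef, x)) ** 2).sum())
        name = "linear" if order == 1 else f"polynomial_{order}"
        scores[name] = _aicc(rss, n, order + 1)
        n_params[name] = order + 1

    lx = np.log(x)
    coef = np.polyfit(lx, y, 1)
    rss = float(((y - np.polyval(coef, lx)) ** 2).sum())
    scores["logarithmic"] = _aicc(rss, n, 2)
    n_params["logarithmic"] = 2

    def expmodel(t, a, b, c):
        return a * np.exp(np.clip(b * t, -50, 50)) + c

    try:
        popt, _ = optimize.curve_fit(
            expmodel, x, y,
            p0=[(y[-1] - y[0]) / max(np.exp(x[-1]) - np.exp(x[0]), 1e-9), 0.5, y[0]],
            maxfev=5000,
        )
        rss = float(((y - expmodel(x, *popt)) ** 2).sum())
        scores["exponential"] = _aicc(rss, n, 3)
        n_params["exponential"] = 3
    except (RuntimeError, ValueError) as exc:  # optimizer failure: candidate excluded
        logger.info("exponential ML-DFA candidate excluded: %s", exc)

    lowest = min(scores.values())
    supported = [m for m, s in scores.items() if s <= lowest + 2.0]
    # parsimony tie-break; "linear" sorts ahead of "logarithmic" at equal k
    best = min(supported, key=lambda m: (n_params[m], m != "linear", scores[m]))
    result.mldfa_best_model = best
    result.valid = best == "linear" and result.H is not None and result.H > 0
    return result


def smooth_hurst_series(H_t: np.ndarray, smoothing_factor: float = 0.3) -> np.ndarray:
    """Exponential smoothing s_t = lam*H_t + (1-lam)*s_{t-1}; NaNs are
    carried forward from the last smoothed value."""
    lam = smoothing_factor
    if not 0 < lam <= 1:
        raise ValueError(f"smoothing factor must be in (0, 1], got {lam}")
    h = np.asarray(H_t, dtype=float).ravel()
    if h.size == 0:
        raise ValueError("empty Hurst series")
    out = np.empty_like(h)
    prev = np.nan
    for i, v in enumerate(h):
        if np.isnan(v):
            out[i] = prev
        elif np.isnan(prev):
            out[i] = v
            prev = v
        else:
            prev = lam * v + (1 - lam) * prev
            out[i] = prev
    return out


def characterize_acf_spectrum(
    window, max_lag: int = 50, fit_band: tuple[float, float] = (0.5, 45.0)
) -> SpectralCharacterization:
    """Sample ACF/PACF plus log-log periodogram slope over the broadband
    range, with power-law constants from the same least-squares fits."""
    from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

    x = np.asarray(getattr(window, "samples", window), dtype=float).ravel()
    fs = float(getattr(window, "fs", 1.0))
    if np.var(x) == 0:
        raise ValueError("zero-variance window")
    if max_lag >= x.size:
        raise ValueError("max_lag must be below the window length")
    acf = sm_acf(x, nlags=max_lag, fft=True)
    pacf_nlags = min(max_lag, x.size // 2 - 1)
    pacf = sm_pacf(x, nlags=pacf_nlags, method="ld")

    freqs, power = signal.periodogram(x, fs=fs, detrend="constant")
    mask = (freqs >= fit_band[0]) & (freqs <= fit_band[1]) & (power > 0)
    lf, lp = np.log10(freqs[mask]), np.log10(power[mask])
    slope, icept = np.polyfit(lf, lp, 1)
    beta = -float(slope)
    B = float(10.0**icept)

    lags = np.arange(1, max_lag + 1)
    pos = acf[1:] > 0
    if pos.sum() >= 2:
        a_slope, a_icept = np.polyfit(np.log10(lags[pos]), np.log10(acf[1:][pos]), 1)
        alpha, C = -float(a_slope), float(10.0**a_icept)
    else:
        alpha, C = float("nan"), float("nan")

    return SpectralCharacterization(acf, pacf, beta, B, alpha, C)
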