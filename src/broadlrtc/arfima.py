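"""ARFIMA(p,d,q) fitting of analysis windows.

Two-stage scheme: the fractional-differencing parameter d = H - 0.5 comes
from the DFA Hurst estimate; the window is fractionally differenced by d
(fast FFT convolution of the binomial coefficients), its stationarity is
checked with an augmented Dickey-Fuller test, and an AR model is fitted to
the residual short-range-dependent process. Residual adequacy is assessed
with Ljung-Box and one-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

__all__ = [
    "ARFIMAFit",
    "frac_diff_coefficients",
    "fractional_difference",
    "fractional_integrate",
    "adf_stationarity_test",
    "select_order",
    "fit_ar",
    "residual_diagnostics",
    "fit_arfima_window",
    "pacf_identification",
]


@dataclass
class ARFIMAFit:
    """Estimated ARFIMA parameters and residual diagnostics for one window."""

    d: float | None
    p: int
    q: int
    phi: np.ndarray
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: float = float("nan")
    aic: float = float("nan")
    ljung_box_p: float = float("nan")
    ks_p: float = float("nan")
    adf_stationary: bool | None = None
    skip_reason: str | None = None

    @property
    def n_parameters(self) -> int:
        """d (when set) plus AR plus MA coefficients."""
        return int(self.d is not None) + len(self.phi) + len(self.theta)

    @property
    def residuals_adequate(self) -> bool:
        """Neither Ljung-Box nor KS rejects at 0.05."""
        return self.ljung_box_p >= 0.05 and self.ks_p >= 0.05


def frac_diff_coefficients(d: float, n: int) -> np.ndarray:
    """Binomial-expansion coefficients of (1-B)^d: b0=1, b_k = b_{k-1}(k-1-d)/k."""
    b = np.empty(n)
    b[0] = 1.0
    for k in range(1, n):
        b[k] = b[k - 1] * (k - 1 - d) / k
    return b


def fractional_difference(series: np.ndarray, d: float) -> np.ndarray:
    """(1-B)^d applied by FFT convolution, O(N log N).

    Type-II convention: the series is treated as zero before its start, so
    the output has the same length as the input. d=0 is the exact identity
    and d=1 reduces to the first difference with x0 retained.
    """
    x = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if d == 0:
        return x.copy()
    b = frac_diff_coefficients(d, x.size)
    return fftconvolve(x, b)[: x.size]


def fractional_integrate(series: np.ndarray, d: float) -> np.ndarray:
    """Inverse of :func:`fractional_difference`: applies (1-B)^-d."""
    return fractional_difference(series, -d)


def adf_stationarity_test(series: np.ndarray) -> tuple[float, float, bool]:
    """Augmented Dickey-Fuller unit-root test.

    Lag order selected by AIC up to floor((N-1)^(1/3)). Returns
    ``(statistic, p_value, stationary)`` where stationarity means the
    unit-root null is rejected at 0.05.
    """
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(series, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 samples for the ADF test")
    if np.ptp(x) == 0:
        raise ValueError("ADF test undefined for a constant series")
    maxlag = int(np.floor((x.size - 1) ** (1 / 3)))
    stat, p, *_ = adfuller(x, maxlag=maxlag, autolag="AIC")
    return float(stat), float(p), bool(p < 0.05)


def _ma_invertible(theta: np.ndarray) -> bool:
    if len(theta) == 0:
        return True
    # characteristic roots of z^q + theta_1 z^(q-1) + ... + theta_q inside unit circle
    roots = np.roots(np.r_[1.0, theta])
    return bool(np.all(np.abs(roots) < 1.0 - 1e-8))


def select_order(series: np.ndarray, p_max: int = 10) -> tuple[int, int]:
    """AIC order selection over ARMA(p, q), p in 1..p_max, q in 0..p-1.

    Candidates whose estimated MA polynomial is non-invertible are
    discarded (an invertible AR representation of higher order exists, so
    nothing is lost).
    """
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    from statsmodels.tsa.arima.model import ARIMA

    x = np.asarray(series, dtype=float).ravel()
    best: tuple[float, tuple[int, int]] | None = None
    failures = []
    for p in range(1, p_max + 1):
        for q in range(0, p):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    res = ARIMA(x, order=(p, 0, q), trend="n").fit()
            except Exception as exc:  # noqa: BLE001 — per-candidate log
                failures.append(((p, q), str(exc)))
                continue
            if q > 0 and not _ma_invertible(res.maparams):
                logger.info("ARMA(%d,%d) non-invertible; discarded", p, q)
                continue
            if best is None or res.aic < best[0]:
                best = (res.aic, (p, q))
    if best is None:
        raise RuntimeError(f"all ARMA candidates failed: {failures}")
    return best[1]


def fit_ar(series: np.ndarray, p: int) -> ARFIMAFit:
    """Conditional least-squares AR(p) fit (mean removed, no trend term).

    Sign convention: X_t - sum_i phi_i X_{t-i} = eps_t, so ``phi`` holds
    the coefficients as they appear on the autoregressive side.
    """
    from statsmodels.tsa.ar_model import AutoReg

    x = np.asarray(series, dtype=float).ravel()
    if x.size <= 3 * p:
        raise ValueError(f"series of {x.size} samples too short for AR({p})")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit AR to a constant series")
    res = AutoReg(x - x.mean(), lags=p, trend="n").fit()
    fit = ARFIMAFit(
        d=None,
        p=p,
        q=0,
        phi=np.asarray(res.params, dtype=float),
        sigma2=float(res.sigma2),
        aic=float(res.aic),
    )
    fit._residuals = np.asarray(res.resid, dtype=float)  # kept for diagnostics
    return fit


def residual_diagnostics(
    fit: ARFIMAFit, residuals: np.ndarray, lags: int = 20
) -> ARFIMAFit:
    """Ljung-Box (df reduced by the fitted AR order) and one-sample KS
    against a normal with the residuals' estimated mean and sd."""
    from statsmodels.stats.diagnostic import acorr_ljungbox

    r = np.asarray(residuals, dtype=float).ravel()
    if r.size <= lags:
        raise ValueError(f"{r.size} residuals insufficient for {lags} Ljung-Box lags")
    model_df = min(fit.p + fit.q, lags - 1)
    lb = acorr_ljungbox(r, lags=[lags], model_df=model_df)
    fit.ljung_box_p = float(lb["lb_pvalue"].iloc[0])
    fit.ks_p = float(stats.kstest(r, "norm", args=(r.mean(), r.std(ddof=1))).pvalue)
    return fit


def fit_arfima_window(
    window,
    p: int = 10,
    q: int = 0,
    taper: bool = True,
    run_adf: bool = True,
    diagnostics: bool = True,
    d: float | None = None,
) -> ARFIMAFit:
    """Full two-stage ARFIMA fit of one analysis window.

    d = H - 0.5 from DFA (H < 0.5 gives negative d, i.e. fractional
    integration; this is allowed and flagged only through the d value),
    then the raw window is fractionally differenced and AR(p) fitted.
    Pass a precomputed ``d`` to skip the internal DFA. Returns a fit with
    ``skip_reason`` set when DFA is degenerate.
    """
    from broadlrtc.dfa import estimate_hurst

    if q != 0:
        raise NotImplementedError("MA terms are handled via select_order only; use q=0")
    if d is None:
        dfa_res = estimate_hurst(window, taper=taper)
        if dfa_res.H is None:
            return ARFIMAFit(
                d=None, p=p, q=0, phi=np.full(p, np.nan), skip_reason="degenerate DFA"
            )
        d = dfa_res.H - 0.5
    x = np.asarray(getattr(window, "samples", window), dtype=float).ravel()
    z = fractional_difference(x - x.mean(), d)
    fit = fit_ar(z, p)
    fit.d = float(d)
    if run_adf:
        try:
            *_, fit.adf_stationary = adf_stationarity_test(z)
        except ValueError as exc:
            logger.warning("ADF skipped: %s", exc)
    if diagnostics:
        residual_diagnostics(fit, fit._residuals)
    return fit


def pacf_identification(
    series: np.ndarray, max_lag: int
) -> tuple[np.ndarray, float]:
    """Sample PACF (Levinson-Durbin) with the ±1.96/sqrt(N) significance band."""
    from statsmodels.tsa.stattools import pacf

    x = np.asarray(series, dtype=float).ravel()
    if np.var(x) == 0:
        raise ValueError("zero-variance series")
    values = pacf(x, nlags=max_lag, method="ld")
    return values, 1.96 / np.sqrt(x.size)
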