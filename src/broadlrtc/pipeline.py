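"""Study orchestration: per-participant feature extraction, grand
averages across participants, and report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from broadlrtc import classification as clf
from broadlrtc.arfima import fit_arfima_window
from broadlrtc.complementarity import compare_conditions, lag_analysis
from broadlrtc.dfa import estimate_hurst, smooth_hurst_series
from broadlrtc.erd import ALPHA_BAND, alpha_band_power, erd_percent
from broadlrtc.preprocessing import (
    EEGRecording,
    bandpass_filter,
    downsample,
    epoch_trials,
    notch_filter,
    sliding_windows,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "GrandAverage", "run_participant", "grand_average", "report"]


@dataclass
class StudyConfig:
    """Every stochastic stage carries an explicit seed; the config
    round-trips losslessly through YAML."""

    band: tuple[float, float] = (0.5, 45.0)
    notch: float | None = 50.0
    fs_out: float | None = 128.0
    trial_span: tuple[float, float] = (-3.0, 3.0)
    window_length: float = 2.0
    window_step: float = 0.1
    taper: bool = True
    smoothing_factor: float = 0.3
    ar_order: int = 10
    n_ar_features: int = 6
    erd_band: tuple[float, float] = ALPHA_BAND
    run_adf: bool = False
    folds: int = 10
    repeats: int = 10
    detection_consecutive: int = 1
    seed: int = 0
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    conditions: tuple[str, ...] = ("right", "left")
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("band", "trial_span", "erd_band", "channels", "conditions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GrandAverage:
    """Per-time mean/SD across participants, per condition and channel."""

    table: pd.DataFrame  # columns: condition, channel, t, mean, sd, n
    quantity: str


def preprocess(rec: EEGRecording, config: StudyConfig) -> EEGRecording:
    """Band-pass, notch and downsample according to the study config.

    Stages whose parameters no longer apply at the recording's sampling
    rate (e.g. a 50 Hz notch on 128 Hz synthetic data band-limited below
    Nyquist) are skipped with a log message.
    """
    if config.band is not None and config.band[1] < rec.fs / 2:
        rec = bandpass_filter(rec, *config.band)
    else:
        logger.info("band-pass skipped (edge at or above Nyquist)")
    if config.notch and config.notch < rec.fs / 2:
        rec = notch_filter(rec, config.notch)
    else:
        logger.info("notch skipped")
    if config.fs_out and config.fs_out < rec.fs:
        rec = downsample(rec, config.fs_out)
    return rec


def run_participant(
    rec: EEGRecording,
    config: StudyConfig | None = None,
    fit_arfima: bool = True,
    do_preprocess: bool = True,
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Extract the full per-window feature store for one participant.

    Returns a long-format frame with one row per trial x channel x window
    label, holding the smoothed Hurst exponent, the ARFIMA parameters
    (d, ar1..ar10) and the ERD. Failures are isolated per window (NaN
    features) and logged. Deterministic given the recording and config.
    """
    config = config or StudyConfig()
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if do_preprocess:
        rec = preprocess(rec, config)
    trials = epoch_trials(rec, config.trial_span)
    if trials.n_trials == 0:
        raise ValueError("no usable trials after epoching")
    t0 = float(trials.times[0])

    # resting baseline per channel for ERD
    rest = trials.select("rest")
    baselines = {}
    for ch in trials.channels:
        ci = trials.channel_index(ch)
        powers = [
            alpha_band_power(w, config.erd_band)
            for tr in range(rest.n_trials)
            for w in sliding_windows(
                rest.data[tr, ci], rest.fs, config.window_length, config.window_step, t0
            )
        ]
        if not powers:
            raise ValueError("no rest trials; ERD baseline undefined")
        baselines[ch] = float(np.mean(powers))

    rows = []
    for tr in range(trials.n_trials):
        cond = trials.conditions[tr]
        if conditions is not None and cond not in conditions:
            continue
        for ch in trials.channels:
            ci = trials.channel_index(ch)
            wins = sliding_windows(
                trials.data[tr, ci],
                trials.fs,
                config.window_length,
                config.window_step,
                t0,
                channel=ch,
            )
            H_raw = []
            for w in wins:
                res = estimate_hurst(w, taper=config.taper)
                H_raw.append(np.nan if res.H is None else res.H)
            H_raw = np.asarray(H_raw)
            H_smooth = smooth_hurst_series(H_raw, config.smoothing_factor)
            for w, H, H0 in zip(wins, H_smooth, H_raw):
                row = {
                    "trial": tr,
                    "condition": cond,
                    "channel": ch,
                    "t": round(w.t_end, 6),
                    "H": H,
                }
                if fit_arfima:
                    try:
                        # d reuses the raw (unsmoothed) per-window DFA estimate
                        fit = fit_arfima_window(
                            w,
                            p=config.ar_order,
                            taper=config.taper,
                            run_adf=config.run_adf,
                            diagnostics=config.run_adf,
                            d=None if np.isnan(H0) else float(H0) - 0.5,
                        )
                        row["d"] = fit.d
                        for i in range(config.ar_order):
                            row[f"ar{i + 1}"] = (
                                fit.phi[i] if i < len(fit.phi) else np.nan
                            )
                    except Exception as exc:  # noqa: BLE001 — isolate per window
                        logger.warning(
                            "ARFIMA failed (trial %d %s t=%.1f): %s", tr, ch, w.t_end, exc
                        )
                A = alpha_band_power(w, config.erd_band)
                row["band_power"] = A
                row["erd_percent"] = erd_percent(A, baselines[ch])
                rows.append(row)
    return pd.DataFrame(rows)


def _participant_trace(
    store: pd.DataFrame, quantity: str, condition: str, channel: str
) -> pd.Series:
    sub = store[(store["condition"] == condition) & (store["channel"] == channel)]
    return sub.groupby("t")[quantity].mean()


def grand_average(
    stores: list[pd.DataFrame],
    quantity: str = "H",
    conditions: tuple[str, ...] | None = None,
) -> tuple[GrandAverage, dict[tuple[str, str], np.ndarray]]:
    """Mean/SD across participants of per-participant trial means, plus
    Mann-Whitney movement-vs-rest masks with participants as units."""
    if len(stores) < 2:
        raise ValueError("grand average requires at least 2 participants")
    if conditions is None:
        conditions = tuple(pd.unique(stores[0]["condition"]))
    channels = sorted(stores[0]["channel"].unique())
    records, masks = [], {}
    for cond in conditions:
        for ch in channels:
            traces = [
                _participant_trace(s, quantity, cond, ch) for s in stores
            ]
            mat = pd.concat(traces, axis=1)
            if mat.isna().any().any() or any(
                not t.index.equals(traces[0].index) for t in traces
            ):
                raise ValueError("participants have mismatched window labels")
            arr = mat.to_numpy().T  # participants x times
            for t, m, s in zip(mat.index, arr.mean(axis=0), arr.std(axis=0)):
                records.append(
                    {
                        "condition": cond,
                        "channel": ch,
                        "t": t,
                        "mean": m,
                        "sd": s,
                        "n": len(stores),
                    }
                )
            if cond != "rest" and "rest" in conditions and len(stores) >= 3:
                rest_arr = np.stack(
                    [_participant_trace(s, quantity, "rest", ch).to_numpy() for s in stores]
                )
                _, mask = compare_conditions(arr, rest_arr)
                masks[(cond, ch)] = mask
    return GrandAverage(pd.DataFrame(records), quantity), masks


def classify_participant(
    store: pd.DataFrame,
    condition: str,
    feature_set: str,
    config: StudyConfig | None = None,
    seed=None,
) -> clf.ClassificationTimecourse:
    """Per-window LDA time course for one participant and feature set."""
    config = config or StudyConfig()
    times = np.sort(store["t"].unique())
    n_trials = store[store["condition"] == condition]["trial"].nunique()
    chance = clf.chance_threshold(n_trials)
    acc, acc_sd, sens, spec = [], [], [], []
    rng = np.random.default_rng(seed)
    for t in times:
        fm = clf.build_features(store, feature_set, t, condition, seed=rng)
        m = clf.train_eval_lda(fm, config.folds, config.repeats, seed=rng)
        acc.append(m["accuracy"])
        acc_sd.append(m["accuracy_sd"])
        sens.append(m["sensitivity"])
        spec.append(m["specificity"])
    return clf.ClassificationTimecourse(
        times,
        np.asarray(acc),
        np.asarray(acc_sd),
        np.asarray(sens),
        np.asarray(spec),
        chance,
        n_trials,
    )


def report(
    timecourses: dict[tuple[int, str, str], clf.ClassificationTimecourse],
    erd_traces: np.ndarray | None = None,
    lrtc_traces: np.ndarray | None = None,
    min_consecutive: int = 1,
) -> dict[str, pd.DataFrame]:
    """Summary tables: per-feature-set peak metrics (mean +- SD across
    participants), per-participant detection times, and optionally the
    ERD-LRTC correlation/lag summary.

    ``timecourses`` is keyed by (participant, condition, feature_set).
    Peak accuracy is the per-participant maximum over window labels.
    """
    peak_rows, det_rows = [], []
    for (pid, cond, fset), tc in timecourses.items():
        i = int(np.argmax(tc.accuracy))
        peak_rows.append(
            {
                "participant": pid,
                "condition": cond,
                "feature_set": fset,
                "peak_accuracy": tc.accuracy[i],
                "sensitivity": tc.sensitivity[i],
                "specificity": tc.specificity[i],
            }
        )
        det_rows.append(
            {
                "participant": pid,
                "condition": cond,
                "feature_set": fset,
                "detection_time": tc.detection_time(min_consecutive),
                "chance_threshold": tc.chance,
            }
        )
    peaks = pd.DataFrame(peak_rows)
    summary = (
        peaks.groupby(["feature_set", "condition"])
        .agg(
            accuracy_mean=("peak_accuracy", "mean"),
            accuracy_sd=("peak_accuracy", "std"),
            sensitivity_mean=("sensitivity", "mean"),
            specificity_mean=("specificity", "mean"),
        )
        .reset_index()
    )
    out = {"summary": summary, "detection_times": pd.DataFrame(det_rows)}
    if erd_traces is not None and lrtc_traces is not None:
        la = lag_analysis(erd_traces, lrtc_traces)
        out["erd_lrtc"] = pd.DataFrame(
            {
                "r": la.r,
                "best_lag": la.best_lag,
            }
        )
    return out
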