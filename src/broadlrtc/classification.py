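"""Per-window LDA movement-vs-rest classification.

One independent LDA per sliding-window label, trained on the movement
trials of one condition against an equal number of randomly drawn rest
trials, evaluated with repeated stratified k-fold cross-validation.
Features are z-scored inside training folds only (H lives near 0.5-1
while ERD spans +-100, so raw scales are wildly disparate). Significance
of accuracy against chance uses the exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FEATURE_SETS",
    "FeatureMatrix",
    "ClassificationTimecourse",
    "build_features",
    "train_eval_lda",
    "chance_threshold",
    "detection_time",
]

# feature kind -> (column, channels); channel choices follow the study design:
# H on all three motor channels, ERD on C3/C4 only, ARFIMA = d + AR1..AR6 x 3.
_LRTC_CHANNELS = ("C3", "Cz", "C4")
_ERD_CHANNELS = ("C3", "C4")
_ARFIMA_COLUMNS = ("d", "ar1", "ar2", "ar3", "ar4", "ar5", "ar6")

FEATURE_SETS = ("lrtc", "erd", "arfima", "lrtc+erd", "arfima+erd")


@dataclass
class FeatureMatrix:
    """Balanced per-window design matrix: movement rows then rest rows."""

    X: np.ndarray
    y: np.ndarray  # 1 = movement, 0 = rest
    feature_names: list[str]
    t: float
    rest_trials_used: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ClassificationTimecourse:
    times: np.ndarray
    accuracy: np.ndarray
    accuracy_sd: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    chance: float
    n_trials: int

    def detection_time(self, min_consecutive: int = 1) -> float | None:
        return detection_time(
            self.times, self.accuracy, self.chance, min_consecutive
        )


def _columns_for(feature_set: str) -> list[tuple[str, str]]:
    fs = feature_set.lower()
    if fs not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}")
    cols: list[tuple[str, str]] = []
    for part in fs.split("+"):
        if part == "lrtc":
            cols += [("H", ch) for ch in _LRTC_CHANNELS]
        elif part == "erd":
            cols += [("erd_percent", ch) for ch in _ERD_CHANNELS]
        elif part == "arfima":
            cols += [(c, ch) for ch in _LRTC_CHANNELS for c in _ARFIMA_COLUMNS]
    return cols


def build_features(
    store: pd.DataFrame,
    feature_set: str,
    t: float,
    condition: str,
    seed=None,
) -> FeatureMatrix:
    """Assemble the balanced design matrix for one window label.

    ``store`` is a long-format per-window feature table with columns
    trial, condition, channel, t plus the feature columns (H, d, ar1..,
    erd_percent). Rest rows are drawn at random (without replacement when
    possible) to match the movement trial count; trials with any missing
    requested feature are dropped with their rate implicitly visible in
    the row count.
    """
    cols = _columns_for(feature_set)
    sub = store[np.isclose(store["t"], t)]
    if sub.empty:
        raise ValueError(f"no rows at window label t={t}")

    def pivot(condition_name: str) -> pd.DataFrame:
        rows = sub[sub["condition"] == condition_name]
        wide = rows.pivot_table(index="trial", columns="channel", aggfunc="first")
        out = pd.DataFrame(index=wide.index)
        for col, ch in cols:
            out[f"{col}_{ch}"] = wide[(col, ch)] if (col, ch) in wide else np.nan
        return out.dropna()

    move = pivot(condition)
    rest = pivot("rest")
    if move.empty or rest.empty:
        raise ValueError(f"no usable trials for {condition!r} vs rest at t={t}")
    rng = np.random.default_rng(seed)
    n = len(move)
    replace = len(rest) < n
    picked = rng.choice(rest.index.to_numpy(), size=n, replace=replace)
    rest = rest.loc[picked]
    X = np.vstack([move.to_numpy(), rest.to_numpy()])
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return FeatureMatrix(X, y, [f"{c}_{ch}" for c, ch in cols], t, picked)


def train_eval_lda(
    features: FeatureMatrix,
    folds: int = 10,
    repeats: int = 10,
    seed=None,
) -> dict[str, float]:
    """Repeated stratified k-fold LDA; metrics in percent.

    Sensitivity is movement recall, specificity is rest recall. LDA uses
    the least-squares solver with automatic shrinkage toward the diagonal
    so near-singular pooled covariances stay estimable.
    """
    X, y = features.X, features.y
    n_per_class = min(np.bincount(y))
    if folds > n_per_class:
        raise ValueError(f"{folds} folds exceed the {n_per_class} samples per class")
    rng = np.random.default_rng(seed)
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=int(rng.integers(2**31))
    )
    accs, sens, specs = [], [], []
    for train, test in cv.split(X, y):
        clf = make_pipeline(
            StandardScaler(),
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
        )
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        accs.append(np.mean(pred == truth))
        if (truth == 1).any():
            sens.append(np.mean(pred[truth == 1] == 1))
        if (truth == 0).any():
            specs.append(np.mean(pred[truth == 0] == 0))
    return {
        "accuracy": 100 * float(np.mean(accs)),
        "accuracy_sd": 100 * float(np.std(accs)),
        "sensitivity": 100 * float(np.mean(sens)),
        "specificity": 100 * float(np.mean(specs)),
    }


def chance_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Smallest accuracy (percent) whose binomial tail under chance
    (success probability 0.5) falls below ``alpha``.

    Capped at 100% when even a perfect score is not significant (tiny n).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    k = np.arange(n_trials + 2)
    tail = stats.binom.sf(k - 1, n_trials, 0.5)  # P[X >= k]
    crossing = np.nonzero(tail < alpha)[0]
    k_star = min(int(crossing[0]), n_trials)
    return 100.0 * k_star / n_trials


def detection_time(
    times: np.ndarray,
    accuracy: np.ndarray,
    threshold: float,
    min_consecutive: int = 1,
) -> float | None:
    """Earliest window label where accuracy strictly exceeds the chance
    threshold for ``min_consecutive`` consecutive windows; None if never."""
    times = np.asarray(times, dtype=float)
    acc = np.asarray(accuracy, dtype=float)
    above = acc > threshold
    k = max(1, int(min_consecutive))
    for i in range(above.size - k + 1):
        if above[i : i + k].all():
            return float(times[i])
    return None
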