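import numpy as np
import pytest

from broadlrtc.pipeline import StudyConfig, run_participant
from broadlrtc.synth import SyntheticConfig, synthesize_movement_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_dfa(x, box_sizes):
    """Brute-force triple-loop DFA reference (independent of the package
    implementation): integrate, least-squares detrend per box, RMS,
    averaged over the forward and time-reversed series."""
    x = np.asarray(x, dtype=float)
    N = x.size
    per_direction = []
    for direction in (x, x[::-1]):
        prof = np.cumsum(direction - np.mean(direction))
        Fs = []
        for n in box_sizes:
            nb = N // n
            sq = 0.0
            cnt = 0
            for b in range(nb):
                seg = prof[b * n : (b + 1) * n]
                t = np.arange(n, dtype=float)
                A = np.vstack([t, np.ones(n)]).T
                coef, *_ = np.linalg.lstsq(A, seg, rcond=None)
                resid = seg - A @ coef
                sq += float(np.sum(resid**2))
                cnt += n
            Fs.append(np.sqrt(sq / cnt))
        per_direction.append(np.asarray(Fs))
    return 0.5 * (per_direction[0] + per_direction[1])


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic participant, 6 trials per condition, moderate alpha."""
    cfg = SyntheticConfig(
        n_participants=1,
        n_trials_per_condition=6,
        d_baseline=0.05,
        d_peak=0.35,
        d_ramp_window=(-1.0, 0.0),
        alpha_amplitude=1.5,
        alpha_suppression=0.4,
        erd_ramp_window=(-0.5, 0.5),
        seed=77,
    )
    recs, truths = synthesize_movement_dataset(cfg)
    return cfg, recs[0], truths[0]


@pytest.fixture(scope="session")
def movement_store(small_dataset):
    """Full feature store (H, ARFIMA params, ERD) for the small dataset."""
    _, rec, _ = small_dataset
    return run_participant(rec, StudyConfig(), fit_arfima=True)
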