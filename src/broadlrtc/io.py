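"""Plain-text I/O for recordings, events and feature stores.

Recordings are stored as TSV matrices (one column per channel) with the
sampling rate in a ``# fs=<Hz>`` header comment; events as a TSV with
columns onset_seconds, condition. Everything round-trips losslessly
enough for a 128 Hz pipeline (full float precision is written).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from broadlrtc.preprocessing import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_ground_truth",
]


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.signal.T, delimiter="\t", fmt="%.10g")
    if rec.events:
        write_events(rec.events, path.with_suffix(".events.tsv"))


def read_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        channels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    events_path = path.with_suffix(".events.tsv")
    events = read_events(events_path) if events_path.exists() else []
    return EEGRecording(data.T, fs, channels, events)


def write_events(events: list[tuple[float, str]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["onset_seconds", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path: str | Path) -> list[tuple[float, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.onset_seconds), str(r.condition)) for r in df.itertuples()]


def write_ground_truth(truth, path: str | Path) -> None:
    """Long-format TSV of the programmed per-trial dynamics."""
    frames = []
    for trial, (cond, onset) in enumerate(zip(truth.conditions, truth.onsets)):
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial,
                    "condition": cond,
                    "onset_seconds": onset,
                    "time": truth.times,
                    "d": truth.d_profiles[trial],
                    "alpha_scale": truth.alpha_scales[trial],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
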