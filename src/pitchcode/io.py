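"""Plain-text and WAV I/O for stimuli, annotations, tracks and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


def write_wav(path: str | Path, waveform: np.ndarray, rate_hz: float) -> None:
    """Write a mono float32 WAV."""
    wavfile.write(str(path), int(round(rate_hz)), np.asarray(waveform, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV as float64 (integer PCM scaled to [-1, 1])."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), float(rate)


def write_annotations_tsv(path: str | Path, annotations: list[tuple[float, str]]) -> None:
    pd.DataFrame(annotations, columns=["onset_s", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations_tsv(path: str | Path) -> list[tuple[float, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["onset_s"].astype(float), df["label"].astype(str)))


def write_track_tsv(path: str | Path, times_s: np.ndarray, values: np.ndarray,
                    value_name: str = "value") -> None:
    pd.DataFrame({"time_s": times_s, value_name: values}).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_tsv(path: str | Path, matrix: np.ndarray,
                     row_names: list[str] | None = None) -> None:
    df = pd.DataFrame(np.asarray(matrix))
    if row_names is not None:
        df.index = row_names
    df.to_csv(path, sep="\t", header=False)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
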