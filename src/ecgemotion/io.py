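"""Reading, writing and windowing of single-lead ECG sample streams.

ECG recordings are exchanged as plain text, one sample value per line (a
single-column CSV with an optional header is also accepted).  The sampling
rate is supplied out of band — it is not stored in the sample file — with a
default of 1000 Hz.  A labeled collection of windows is described by a
manifest CSV with columns ``file,subject,timestamp,label``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FS = 1000.0

__all__ = [
    "DEFAULT_FS",
    "ECGWindow",
    "read_window",
    "write_window",
    "read_manifest",
    "write_manifest",
    "window_stream",
]


@dataclasses.dataclass(frozen=True)
class ECGWindow:
    """One fixed-length single-lead ECG segment; the pipeline's unit of work.

    Parameters
    ----------
    samples : ndarray
        Signal values x[n], n = 0..N-1, in arbitrary signal units.
    fs : float
        Sampling rate in Hz.
    subject_id, label : str, optional
        Provenance and emotion-class annotation carried through the pipeline.
    t0 : float, optional
        Start time of the window in seconds within its source recording.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    label: str | None = None
    t0: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("ECG window needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECG window contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the window start."""
        return np.arange(self.n_samples) / self.fs

    def replace(self, samples: np.ndarray) -> "ECGWindow":
        """Return a copy of this window with new sample values (same metadata)."""
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))


def read_window(
    path: str | Path,
    fs: float = DEFAULT_FS,
    *,
    subject_id: str | None = None,
    label: str | None = None,
) -> ECGWindow:
    """Read a plain-text sample file (one value per line) into an :class:`ECGWindow`.

    Lines that are empty or a non-numeric header (first line only) are skipped;
    any other non-numeric line raises a parse error naming the line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip().rstrip(",")
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1:  # tolerate a single-column CSV header
                    continue
                raise ValueError(
                    f"{path}: non-numeric sample on line {lineno}: {text!r}"
                ) from None
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    return ECGWindow(np.asarray(values), fs, subject_id=subject_id, label=label)


def write_window(window: ECGWindow, path: str | Path, fmt: str = "%.10g") -> None:
    """Write one sample per line; ``fmt`` controls the text precision."""
    np.savetxt(path, window.samples, fmt=fmt)


MANIFEST_COLUMNS = ["file", "subject", "timestamp", "label"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV (columns file,subject,timestamp,label)."""
    df = pd.read_csv(path, dtype={"file": str, "subject": str, "label": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["file"].duplicated().any():
        dupes = df.loc[df["file"].duplicated(), "file"].tolist()
        raise ValueError(f"manifest has duplicate file paths: {dupes}")
    return df[MANIFEST_COLUMNS]


def write_manifest(records: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(records))
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def window_stream(
    samples: Sequence[float],
    fs: float,
    duration: float,
    stride: float,
    **meta,
) -> list[ECGWindow]:
    """Slice a continuous recording into fixed-length windows.

    Windows are half-open sample ranges ``[k*stride*fs, k*stride*fs + duration*fs)``;
    a trailing partial window is discarded.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    samples = np.asarray(samples, dtype=float)
    n_win = int(round(duration * fs))
    n_step = int(round(stride * fs))
    if n_win > samples.size:
        raise ValueError("duration exceeds signal length")
    windows = []
    start = 0
    while start + n_win <= samples.size:
        windows.append(
            ECGWindow(samples[start : start + n_win], fs, t0=start / fs, **meta)
        )
        start += n_step
    return windows
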