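"""PQRST fiducial detection on a pre-processed single-lead ECG window.

R peaks are found first, as local maxima exceeding a fraction of a robust
amplitude estimate (the 99th percentile of the signal), with a refractory
period that keeps only the taller of two conflicting candidates.  The
remaining landmarks are then localized per beat by local extremum search in
physiologically-sized windows around each R peak:

* Q — minimum in the ``q_search`` seconds before R
* S — minimum in the ``s_search`` seconds after R
* P — maximum between ``p_search`` seconds before R and the Q point
* T — maximum between the S point and ``t_search`` seconds after R

Beats whose search ranges cross the window bounds or a neighbouring R peak
are dropped rather than padded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .io import ECGWindow

__all__ = ["SearchWindows", "BeatAnnotations", "detect_r_peaks", "annotate_beats"]


@dataclasses.dataclass(frozen=True)
class SearchWindows:
    """Per-wave search extents in seconds relative to the R peak."""

    p_search: float = 0.28  # P sought up to this far before R (down to Q)
    q_search: float = 0.06
    s_search: float = 0.08
    t_search: float = 0.36  # T sought from S out to this far after R


@dataclasses.dataclass(frozen=True)
class BeatAnnotations:
    """Per-beat P/Q/R/S/T sample indices (0-based), beats ordered by R."""

    p_idx: np.ndarray
    q_idx: np.ndarray
    r_idx: np.ndarray
    s_idx: np.ndarray
    t_idx: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=int)
            for a in (self.p_idx, self.q_idx, self.r_idx, self.s_idx, self.t_idx)
        ]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise ValueError("annotation arrays must have equal length")
        for name, a in zip("pqrst", arrays):
            object.__setattr__(self, f"{name}_idx", a)
        stacked = np.stack(arrays)
        if n and not np.all(np.diff(stacked, axis=0) > 0):
            raise ValueError("landmarks must satisfy p < q < r < s < t per beat")
        if n > 1 and not np.all(np.diff(arrays[2]) > 0):
            raise ValueError("R indices must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.r_idx.size)


def detect_r_peaks(
    window: ECGWindow,
    min_rr: float = 0.3,
    rel_threshold: float = 0.5,
) -> np.ndarray:
    """Detect R peaks: thresholded local maxima with a refractory period.

    The amplitude threshold is ``rel_threshold`` times the 99th percentile of
    the signal (robust against isolated spikes).  Returns sample indices;
    empty when the signal has no local maxima.  Raises when local maxima exist
    but all are non-positive (inverted-polarity input).
    """
    if min_rr <= 0:
        raise ValueError("min_rr must be positive")
    x = window.samples
    candidates, _ = sps.find_peaks(x)
    if candidates.size == 0:
        return np.asarray([], dtype=int)
    if np.max(x[candidates]) <= 0:
        raise ValueError("no positive R peaks (check signal polarity)")
    threshold = rel_threshold * np.percentile(x, 99)
    distance = max(1, int(round(min_rr * window.fs)))
    peaks, _ = sps.find_peaks(x, height=threshold, distance=distance)
    return peaks.astype(int)


def _argext(x: np.ndarray, lo: int, hi: int, take_max: bool) -> int:
    seg = x[lo:hi]
    return lo + int(np.argmax(seg) if take_max else np.argmin(seg))


def annotate_beats(
    window: ECGWindow,
    r_peaks,
    search: SearchWindows = SearchWindows(),
) -> BeatAnnotations:
    """Localize P, Q, S, T around each detected R peak.

    Beats whose search ranges fall outside the window or overlap a
    neighbouring R peak are dropped; at least two fully-annotated beats are
    required.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise ValueError("insufficient beats: need at least 2 R peaks")
    x = window.samples
    fs = window.fs
    n = x.size
    p_n = int(round(search.p_search * fs))
    q_n = int(round(search.q_search * fs))
    s_n = int(round(search.s_search * fs))
    t_n = int(round(search.t_search * fs))

    beats = []
    for i, r in enumerate(r_peaks):
        lo = r - p_n
        hi = r + t_n
        if lo < 0 or hi >= n:
            continue
        if i > 0 and lo <= r_peaks[i - 1]:
            continue
        if i + 1 < r_peaks.size and hi >= r_peaks[i + 1]:
            continue
        q = _argext(x, r - q_n, r, take_max=False)
        s = _argext(x, r + 1, r + s_n + 1, take_max=False)
        p = _argext(x, lo, q, take_max=True)
        t = _argext(x, s + 1, hi + 1, take_max=True)
        if not (p < q < r < s < t):
            continue
        beats.append((p, q, r, s, t))

    if len(beats) < 2:
        raise ValueError("insufficient beats: fewer than 2 fully annotated beats")
    arr = np.asarray(beats, dtype=int)
    return BeatAnnotations(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
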