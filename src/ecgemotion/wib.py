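"""Within-beat (WIB) interval statistics.

For every annotated beat three intra-beat intervals are measured from the
fiducial peaks (peak-to-peak, not onset-to-onset): PR = R - P, QRS = S - Q and
ST = T - S, all in milliseconds.  Five statistics — min, max, sample SD, mean
and median — are computed across beats for each interval, giving 15 features
named ``min_pr`` ... ``median_qrs``.
"""

from __future__ import annotations

import numpy as np

from .pqrst import BeatAnnotations

__all__ = ["WIB_FEATURE_NAMES", "interval_series", "wib_features"]

INTERVALS = ("pr", "st", "qrs")
STATS = ("min", "max", "sd", "mean", "median")

WIB_FEATURE_NAMES = [f"{stat}_{iv}" for iv in INTERVALS for stat in STATS]


def interval_series(ann: BeatAnnotations, fs: float) -> dict[str, np.ndarray]:
    """Per-beat PR, ST and QRS intervals in ms."""
    if ann.n_beats < 2:
        raise ValueError("insufficient beats: need at least 2 annotated beats")
    to_ms = 1000.0 / fs
    return {
        "pr": (ann.r_idx - ann.p_idx) * to_ms,
        "st": (ann.t_idx - ann.s_idx) * to_ms,
        "qrs": (ann.s_idx - ann.q_idx) * to_ms,
    }


def _stats(values: np.ndarray) -> dict[str, float]:
    if values.size < 2:
        raise ValueError("insufficient beats: need at least 2 interval values")
    return {
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "sd": float(np.std(values, ddof=1)),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
    }


def wib_features(intervals: dict[str, np.ndarray]) -> dict[str, float]:
    """The 15 exported WIB features in canonical order."""
    out: dict[str, float] = {}
    for iv in INTERVALS:
        stats = _stats(np.asarray(intervals[iv], dtype=float))
        for stat in STATS:
            out[f"{stat}_{iv}"] = stats[stat]
    return out
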