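"""Heart-rate-variability analysis from detected R peaks.

Fourteen canonical features are exported per window, in three groups:

* time domain — ``sdnn`` (sample SD of NN intervals, ms), ``mn_nn`` (mean NN,
  ms), ``rmssd`` (root mean square of successive differences, ms), ``m_nn``
  (maximum NN, ms), ``nn50`` (count of successive differences strictly greater
  than 50 ms) and ``pnn50`` (nn50 as a percentage of successive-difference
  pairs);
* frequency domain — band powers (ms^2) of the interpolated HRV series in the
  VLF (0.0033-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands:
  ``lf``, ``lfnu``, ``lf_hf``, ``total_power``, ``hfnu``, ``vlf``.  ``hf`` is
  computed for the ratios but not exported, keeping the block at 14 features;
* geometric (Poincare) — ``sd1`` and ``sd2``, the dispersions of consecutive
  NN pairs perpendicular to and along the identity line.

The HRV series is built by cubic-spline interpolation of the NN intervals at
their cumulative times, resampled uniformly at 4 Hz (standard practice).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.interpolate import CubicSpline

from .pqrst import BeatAnnotations
from .spectral import WelchConfig, band_power, welch_psd

logger = logging.getLogger(__name__)

__all__ = [
    "RRSeries",
    "HRV_FEATURE_NAMES",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
    "rr_from_annotations",
    "rr_from_peaks",
    "interpolate_hrv",
    "hrv_time_features",
    "hrv_frequency_features",
    "hrv_geometric_features",
    "hrv_features",
]

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

HRV_FEATURE_NAMES = [
    "sdnn", "mn_nn", "rmssd", "m_nn", "nn50", "pnn50",
    "lf", "lfnu", "lf_hf", "total_power", "hfnu", "vlf",
    "sd1", "sd2",
]

DEFAULT_RESAMPLE_HZ = 4.0


@dataclasses.dataclass(frozen=True)
class RRSeries:
    """NN (R-R) intervals in ms and their cumulative times in seconds."""

    rr_intervals: np.ndarray  # ms
    rr_times: np.ndarray  # s, cumulative sums of the intervals

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_intervals, dtype=float)
        t = np.asarray(self.rr_times, dtype=float)
        if rr.size != t.size:
            raise ValueError("intervals and times must have equal length")
        if np.any(rr <= 0):
            raise ValueError("all R-R intervals must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("cumulative times must be strictly increasing")
        object.__setattr__(self, "rr_intervals", rr)
        object.__setattr__(self, "rr_times", t)

    @property
    def n_intervals(self) -> int:
        return int(self.rr_intervals.size)


def rr_from_peaks(r_idx, fs: float) -> RRSeries:
    """NN series from R-peak sample indices."""
    r_idx = np.asarray(r_idx, dtype=float)
    if r_idx.size < 3:
        raise ValueError("insufficient beats for HRV: need at least 3 R peaks")
    if np.any(np.diff(r_idx) <= 0):
        raise ValueError("R indices must be strictly increasing")
    rr_ms = np.diff(r_idx) / fs * 1000.0
    rr_times = np.cumsum(rr_ms) / 1000.0
    return RRSeries(rr_ms, rr_times)


def rr_from_annotations(ann: BeatAnnotations, fs: float) -> RRSeries:
    return rr_from_peaks(ann.r_idx, fs)


def interpolate_hrv(
    rr: RRSeries, resample_hz: float = DEFAULT_RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline HRV series on a uniform grid spanning the NN times.

    Returns ``(t_grid, values_ms)``.
    """
    if rr.n_intervals < 3:
        raise ValueError("insufficient beats for HRV: need at least 3 intervals")
    span = rr.rr_times[-1] - rr.rr_times[0]
    n_grid = int(math.floor(span * resample_hz)) + 1
    if span <= 0 or n_grid < 4:
        raise ValueError("degenerate time span for HRV interpolation")
    t_grid = rr.rr_times[0] + np.arange(n_grid) / resample_hz
    spline = CubicSpline(rr.rr_times, rr.rr_intervals)
    return t_grid, spline(t_grid)


def hrv_time_features(rr: RRSeries) -> dict[str, float]:
    x = rr.rr_intervals
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.diff(x)
    nn50 = int(np.sum(np.abs(diffs) > 50.0))  # strictly more than 50 ms
    return {
        "sdnn": float(np.std(x, ddof=1)),
        "mn_nn": float(np.mean(x)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "m_nn": float(np.max(x)),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / diffs.size,
    }


def hrv_frequency_features(
    hrv_series: np.ndarray,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    cfg: WelchConfig = WelchConfig(),
) -> dict[str, float]:
    """VLF/LF/HF band powers of the mean-removed HRV series (all in ms^2).

    The Welch segment length is shrunk to the series length when the series
    is shorter than the configured ``lseg``.  ``hf`` is included in the
    returned mapping for API use even though the exported vector omits it;
    ``lf_hf`` is NaN when hf is zero.
    """
    x = np.asarray(hrv_series, dtype=float)
    if x.size < cfg.lseg:
        cfg = WelchConfig(lseg=x.size, lover=x.size // 2, window_fn=cfg.window_fn)
        logger.info("HRV series shorter than lseg; shrunk to %d samples", x.size)
    psd = welch_psd(x - np.mean(x), resample_hz, cfg)
    vlf = band_power(psd, *VLF_BAND)
    lf = band_power(psd, *LF_BAND)
    hf = band_power(psd, *HF_BAND)
    if lf + hf > 0:
        lfnu = 100.0 * lf / (lf + hf)
        hfnu = 100.0 * hf / (lf + hf)
    else:
        lfnu = hfnu = 0.0
    if hf > 0:
        lf_hf = lf / hf
    else:
        lf_hf = float("nan")
        logger.warning("HF power is zero; lf_hf reported as NaN")
    return {
        "lf": lf,
        "lfnu": lfnu,
        "lf_hf": lf_hf,
        "total_power": vlf + lf + hf,
        "hfnu": hfnu,
        "vlf": vlf,
        "hf": hf,
    }


def hrv_geometric_features(rr: RRSeries) -> dict[str, float]:
    """Poincare SD1/SD2 from successive NN differences and sums (sample SD)."""
    x = rr.rr_intervals
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    d = x[1:] - x[:-1]
    s = x[1:] + x[:-1]
    return {
        "sd1": float(np.std(d, ddof=1) / math.sqrt(2.0)),
        "sd2": float(np.std(s, ddof=1) / math.sqrt(2.0)),
    }


def hrv_features(
    rr: RRSeries,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    cfg: WelchConfig = WelchConfig(),
) -> dict[str, float]:
    """The 14 exported HRV features in canonical order."""
    feats = {}
    feats.update(hrv_time_features(rr))
    _, series = interpolate_hrv(rr, resample_hz)
    freq = hrv_frequency_features(series, resample_hz, cfg)
    freq.pop("hf")
    feats.update(freq)
    feats.update(hrv_geometric_features(rr))
    return {name: feats[name] for name in HRV_FEATURE_NAMES}
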