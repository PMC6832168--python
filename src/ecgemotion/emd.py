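"""Empirical mode decomposition and Hilbert-based EMD features.

The decomposition is the classic sifting procedure: cubic-spline upper and
lower envelopes are drawn through the local maxima and minima (with mirror
extension of the end extrema to tame boundary splines), the envelope mean is
subtracted, and the step is iterated until the Cauchy criterion

    SD = sum((h_prev - h)^2) / sum(h_prev^2) < sift_tol

or an iteration cap is reached.  Each extracted intrinsic mode function (IMF)
is subtracted from the running residual and sifting restarts on the residual
until it is monotone (fewer than four extrema) or the IMF budget is spent.
The residual is maintained by exact subtraction, so IMFs + residual always
reconstruct the input to machine precision.

Four features are taken from each of the first six IMFs (24 in total):

* ``spec_p_i``   — time-domain power, the mean of squared samples;
* ``spec_pf_i``  — frequency-domain power, the full-range trapezoidal
  integral of the IMF's Welch PSD;
* ``mean_if_i``  — mean instantaneous frequency (Hz) from the phase
  derivative of the Hilbert analytic signal, averaged over the interior
  90% of samples (5% trimmed from each edge);
* ``ins_p_i``    — power of the mean-removed instantaneous-frequency series.

Missing IMF slots (signals that decompose into fewer than six modes) are
zero-filled so the block length is always 24.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .io import ECGWindow
from .spectral import PSD, WelchConfig, band_power, welch_psd

logger = logging.getLogger(__name__)

__all__ = [
    "IMFSet",
    "EMD_FEATURE_NAMES",
    "EMD_WELCH_DEFAULT",
    "emd_decompose",
    "time_power",
    "instantaneous_frequency",
    "emd_features",
]

N_IMFS_EXPORTED = 6

EMD_FEATURE_NAMES = (
    [f"spec_p_{i}" for i in range(1, 7)]
    + [f"spec_pf_{i}" for i in range(1, 7)]
    + [f"mean_if_{i}" for i in range(1, 7)]
    + [f"ins_p_{i}" for i in range(1, 7)]
)

#: Sentinel meaning "one full-length untapered segment" (see emd_features).
EMD_WELCH_DEFAULT = None


@dataclasses.dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs (highest frequency first) and the final residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapse)."""
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema, mirror-extended at the ends."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    n_mirror = min(2, idx.size - 1)
    # mirror extrema about the first/last sample so the spline does not swing
    left_t = 2 * 0.0 - t[1 : 1 + n_mirror][::-1]
    left_v = v[1 : 1 + n_mirror][::-1]
    right_t = 2 * (n - 1) - t[-1 - n_mirror : -1][::-1]
    right_v = v[-1 - n_mirror : -1][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n, dtype=float))


def emd_decompose(
    window: ECGWindow | np.ndarray,
    max_imfs: int = 8,
    sift_tol: float = 0.2,
    max_sift_iters: int = 100,
) -> IMFSet:
    """Decompose a signal into IMFs by classic envelope sifting."""
    x = window.samples if isinstance(window, ECGWindow) else np.asarray(window, float)
    if x.size < 16:
        raise ValueError("signal too short for EMD (need at least 16 samples)")
    residual = x.copy()
    imfs: list[np.ndarray] = []

    maxima, minima = _local_extrema(residual)
    if maxima.size + minima.size < 4:
        logger.info("fewer than 4 extrema; returning input as residual")
        return IMFSet([], residual)

    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2 or maxima.size + minima.size < 4:
            break  # residual is (near) monotone
        h = residual.copy()
        for _ in range(max_sift_iters):
            mx, mn = _local_extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_next = h - mean_env
            denom = float(np.sum(h * h))
            if denom == 0.0:
                h = h_next
                break
            sd = float(np.sum((h - h_next) ** 2)) / denom
            h = h_next
            if sd < sift_tol:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs, residual)


def time_power(samples) -> float:
    """Mean of squared samples."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(x * x))


def instantaneous_frequency(samples, fs: float) -> np.ndarray:
    """Instantaneous frequency (Hz) of a narrowband signal, length N-1.

    Computed as the finite-difference derivative of the unwrapped analytic
    phase divided by 2*pi.  Downstream statistics should exclude ~5% of
    samples at each edge, where the Hilbert transform is unreliable.
    """
    x = np.asarray(samples, dtype=float)
    if not np.any(x):
        raise ValueError("undefined phase: all-zero input")
    phase = np.unwrap(np.angle(hilbert(x)))
    return np.diff(phase) * fs / (2.0 * np.pi)


def _interior(series: np.ndarray, edge_fraction: float = 0.05) -> np.ndarray:
    k = int(np.floor(edge_fraction * series.size))
    return series[k : series.size - k] if k > 0 else series


def emd_features(
    imfset: IMFSet,
    fs: float,
    cfg: WelchConfig | None = EMD_WELCH_DEFAULT,
    *,
    ins_p_demean: bool = True,
) -> dict[str, float]:
    """The 24 exported EMD features in canonical order (zero-fill past n_imfs).

    With ``cfg=None`` (the default) the IMF spectra are estimated by Welch
    with a single untapered full-length segment — slow IMFs span only a few
    cycles per window, and this choice gives the frequency resolution and
    exact per-segment Parseval balance needed for the band integral
    ``spec_pf`` to agree with the time-domain power ``spec_p``.
    """
    spec_p = np.zeros(N_IMFS_EXPORTED)
    spec_pf = np.zeros(N_IMFS_EXPORTED)
    mean_if = np.zeros(N_IMFS_EXPORTED)
    ins_p = np.zeros(N_IMFS_EXPORTED)
    if imfset.n_imfs < N_IMFS_EXPORTED:
        logger.info(
            "only %d IMFs available; remaining feature slots zero-filled",
            imfset.n_imfs,
        )
    for i, imf in enumerate(imfset.imfs[:N_IMFS_EXPORTED]):
        spec_p[i] = time_power(imf)
        if spec_p[i] == 0.0:
            continue
        if cfg is None:
            welch_cfg = WelchConfig(imf.size, imf.size // 2, "boxcar")
        elif imf.size < cfg.lseg:
            welch_cfg = WelchConfig(imf.size, imf.size // 2, cfg.window_fn,
                                    cfg.oversample)
        else:
            welch_cfg = cfg
        psd = welch_psd(imf, fs, welch_cfg)
        spec_pf[i] = band_power(psd, 0.0, float(psd.freqs[-1]))
        if_series = _interior(instantaneous_frequency(imf, fs))
        mean_if[i] = float(np.mean(if_series))
        ins_p[i] = time_power(if_series - np.mean(if_series) if ins_p_demean else if_series)
    out: dict[str, float] = {}
    for name, arr in (
        ("spec_p", spec_p),
        ("spec_pf", spec_pf),
        ("mean_if", mean_if),
        ("ins_p", ins_p),
    ):
        for i in range(N_IMFS_EXPORTED):
            out[f"{name}_{i + 1}"] = float(arr[i])
    return out
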