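"""Welch power-spectral-density estimation and trapezoidal band power.

The estimator is written out explicitly: the signal is split into segments of
``lseg`` samples advanced by ``lseg - lover`` (a trailing partial segment is
discarded), each segment is tapered with the chosen window and transformed
with a real FFT, and the squared magnitudes are averaged across segments.

The density normalisation is chosen so that the trapezoidal integral of the
PSD over [0, fs/2] approximates the mean squared value of a zero-mean signal
(one-sided density in signal-units^2 per Hz, with the window's coherent power
``sum(w^2)`` divided out and interior bins doubled).  No per-segment
de-trending is applied.

Band powers integrate the piecewise-linear interpolant of the PSD over
half-open bands ``[f_lo, f_hi)`` with linear interpolation at the band edges,
which makes band power exactly additive over adjacent bands.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["WelchConfig", "PSD", "welch_psd", "band_power"]


@dataclasses.dataclass(frozen=True)
class WelchConfig:
    lseg: int = 256  # segment length, samples
    lover: int = 128  # overlap, samples
    window_fn: str = "hann"
    oversample: int = 4  # zero-pad factor of the FFT grid

    def __post_init__(self) -> None:
        if not (0 < self.lover < self.lseg):
            raise ValueError("need 0 < lover < lseg")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")


@dataclasses.dataclass(frozen=True)
class PSD:
    """Frequency grid (Hz, from 0 to fs/2) and one-sided power density."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.size != p.size:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power density must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


def _taper(name: str, length: int) -> np.ndarray:
    name = name.lower()
    n = np.arange(length)
    if name in ("hann", "hanning"):
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / length))
    if name in ("rect", "boxcar", "rectangular"):
        return np.ones(length)
    if name == "hamming":
        return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / length)
    raise ValueError(f"unknown window function: {name}")


def welch_psd(samples, fs: float, cfg: WelchConfig = WelchConfig()) -> PSD:
    """Averaged-periodogram PSD over overlapping tapered segments."""
    x = np.asarray(samples, dtype=float)
    lseg, lover = cfg.lseg, cfg.lover
    if x.size < lseg:
        raise ValueError("signal shorter than segment")
    step = lseg - lover
    w = _taper(cfg.window_fn, lseg)
    scale = 1.0 / (fs * np.sum(w * w))
    # The FFT grid is zero-padded by `oversample` so the piecewise-linear
    # trapezoidal band integral resolves the taper's main lobe; the density
    # normalisation is unchanged by zero-padding.
    nfft = lseg * cfg.oversample

    n_segments = 1 + (x.size - lseg) // step
    acc = np.zeros(nfft // 2 + 1)
    for k in range(n_segments):
        seg = x[k * step : k * step + lseg] * w
        spectrum = np.fft.rfft(seg, n=nfft)
        acc += (spectrum.real**2 + spectrum.imag**2)
    power = acc * (scale / n_segments)
    # one-sided: double every bin except DC (and Nyquist for even nfft)
    power[1:-1] *= 2.0
    if nfft % 2:
        power[-1] *= 2.0
    freqs = np.arange(nfft // 2 + 1) * (fs / nfft)
    return PSD(freqs, power)


def _interp_power(psd: PSD, f: float) -> float:
    return float(np.interp(f, psd.freqs, psd.power))


def band_power(psd: PSD, f_lo: float, f_hi: float) -> float:
    """Trapezoidal integral of the PSD over the band ``[f_lo, f_hi)``.

    Band edges are linearly interpolated onto the grid, so powers of adjacent
    bands add exactly to the power of their union.
    """
    if not (0.0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    f_hi = min(f_hi, float(psd.freqs[-1]))
    if f_hi <= f_lo or f_lo > psd.freqs[-1]:
        raise ValueError("band does not overlap the frequency grid")
    inside = (psd.freqs > f_lo) & (psd.freqs < f_hi)
    grid = np.concatenate(([f_lo], psd.freqs[inside], [f_hi]))
    vals = np.concatenate(
        ([_interp_power(psd, f_lo)], psd.power[inside], [_interp_power(psd, f_hi)])
    )
    return float(np.trapezoid(vals, grid))
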