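"""Ten-frequency-band (TFB) spectral features.

The 0-100 Hz range of the pre-processed ECG's Welch spectrum (lseg=256,
lover=128, Hann taper by default) is partitioned into ten half-open 10 Hz
sub-bands ``[10*(i-1), 10*i)`` and the trapezoidal spectral power of each is
exported as ``band_1`` ... ``band_10``.  The half-open convention with edge
interpolation makes the ten band powers sum exactly to the full [0, 100) Hz
power.
"""

from __future__ import annotations

import numpy as np

from .io import ECGWindow
from .spectral import WelchConfig, band_power, welch_psd

__all__ = ["TFB_FEATURE_NAMES", "N_BANDS", "BAND_WIDTH_HZ", "tfb_features"]

N_BANDS = 10
BAND_WIDTH_HZ = 10.0

TFB_FEATURE_NAMES = [f"band_{i}" for i in range(1, N_BANDS + 1)]


def tfb_features(
    window: ECGWindow, cfg: WelchConfig = WelchConfig()
) -> dict[str, float]:
    """Spectral power in ten 10 Hz sub-bands of [0, 100) Hz."""
    if window.fs / 2 < N_BANDS * BAND_WIDTH_HZ:
        raise ValueError("Nyquist below TFB range (need fs >= 200 Hz)")
    psd = welch_psd(window.samples, window.fs, cfg)
    out = {}
    for i in range(1, N_BANDS + 1):
        out[f"band_{i}"] = band_power(
            psd, BAND_WIDTH_HZ * (i - 1), BAND_WIDTH_HZ * i
        )
    return out
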