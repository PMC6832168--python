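"""Assembly of the canonical 63-feature vector and batch feature tables.

A feature vector concatenates four blocks in fixed order: 14 HRV features,
24 EMD features, 15 within-beat features and 10 ten-frequency-band features.
If PQRST detection fails on a window (too few usable beats), the HRV and WIB
blocks are filled with NaN sentinels and the vector is still 63 entries long;
``build_table`` then drops such rows, mirroring the practice of discarding
anomalous recordings rather than imputing.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .emd import EMD_FEATURE_NAMES, EMD_WELCH_DEFAULT, emd_decompose, emd_features
from .hrv import HRV_FEATURE_NAMES, hrv_features, rr_from_peaks
from .io import ECGWindow
from .preprocess import PreprocessConfig, preprocess
from .pqrst import SearchWindows, annotate_beats, detect_r_peaks
from .spectral import WelchConfig
from .tfb import TFB_FEATURE_NAMES, tfb_features
from .wib import WIB_FEATURE_NAMES, interval_series, wib_features

logger = logging.getLogger(__name__)

__all__ = ["FEATURE_NAMES", "PipelineConfig", "extract_features", "build_table"]

#: Canonical 63 feature names: 14 HRV + 24 EMD + 15 WIB + 10 TFB.
FEATURE_NAMES = (
    list(HRV_FEATURE_NAMES)
    + list(EMD_FEATURE_NAMES)
    + list(WIB_FEATURE_NAMES)
    + list(TFB_FEATURE_NAMES)
)
assert len(FEATURE_NAMES) == 63


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the whole extraction pipeline."""

    preprocess: PreprocessConfig = PreprocessConfig()
    run_preprocess: bool = True
    search: SearchWindows = SearchWindows()
    min_rr: float = 0.3
    rel_threshold: float = 0.5
    hrv_resample_hz: float = 4.0
    welch: WelchConfig = WelchConfig()  # HRV-frequency and TFB stages
    emd_welch: WelchConfig | None = EMD_WELCH_DEFAULT  # None = full-length segment
    max_imfs: int = 8
    sift_tol: float = 0.2
    max_sift_iters: int = 100

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "search" in kwargs:
            kwargs["search"] = SearchWindows(**kwargs["search"])
        for key in ("welch", "emd_welch"):
            if key in kwargs:
                kwargs[key] = WelchConfig(**kwargs[key])
        return cls(**kwargs)


def extract_features(
    window: ECGWindow, cfg: PipelineConfig = PipelineConfig()
) -> dict[str, float]:
    """Extract the 63 canonical features from one window.

    Any failure of the beat-dependent stages leaves NaN sentinels in the HRV
    and WIB blocks; the EMD and TFB blocks are always computed.
    """
    if cfg.run_preprocess:
        window = preprocess(window, cfg.preprocess)

    feats: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    try:
        r_peaks = detect_r_peaks(window, cfg.min_rr, cfg.rel_threshold)
        ann = annotate_beats(window, r_peaks, cfg.search)
        rr = rr_from_peaks(ann.r_idx, window.fs)
        feats.update(hrv_features(rr, cfg.hrv_resample_hz, cfg.welch))
        feats.update(wib_features(interval_series(ann, window.fs)))
    except ValueError as exc:
        logger.warning("beat-dependent features unavailable: %s", exc)

    imfset = emd_decompose(window, cfg.max_imfs, cfg.sift_tol, cfg.max_sift_iters)
    feats.update(emd_features(imfset, window.fs, cfg.emd_welch))
    feats.update(tfb_features(window, cfg.welch))
    return {name: feats[name] for name in FEATURE_NAMES}


def build_table(
    dataset: list[tuple[ECGWindow, str]],
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """One feature row per window; rows containing sentinels are dropped.

    Returns a DataFrame with ``subject`` and ``label`` columns followed by the
    63 canonical feature columns.
    """
    labels = {label for _, label in dataset}
    if len(labels) < 2:
        raise ValueError("need at least 2 classes in the dataset")
    rows = []
    for window, label in dataset:
        feats = extract_features(window, cfg)
        rows.append({"subject": window.subject_id, "label": label, **feats})
    df = pd.DataFrame(rows, columns=["subject", "label"] + FEATURE_NAMES)
    complete = ~df[FEATURE_NAMES].isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d window(s) with incomplete features", n_dropped)
    df = df[complete].reset_index(drop=True)
    if df.empty:
        raise ValueError("all rows dropped: no window produced a complete vector")
    return df
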