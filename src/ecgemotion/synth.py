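"""Synthetic single-lead ECG generator with known ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative to
the R peak — a simplification of the McSharry dynamical model that keeps every
landmark location analytically known.  The R-R process is a deterministic mean
interval plus optional sinusoidal modulators (giving closed-form LF/HF
spectral content) and optional white jitter.  Corruption adds a polynomial
baseline trend, broadband Gaussian noise and an optional powerline tone, so
the preprocessing stages have realistic work to do.

Defaults mirror the acquisition conditions the pipeline targets: 20 s windows
sampled at 1000 Hz.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import ECGWindow

__all__ = [
    "BeatTemplateParams",
    "RhythmParams",
    "CorruptionParams",
    "generate_window",
    "generate_labeled_dataset",
    "DEFAULT_TEMPLATE",
]

WAVE_NAMES = ("p", "q", "r", "s", "t")


@dataclasses.dataclass(frozen=True)
class BeatTemplateParams:
    """Per-wave Gaussian bump parameters of one PQRST beat.

    ``amplitudes`` are in signal units, ``offsets`` are wave-center times in
    seconds relative to the R peak (negative = before R), ``widths`` are the
    Gaussian standard deviations in seconds.
    """

    amplitudes: Mapping[str, float]
    offsets: Mapping[str, float]
    widths: Mapping[str, float]

    def __post_init__(self) -> None:
        for field in (self.amplitudes, self.offsets, self.widths):
            missing = set(WAVE_NAMES) - set(field)
            if missing:
                raise ValueError(f"missing wave parameters: {sorted(missing)}")
        if any(self.widths[w] <= 0 for w in WAVE_NAMES):
            raise ValueError("all wave widths must be positive")
        centers = [self.offsets[w] for w in WAVE_NAMES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly ordered P < Q < R < S < T")
        r_amp = self.amplitudes["r"]
        positives = [a for a in self.amplitudes.values() if a > 0]
        if positives and r_amp < max(positives):
            raise ValueError("R amplitude must be the largest positive bump")

    @property
    def support(self) -> float:
        """Half-width (seconds) beyond which the beat is negligible (4 sigma)."""
        return max(abs(self.offsets[w]) + 4.0 * self.widths[w] for w in WAVE_NAMES)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Beat waveform at times ``t`` (seconds relative to the R peak)."""
        out = np.zeros_like(t, dtype=float)
        for w in WAVE_NAMES:
            out += self.amplitudes[w] * np.exp(
                -0.5 * ((t - self.offsets[w]) / self.widths[w]) ** 2
            )
        return out


# A normal-looking adult morphology: dominant upright R, small P and T bumps,
# narrow Q/S deflections.  Amplitudes in millivolt-like units.
DEFAULT_TEMPLATE = BeatTemplateParams(
    amplitudes={"p": 0.12, "q": -0.10, "r": 1.00, "s": -0.15, "t": 0.30},
    offsets={"p": -0.16, "q": -0.04, "r": 0.0, "s": 0.04, "t": 0.20},
    widths={"p": 0.025, "q": 0.010, "r": 0.012, "s": 0.010, "t": 0.045},
)


@dataclasses.dataclass(frozen=True)
class RhythmParams:
    """R-R interval process: mean + sinusoidal modulators + white jitter.

    ``rr_modulations`` is a list of ``(frequency_hz, amplitude_s)`` pairs; each
    contributes ``amp * sin(2*pi*f*t_beat)`` to the interval, so a 0.1 Hz
    modulator produces LF power in the HRV spectrum and a 0.3 Hz one HF power.
    """

    mean_rr: float = 0.8
    rr_modulations: Sequence[tuple[float, float]] = ()
    rr_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be non-negative")


@dataclasses.dataclass(frozen=True)
class CorruptionParams:
    """Additive nuisance terms: baseline trend, broadband noise, powerline."""

    trend_poly_coeffs: Sequence[float] = ()
    noise_sd: float = 0.0
    powerline_hz: float | None = None
    powerline_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _beat_times(rhythm: RhythmParams, duration: float, margin: float) -> np.ndarray:
    """R-peak times covering ``[-margin, duration + margin]``."""
    rng = np.random.default_rng(rhythm.seed)
    times = [-margin]
    t = times[0]
    # guard against pathological parameter choices driving rr non-positive
    floor = 0.2 * rhythm.mean_rr
    while t < duration + margin:
        rr = rhythm.mean_rr
        for f, amp in rhythm.rr_modulations:
            rr += amp * np.sin(2.0 * np.pi * f * t)
        if rhythm.rr_jitter_sd > 0:
            rr += rng.normal(0.0, rhythm.rr_jitter_sd)
        rr = max(rr, floor)
        t += rr
        times.append(t)
    return np.asarray(times)


def generate_window(
    template: BeatTemplateParams,
    rhythm: RhythmParams,
    corruption: CorruptionParams,
    fs: float = 1000.0,
    duration: float = 20.0,
    *,
    subject_id: str | None = None,
    label: str | None = None,
) -> tuple[ECGWindow, np.ndarray]:
    """Generate one ECG window plus the ground-truth R-peak times (seconds).

    The returned beat times are those falling inside ``[0, duration)``; beats
    just outside contribute waveform tails so edge beats are not clipped
    artificially.  Identical parameters (including ``rhythm.seed``) yield
    bit-identical output.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    margin = template.support + rhythm.mean_rr
    all_beats = _beat_times(rhythm, duration, margin)
    in_window = all_beats[(all_beats >= 0.0) & (all_beats < duration)]
    if in_window.size < 2:
        raise ValueError("insufficient beats: rhythm produced fewer than 2 beats")

    signal = np.zeros(n)
    half = template.support
    for tb in all_beats:
        lo = max(0, int(np.floor((tb - half) * fs)))
        hi = min(n, int(np.ceil((tb + half) * fs)) + 1)
        if hi <= lo:
            continue
        signal[lo:hi] += template.evaluate(t[lo:hi] - tb)

    if corruption.trend_poly_coeffs:
        signal = signal + np.polyval(list(corruption.trend_poly_coeffs), t)
    if corruption.powerline_hz is not None and corruption.powerline_amp:
        signal = signal + corruption.powerline_amp * np.sin(
            2.0 * np.pi * corruption.powerline_hz * t
        )
    if corruption.noise_sd > 0:
        # independent stream so the rhythm realisation is noise-invariant
        noise_rng = np.random.default_rng((rhythm.seed, 0xEC6))
        signal = signal + noise_rng.normal(0.0, corruption.noise_sd, size=n)

    window = ECGWindow(signal, fs, subject_id=subject_id, label=label)
    return window, in_window


def generate_labeled_dataset_with_truth(
    class_specs: Mapping[
        str, tuple[BeatTemplateParams, RhythmParams, CorruptionParams]
    ],
    n_per_class: int,
    fs: float = 1000.0,
    duration: float = 20.0,
    seed: int = 0,
) -> list[tuple[ECGWindow, str, np.ndarray]]:
    """As :func:`generate_labeled_dataset`, also returning true beat times."""
    labels = list(class_specs)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate class labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(labels) * n_per_class) % (2**31)
    dataset: list[tuple[ECGWindow, str, np.ndarray]] = []
    k = 0
    for label in labels:
        template, rhythm, corruption = class_specs[label]
        for i in range(n_per_class):
            r = dataclasses.replace(rhythm, seed=int(child_seeds[k]))
            k += 1
            window, beats = generate_window(
                template,
                r,
                corruption,
                fs,
                duration,
                subject_id=f"sim-{label}-{i:03d}",
                label=label,
            )
            dataset.append((window, label, beats))
    return dataset


def generate_labeled_dataset(
    class_specs: Mapping[
        str, tuple[BeatTemplateParams, RhythmParams, CorruptionParams]
    ],
    n_per_class: int,
    fs: float = 1000.0,
    duration: float = 20.0,
    seed: int = 0,
) -> list[tuple[ECGWindow, str]]:
    """Generate ``n_per_class`` windows per class with per-window rhythm seeds.

    Class specs map label -> (template, rhythm, corruption).  Each window gets
    a distinct rhythm seed derived from ``seed`` so windows within a class are
    independent realisations; the whole dataset is reproducible under ``seed``.
    """
    return [
        (window, label)
        for window, label, _ in generate_labeled_dataset_with_truth(
            class_specs, n_per_class, fs, duration, seed
        )
    ]


def emotion_class_specs() -> dict[str, tuple[BeatTemplateParams, RhythmParams, CorruptionParams]]:
    """Standard four-class study conditions for synthetic training data.

    The classes mimic the autonomic signatures the four arousal-valence
    quadrants are expected to leave on an ECG: high-arousal states (joy,
    anger) get short mean R-R intervals, low-arousal ones (pleasure, sadness)
    long; sympathetic-leaning states get LF-dominant R-R modulation and
    parasympathetic-leaning ones more HF modulation, plus mild morphology
    differences (T/S/P amplitudes).  All classes share realistic broadband
    noise (0.03 signal units), a slow baseline trend and white R-R jitter.
    """

    def tpl(**over):
        amp = dict(DEFAULT_TEMPLATE.amplitudes)
        amp.update(over)
        return BeatTemplateParams(amp, DEFAULT_TEMPLATE.offsets, DEFAULT_TEMPLATE.widths)

    corruption = CorruptionParams(
        trend_poly_coeffs=[0.0005, -0.01, 0.05], noise_sd=0.03
    )
    return {
        "joy": (
            tpl(t=0.35),
            RhythmParams(0.65, [(0.1, 0.02), (0.3, 0.015)], rr_jitter_sd=0.02),
            corruption,
        ),
        "anger": (
            tpl(s=-0.25),
            RhythmParams(0.72, [(0.1, 0.04)], rr_jitter_sd=0.03),
            corruption,
        ),
        "pleasure": (
            tpl(p=0.18),
            RhythmParams(0.85, [(0.25, 0.03)], rr_jitter_sd=0.015),
            corruption,
        ),
        "sadness": (
            tpl(t=0.20),
            RhythmParams(0.95, [(0.1, 0.02)], rr_jitter_sd=0.01),
            corruption,
        ),
    }


def write_ground_truth(
    path: str | Path,
    entries: Sequence[dict],
) -> None:
    """Write the simulate CLI's ground-truth JSON (beat times + parameters)."""
    with open(path, "w") as fh:
        json.dump(list(entries), fh, indent=1, default=list)
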