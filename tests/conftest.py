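import numpy as np
import pytest

from ecgemotion import (
    CorruptionParams,
    DEFAULT_TEMPLATE,
    RhythmParams,
    annotate_beats,
    detect_r_peaks,
    generate_window,
    preprocess,
)

FS = 1000.0
DURATION = 20.0


@pytest.fixture(scope="session")
def clean_window():
    """Noise-free window with a perfectly regular 1.0 s rhythm."""
    window, beats = generate_window(
        DEFAULT_TEMPLATE, RhythmParams(mean_rr=1.0, seed=1), CorruptionParams(),
        FS, DURATION,
    )
    return window, beats


@pytest.fixture(scope="session")
def realistic_window():
    """Modulated, jittered rhythm with trend, noise and powerline pickup."""
    rhythm = RhythmParams(
        mean_rr=0.8,
        rr_modulations=[(0.1, 0.04), (0.3, 0.02)],
        rr_jitter_sd=0.01,
        seed=7,
    )
    corruption = CorruptionParams(
        trend_poly_coeffs=[0.002, -0.05, 0.1],
        noise_sd=0.03,
        powerline_hz=50.0,
        powerline_amp=0.02,
    )
    return generate_window(DEFAULT_TEMPLATE, rhythm, corruption, FS, DURATION)


@pytest.fixture(scope="session")
def preprocessed_realistic(realistic_window):
    window, beats = realistic_window
    return preprocess(window), beats


@pytest.fixture(scope="session")
def annotated_realistic(preprocessed_realistic):
    window, beats = preprocessed_realistic
    peaks = detect_r_peaks(window)
    return window, annotate_beats(window, peaks), beats


def random_generation_params(rng):
    """Draw plausible template/rhythm variations for property tests."""
    import dataclasses

    amp = dict(DEFAULT_TEMPLATE.amplitudes)
    for wave in amp:
        amp[wave] *= rng.uniform(0.8, 1.2)
    widths = {w: v * rng.uniform(0.85, 1.15) for w, v in DEFAULT_TEMPLATE.widths.items()}
    template = dataclasses.replace(DEFAULT_TEMPLATE, amplitudes=amp, widths=widths)
    rhythm = RhythmParams(
        mean_rr=rng.uniform(0.6, 1.1),
        rr_modulations=[(0.1, 0.02)],
        rr_jitter_sd=rng.uniform(0.0, 0.02),
        seed=int(rng.integers(0, 2**31)),
    )
    return template, rhythm
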