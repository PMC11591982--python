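"""Shared fixtures: synthetic captures and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from palmbp import PulseModelParams, render_synthetic_frames, simulate_pulse_wave
from palmbp.bp_models import compute_bmi, formula_value
from palmbp.pipeline import PipelineConfig, SubjectCapture, extract_features

ALPHA_SBP = (60.0, 40.0, 0.5)
ALPHA_DBP = (40.0, 20.0, 0.3)


@pytest.fixture(scope="session")
def sine_trace():
    """Noise-free 1 Hz sine, 10 s at 20 fps (peaks exactly on samples)."""
    params = PulseModelParams(a0=0.0, harmonics=((0.0, 1.0),), omega_h=2 * np.pi * 1.0)
    return simulate_pulse_wave(params, fps=20, duration=10)


def make_frame_captures(
    n_subjects: int,
    seed: int,
    config: PipelineConfig,
    frame_side: int = 32,
    fps: float = 20.0,
):
    """Noiseless synthetic subjects for closed-loop calibration tests.

    Each subject gets a pulse waveform with its own harmonic content (the
    shape spread that survives unit-variance normalization and makes the
    feature-to-pressure map identifiable), rendered to frames. The
    ground-truth pressures apply the known generating coefficients to the
    features extracted through the package's own path, so a perfect
    calibration would reproduce them exactly.

    Returns (captures, truths) with truths a list of (sbp, dbp).
    """
    rng = np.random.default_rng(seed)
    captures, truths = [], []
    for i in range(n_subjects):
        h2 = rng.uniform(0.1, 0.6)
        h3 = rng.uniform(0.0, 0.3)
        hr = rng.uniform(0.9, 1.6)  # 54-96 bpm
        params = PulseModelParams(
            harmonics=((5.0, 0.0), (5 * h2, 1.0), (5 * h3, 0.5)),
            omega_h=2 * np.pi * hr,
        )
        trace = simulate_pulse_wave(params, fps, duration=10.5)
        frames, landmarks = render_synthetic_frames(
            trace, (frame_side, frame_side), seed=seed * 1000 + i
        )
        height = rng.uniform(1.5, 1.9)
        weight = rng.uniform(50, 95)
        bmi = compute_bmi(height, weight)
        summary = extract_features(frames=frames, landmarks=landmarks, config=config)
        sbp = float(formula_value(ALPHA_SBP, summary.e_peak, bmi))
        dbp = float(formula_value(ALPHA_DBP, summary.e_valley, bmi))
        captures.append(
            SubjectCapture(
                height=height,
                weight=weight,
                sbp_device=sbp,
                dbp_device=dbp,
                frames=frames,
                landmarks=landmarks,
                label=f"subject {i}",
            )
        )
        truths.append((sbp, dbp))
    return captures, truths


@pytest.fixture(scope="session")
def frame_captures():
    config = PipelineConfig()
    captures, truths = make_frame_captures(9, seed=7, config=config)
    return captures, truths, config
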