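"""Synthetic pulse waves, mixed sources, frames and calibration cohorts.

No public palm-video blood-pressure dataset exists, so every downstream
stage is exercised against signals fabricated here:

* a radial-resonance pulse model — the arterial pulse written as a harmonic
  series at the heart's fundamental frequency, each harmonic attenuated by
  ``exp(-k z / c)`` for subject-to-lens distance ``z`` and wave speed ``c``;
* linear source mixtures with a known mixing matrix, for blind and
  semi-blind separation tests;
* rendered 8-bit frame sequences with hand landmarks, so ROI extraction can
  be tested without a webcam;
* calibration cohorts whose device readings follow the empirical
  blood-pressure formulas exactly, plus optional Gaussian device noise.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateROIError,
    DimensionError,
    InvalidArgumentError,
    SingularMatrixError,
)
from .roi_signal import FrameSequence, LandmarkSet, ROI_LANDMARK_INDICES, _polygon_area

__all__ = [
    "PulseModelParams",
    "PulseTrace",
    "MixingSpec",
    "SubjectRecord",
    "simulate_pulse_wave",
    "mix_sources",
    "generate_cohort",
    "render_synthetic_frames",
]


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of the harmonic radial-resonance pulse model.

    ``harmonics[k-1] = (a_k, b_k)`` are the cosine/sine amplitudes of the
    k-th harmonic of the fundamental angular frequency ``omega_h`` (rad/s);
    ``a0`` is the DC baseline. Each harmonic is attenuated by
    ``exp(-k * z / c)``.
    """

    a0: float = 0.0
    harmonics: tuple[tuple[float, float], ...] = ((1.0, 0.0),)
    omega_h: float = 2 * np.pi * 1.2  # 72 bpm
    z: float = 0.0  # subject-to-lens distance, m
    c: float = 1.0  # wave speed, m/s

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "harmonics", tuple((float(a), float(b)) for a, b in self.harmonics)
        )
        if not self.omega_h > 0:
            raise InvalidArgumentError("omega_h must be positive")
        if not self.c > 0:
            raise InvalidArgumentError("wave speed c must be positive")
        if self.z < 0:
            raise InvalidArgumentError("distance z must be non-negative")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)


@dataclass(frozen=True)
class PulseTrace:
    """A uniformly sampled scalar pulse signal."""

    samples: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float).ravel()
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        if s.size < 1:
            raise InvalidArgumentError("a PulseTrace needs at least one sample")
        if not np.all(np.isfinite(s)):
            raise InvalidArgumentError("samples must be finite")
        object.__setattr__(self, "samples", s)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) / self.fps

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps


@dataclass(frozen=True)
class MixingSpec:
    """Known sources S and mixing matrix A for X = A @ S."""

    sources: np.ndarray  # (n_sources, n_samples)
    mixing: np.ndarray  # (n_channels, n_sources)

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.sources, dtype=float))
        a = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        object.__setattr__(self, "sources", s)
        object.__setattr__(self, "mixing", a)
        if a.shape[1] != s.shape[0]:
            raise DimensionError(
                f"mixing has {a.shape[1]} columns but there are {s.shape[0]} sources"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One calibration row: BMI, device readings, extracted pulse features."""

    bmi: float
    sbp_device: float
    dbp_device: float
    e_peak: float
    e_valley: float

    def __post_init__(self) -> None:
        if not 10 < self.bmi < 60:
            raise InvalidArgumentError(f"implausible BMI {self.bmi}")
        if not self.sbp_device > self.dbp_device > 0:
            raise InvalidArgumentError("need SBP > DBP > 0")


def simulate_pulse_wave(
    params: PulseModelParams,
    fps: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PulseTrace:
    """Sample the harmonic pulse model at ``fps`` for ``duration`` seconds.

    ``p(t) = a0 + sum_k (a_k cos(w k t) + b_k sin(w k t)) exp(-k z / c)``
    plus optional white Gaussian noise of standard deviation ``noise_sd``.
    """
    if not fps > 0 or not duration > 0:
        raise InvalidArgumentError("fps and duration must be positive")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    n = int(round(duration * fps))
    if n < 2:
        raise InvalidArgumentError("duration * fps must be at least 2 samples")
    t = np.arange(n) / fps
    p = np.full(n, float(params.a0))
    for k, (ak, bk) in enumerate(params.harmonics, start=1):
        atten = np.exp(-k * params.z / params.c)
        p += (ak * np.cos(params.omega_h * k * t) + bk * np.sin(params.omega_h * k * t)) * atten
    if noise_sd > 0:
        p += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return PulseTrace(samples=p, fps=fps)


def mix_sources(spec: MixingSpec, semi_blind: bool = False) -> np.ndarray:
    """Form the observed mixture X = A @ S.

    With ``semi_blind=True`` the mixing matrix is additionally required to
    have full column rank, since semi-blind unmixing will invert it.
    """
    if semi_blind:
        if np.linalg.matrix_rank(spec.mixing) < spec.mixing.shape[1]:
            raise SingularMatrixError(
                "mixing matrix is rank deficient; semi-blind unmixing impossible"
            )
    return spec.mixing @ spec.sources


def generate_cohort(
    n: int,
    true_params_sbp,
    true_params_dbp,
    bmi_range: tuple[float, float] = (18.5, 32.0),
    feature_range: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a synthetic calibration cohort.

    BMI and the pulse features are uniform over their ranges (with
    ``e_peak > e_valley`` enforced by swapping the two draws — the systolic
    reflectance extreme physically exceeds the diastolic one); device
    readings are the empirical formula value at the true coefficients plus
    ``N(0, noise_sd^2)`` mmHg.

    ``true_params_*`` are coefficient triples ``(alpha0, alpha1, alpha2)``
    of SBP = a0 + a1*Epeak + BMI*(1 + a2*Epeak) (DBP analogous with Evalley).
    """
    from .bp_models import formula_value

    if n < 1:
        raise InvalidArgumentError("n must be at least 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    if not bmi_range[1] > bmi_range[0] or not feature_range[1] > feature_range[0]:
        raise InvalidArgumentError("ranges must be non-empty (hi > lo)")
    rng = np.random.default_rng(seed)
    bmi = rng.uniform(*bmi_range, size=n)
    f1 = rng.uniform(*feature_range, size=n)
    f2 = rng.uniform(*feature_range, size=n)
    e_peak = np.maximum(f1, f2)
    e_valley = np.minimum(f1, f2)
    sbp = formula_value(true_params_sbp, e_peak, bmi)
    dbp = formula_value(true_params_dbp, e_valley, bmi)
    if noise_sd > 0:
        sbp = sbp + rng.normal(0.0, noise_sd, size=n)
        dbp = dbp + rng.normal(0.0, noise_sd, size=n)
    return [
        SubjectRecord(
            bmi=float(bmi[i]),
            sbp_device=float(sbp[i]),
            dbp_device=float(dbp[i]),
            e_peak=float(e_peak[i]),
            e_valley=float(e_valley[i]),
        )
        for i in range(n)
    ]


DEFAULT_BASELINE = 120.0  # webcam green-channel resting intensity, 8-bit units


def render_synthetic_frames(
    trace: PulseTrace,
    frame_size: tuple[int, int] = (64, 64),
    palm_polygon: np.ndarray | None = None,
    seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
    max_frames: int = 20000,
) -> tuple[FrameSequence, list[LandmarkSet]]:
    """Render a palm-like frame sequence carrying the pulse on green.

    Inside the palm polygon the green channel is ``baseline + sample``,
    rounded to 8 bits with clipping; red/blue are skin-toned constants.
    Outside pixels are a static seeded texture. A static sub-LSB dither
    field (emulating the spatial texture of real skin) is added before
    rounding so that averaging over the ROI recovers intensity changes
    finer than one 8-bit step. Every frame's landmark set places points
    1, 5, 17, 0 at the polygon's vertices; the remaining points sit near
    the polygon centroid.

    ``palm_polygon`` is a (4, 2) array of (x, y) pixel vertices in the
    cyclic order (thumb CMC, index MCP, pinky MCP, wrist); the default is a
    quadrilateral inset 1/8th from the frame border.
    """
    from .roi_signal import _interior_mask

    w, h = int(frame_size[0]), int(frame_size[1])
    n = len(trace)
    if n > max_frames:
        raise InvalidArgumentError(f"trace of {n} samples exceeds frame budget {max_frames}")
    if palm_polygon is None:
        palm_polygon = np.array(
            [[w / 8, h / 8], [7 * w / 8, h / 8], [7 * w / 8, 7 * h / 8], [w / 8, 7 * h / 8]],
            dtype=float,
        )
    palm_polygon = np.asarray(palm_polygon, dtype=float)
    if palm_polygon.shape != (4, 2):
        raise InvalidArgumentError("palm_polygon must be a (4, 2) vertex array")
    if abs(_polygon_area(palm_polygon)) <= 1e-9 * max(1.0, w * h):
        raise DegenerateROIError("palm polygon has zero area")
    if (palm_polygon < 0).any() or (palm_polygon[:, 0] > w).any() or (palm_polygon[:, 1] > h).any():
        raise InvalidArgumentError("palm polygon must lie inside the frame bounds")

    rng = np.random.default_rng(seed)
    background = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    dither = rng.uniform(-0.5, 0.5, size=(h, w))
    mask = _interior_mask((h, w), palm_polygon)

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    skin_r, skin_b = 150.0, 110.0
    for i, s in enumerate(trace.samples):
        frame = background.copy()
        g = np.clip(np.rint(baseline + s + dither[mask]), 0, 255).astype(np.uint8)
        frame[mask, 0] = np.uint8(skin_r)
        frame[mask, 1] = g
        frame[mask, 2] = np.uint8(skin_b)
        frames[i] = frame

    pts = np.full((21, 2), np.nan)
    centroid = palm_polygon.mean(axis=0)
    # park the 17 unused landmarks on a small ring around the centroid so
    # no two coincide
    ring = np.arange(21)
    pts[:, 0] = (centroid[0] + 0.02 * w * np.cos(ring)) / w
    pts[:, 1] = (centroid[1] + 0.02 * h * np.sin(ring)) / h
    for vertex, idx in zip(palm_polygon, ROI_LANDMARK_INDICES):
        pts[idx] = vertex / np.array([w, h])
    landmarks = LandmarkSet(points=pts)
    return FrameSequence(frames=frames, fps=trace.fps), [landmarks] * n
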