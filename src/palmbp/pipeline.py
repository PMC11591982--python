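"""End-to-end measurement and calibration orchestration.

A measurement runs: BMI from height/weight -> (palm ROI extraction when
frames are given) -> per-channel z-scoring -> ICA denoising -> pulse
component selection -> ten-window peak/valley features -> blood-pressure
prediction by the chosen method.

Because the empirical coefficients absorb the scale of the features, every
calibration result embeds a fingerprint (hash) of the preprocessing
configuration that produced its features; prediction refuses parameters
whose fingerprint does not match the active configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bp_models import (
    DEFAULT_BMI_INTERVALS,
    BPFormulaParams,
    RegressionParams,
    bmi_interval_lookup,
    compute_bmi,
    fit_nmpso,
    fit_regression,
    predict_formula,
    predict_regression,
)
from .errors import CalibrationMismatchError, InvalidArgumentError
from .ica_denoise import DEFAULT_PULSE_BAND, ICAConfig, run_ica, select_pulse_component
from .nmpso import NMPSOConfig
from .pulse_features import DEFAULT_MIN_INTERVAL_S, PeakValleySummary, ten_window_summary
from .roi_signal import FrameSequence, LandmarkSet, RGBTrace, channel_means, normalize_trace, roi_polygon
from .synthetic_data import PulseTrace, SubjectRecord

__all__ = [
    "PipelineConfig",
    "SubjectCapture",
    "CalibratedModel",
    "MeasurementResult",
    "extract_features",
    "measure",
    "calibrate_end_to_end",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing settings shared by calibration and measurement."""

    prenormalize: bool = True
    ica: ICAConfig = field(default_factory=ICAConfig)
    band: tuple[float, float] = DEFAULT_PULSE_BAND
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S
    n_windows: int = 10

    def fingerprint(self) -> str:
        """Stable hash of everything that shapes the feature scale."""
        payload = {
            "prenormalize": self.prenormalize,
            "ica": {
                "n_components": self.ica.n_components,
                "max_iter": self.ica.max_iter,
                "tol": self.ica.tol,
                "var_threshold": self.ica.var_threshold,
                "contrast": self.ica.contrast,
                "seed": self.ica.seed,
            },
            "band": list(self.band),
            "min_interval_s": self.min_interval_s,
            "n_windows": self.n_windows,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class SubjectCapture:
    """One calibration subject: a capture plus device readings.

    Either ``trace`` (single-channel or RGB) or ``frames`` + ``landmarks``
    must be provided.
    """

    height: float  # m
    weight: float  # kg
    sbp_device: float | None = None
    dbp_device: float | None = None
    trace: PulseTrace | RGBTrace | None = None
    frames: FrameSequence | None = None
    landmarks: Sequence[LandmarkSet] | None = None
    label: str = ""


@dataclass(frozen=True)
class CalibratedModel:
    """Fitted parameters for both targets, bound to a preprocessing hash."""

    method: str  # "nmpso" | "regression"
    sbp: Sequence[BPFormulaParams] | RegressionParams
    dbp: Sequence[BPFormulaParams] | RegressionParams
    fingerprint: str

    def to_dict(self) -> dict:
        def enc(p):
            if isinstance(p, RegressionParams):
                return {"target": p.target, "gamma": list(p.gamma)}
            return {
                "target": p[0].target,
                "intervals": [
                    {"lo": q.bmi_interval[0], "hi": q.bmi_interval[1], "alpha": list(q.alpha)}
                    for q in p
                ],
            }

        return {
            "method": self.method,
            "fingerprint": self.fingerprint,
            "sbp": enc(self.sbp),
            "dbp": enc(self.dbp),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedModel":
        def dec(e, target):
            if "gamma" in e:
                g = e["gamma"]
                return RegressionParams(g[0], g[1], g[2], target=target)
            return [
                BPFormulaParams(
                    *iv["alpha"], target=target, bmi_interval=(iv["lo"], iv["hi"])
                )
                for iv in e["intervals"]
            ]

        return cls(
            method=d["method"],
            sbp=dec(d["sbp"], "SBP"),
            dbp=dec(d["dbp"], "DBP"),
            fingerprint=d["fingerprint"],
        )


@dataclass(frozen=True)
class MeasurementResult:
    sbp: float
    dbp: float
    method: str
    e_peak: float
    e_valley: float
    bmi: float
    windows_used: int
    preprocessing_fingerprint: str


def _roi_trace(frames: FrameSequence, landmarks: Sequence[LandmarkSet]) -> RGBTrace:
    """Per-frame palm polygon -> channel means; landmarks may move per frame."""
    if len(landmarks) != len(frames):
        raise InvalidArgumentError(
            f"{len(landmarks)} landmark sets for {len(frames)} frames"
        )
    h, w = frames.frames.shape[1:3]
    vals = np.empty((len(frames), 3))
    for i, lms in enumerate(landmarks):
        poly = roi_polygon(lms, frame_size=(w, h))
        one = channel_means(frames.frames[i : i + 1], poly, fps=frames.fps)
        vals[i] = one.values[0]
    return RGBTrace(values=vals, fps=frames.fps)


def extract_features(
    trace: PulseTrace | RGBTrace | None = None,
    frames: FrameSequence | None = None,
    landmarks: Sequence[LandmarkSet] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PeakValleySummary:
    """Shared feature path: capture -> denoised pulse -> ten-window summary."""
    if frames is not None:
        if landmarks is None:
            raise InvalidArgumentError("frames require per-frame landmarks")
        trace = _roi_trace(frames, landmarks)
    if trace is None:
        raise InvalidArgumentError("provide a trace or frames+landmarks")

    if isinstance(trace, RGBTrace):
        if config.prenormalize:
            trace = normalize_trace(trace)
        X = trace.values.T  # channels x samples
        result = run_ica(X, config.ica)
        pulse = select_pulse_component(result.components, trace.fps, config.band)
    else:
        samples = trace.samples
        if config.prenormalize:
            sd = samples.std()
            samples = (samples - samples.mean()) / sd if sd > 0 else samples * 0.0
        pulse = PulseTrace(samples=samples, fps=trace.fps)
    return ten_window_summary(pulse, config.min_interval_s, config.n_windows)


def measure(
    *,
    height: float,
    weight: float,
    params: CalibratedModel,
    method: str | None = None,
    trace: PulseTrace | RGBTrace | None = None,
    frames: FrameSequence | None = None,
    landmarks: Sequence[LandmarkSet] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> MeasurementResult:
    """One non-contact blood-pressure measurement.

    Requires at least ``n_windows`` seconds of capture and calibration
    parameters fingerprint-matched to ``config``.
    """
    method = method or params.method
    if method != params.method:
        raise InvalidArgumentError(
            f"requested method {method!r} but params were fitted with {params.method!r}"
        )
    fp = config.fingerprint()
    if params.fingerprint != fp:
        raise CalibrationMismatchError(
            f"params fingerprint {params.fingerprint} != active config {fp}; "
            "recalibrate under the current preprocessing settings"
        )
    cap = trace if trace is not None else frames
    if cap is not None and cap.duration < config.n_windows:
        raise InvalidArgumentError(
            f"capture of {cap.duration:.2f} s is shorter than the "
            f"{config.n_windows} s measurement"
        )
    bmi = compute_bmi(height, weight)
    summary = extract_features(trace=trace, frames=frames, landmarks=landmarks, config=config)
    if method == "nmpso":
        sbp = predict_formula(summary.e_peak, bmi, bmi_interval_lookup(bmi, params.sbp))
        dbp = predict_formula(summary.e_valley, bmi, bmi_interval_lookup(bmi, params.dbp))
    elif method == "regression":
        sbp = predict_regression(bmi, summary.e_peak, params.sbp)
        dbp = predict_regression(bmi, summary.e_valley, params.dbp)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return MeasurementResult(
        sbp=sbp,
        dbp=dbp,
        method=method,
        e_peak=summary.e_peak,
        e_valley=summary.e_valley,
        bmi=bmi,
        windows_used=summary.windows_used,
        preprocessing_fingerprint=fp,
    )


def calibrate_end_to_end(
    captures: Sequence[SubjectCapture],
    method: str,
    config: PipelineConfig = PipelineConfig(),
    bmi_intervals: Sequence[tuple[float, float]] = DEFAULT_BMI_INTERVALS,
    nmpso_config: NMPSOConfig | None = None,
) -> CalibratedModel:
    """Run the full feature path per subject, then fit the chosen model."""
    if method not in ("nmpso", "regression"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    records: list[SubjectRecord] = []
    for i, cap in enumerate(captures):
        who = cap.label or f"subject {i}"
        if cap.sbp_device is None or cap.dbp_device is None:
            raise InvalidArgumentError(f"{who}: missing device SBP/DBP reading")
        summary = extract_features(
            trace=cap.trace, frames=cap.frames, landmarks=cap.landmarks, config=config
        )
        records.append(
            SubjectRecord(
                bmi=compute_bmi(cap.height, cap.weight),
                sbp_device=cap.sbp_device,
                dbp_device=cap.dbp_device,
                e_peak=summary.e_peak,
                e_valley=summary.e_valley,
            )
        )
    if method == "nmpso":
        sbp = fit_nmpso(records, "SBP", bmi_intervals, nmpso_config)
        dbp = fit_nmpso(records, "DBP", bmi_intervals, nmpso_config)
    else:
        sbp = fit_regression(records, "SBP")
        dbp = fit_regression(records, "DBP")
    return CalibratedModel(method=method, sbp=sbp, dbp=dbp, fingerprint=config.fingerprint())
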