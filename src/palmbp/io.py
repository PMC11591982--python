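"""File formats: cohort CSV, trace CSV, landmark JSON, parameter JSON, frames.

All formats are plain text except the optional per-frame PNG directory
used by the CLI's frame simulator and extractor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .pipeline import CalibratedModel
from .roi_signal import FrameSequence, LandmarkSet, RGBTrace
from .synthetic_data import PulseTrace, SubjectRecord

COHORT_COLUMNS = ["bmi", "sbp_device", "dbp_device", "e_peak", "e_valley"]


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"cohort CSV missing columns {sorted(missing)}")
    for col in COHORT_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise InvalidArgumentError(
                f"cohort CSV row {int(bad[0]) + 2}: missing value in {col!r}"
            )
    return [SubjectRecord(**row[COHORT_COLUMNS].to_dict()) for _, row in df.iterrows()]


def write_trace_csv(trace: PulseTrace | RGBTrace, path: str | Path) -> None:
    """Header ``t,value`` for scalar traces, ``t,r,g,b`` for RGB traces."""
    if isinstance(trace, PulseTrace):
        df = pd.DataFrame({"t": trace.t, "value": trace.samples})
    else:
        t = np.arange(len(trace)) / trace.fps
        df = pd.DataFrame(
            {"t": t, "r": trace.values[:, 0], "g": trace.values[:, 1], "b": trace.values[:, 2]}
        )
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, fps: float | None = None) -> PulseTrace | RGBTrace:
    """Infer fps from the time column unless given explicitly."""
    df = pd.read_csv(path)
    if fps is None:
        t = df["t"].to_numpy()
        if len(t) < 2:
            raise InvalidArgumentError("cannot infer fps from fewer than 2 rows")
        fps = 1.0 / float(np.median(np.diff(t)))
    if {"r", "g", "b"} <= set(df.columns):
        return RGBTrace(values=df[["r", "g", "b"]].to_numpy(), fps=fps)
    if "value" in df.columns:
        return PulseTrace(samples=df["value"].to_numpy(), fps=fps)
    raise InvalidArgumentError("trace CSV needs columns t,value or t,r,g,b")


def write_landmarks_json(landmarks: Sequence[LandmarkSet], path: str | Path) -> None:
    payload = {"frames": [{"points": lms.points.tolist()} for lms in landmarks]}
    Path(path).write_text(json.dumps(payload))


def read_landmarks_json(path: str | Path) -> list[LandmarkSet]:
    payload = json.loads(Path(path).read_text())
    return [LandmarkSet(points=np.array(f["points"])) for f in payload["frames"]]


def write_params_json(model: CalibratedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_params_json(path: str | Path) -> CalibratedModel:
    return CalibratedModel.from_dict(json.loads(Path(path).read_text()))


def write_frames_dir(frames: FrameSequence, directory: str | Path) -> None:
    """One zero-padded PNG per frame plus an fps.json sidecar."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(frames)):
        Image.fromarray(frames.frames[i]).save(directory / f"frame_{i:05d}.png")
    (directory / "fps.json").write_text(json.dumps({"fps": frames.fps}))


def read_frames_dir(directory: str | Path) -> FrameSequence:
    from PIL import Image

    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise InvalidArgumentError(f"no frame_*.png files in {directory}")
    fps = json.loads((directory / "fps.json").read_text())["fps"]
    stack = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in paths])
    return FrameSequence(frames=stack, fps=fps)
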