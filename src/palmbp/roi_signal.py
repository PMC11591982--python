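"""Palm region-of-interest signal extraction.

The camera-facing half of the measurement chain: given per-frame hand
landmarks (21 points in the MediaPipe indexing convention, delivered by a
provider interface or a JSON fixture — never by a vendored detector) and the
frames themselves, build the palm quadrilateral from landmarks 1, 5, 17, 0,
average each color channel over the pixels inside it, and z-score the
resulting per-channel traces over the capture window.

Landmark indices follow the standard 21-point hand model: 0 = wrist,
1 = thumb CMC, 5 = index MCP, 17 = pinky MCP; the quadrilateral through
1 → 5 → 17 → 0 covers the palm, which carries a stable blood-volume pulse
and avoids finger motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateROIError, InvalidArgumentError

__all__ = [
    "LandmarkSet",
    "RGBTrace",
    "FrameSequence",
    "ROI_LANDMARK_INDICES",
    "roi_polygon",
    "channel_means",
    "normalize_trace",
    "points_in_polygon",
]

#: palm quadrilateral corners, in cyclic order: thumb CMC, index MCP,
#: pinky MCP, wrist
ROI_LANDMARK_INDICES = (1, 5, 17, 0)


@dataclass(frozen=True)
class LandmarkSet:
    """21 hand landmarks in normalized image coordinates [0, 1]."""

    points: np.ndarray  # (21, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (21, 2):
            raise InvalidArgumentError(
                f"a LandmarkSet has exactly 21 (x, y) points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidArgumentError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class RGBTrace:
    """Per-frame mean of R, G, B inside the ROI, plus the sampling rate."""

    values: np.ndarray  # (n_frames, 3)
    fps: float

    def __post_init__(self) -> None:
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.size and vals.shape[1] != 3:
            raise InvalidArgumentError(f"RGBTrace needs 3 channels, got {vals.shape}")
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return 0 if self.values.size == 0 else self.values.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.fps


@dataclass(frozen=True)
class FrameSequence:
    """A stack of 8-bit RGB frames with their frame rate."""

    frames: np.ndarray = field(repr=False)  # (n_frames, H, W, 3) uint8
    fps: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise InvalidArgumentError(
                f"frames must have shape (n, H, W, 3), got {arr.shape}"
            )
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        object.__setattr__(self, "frames", arr)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.fps


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points.

    Points exactly on an edge follow the half-open crossing convention, so the
    test is deterministic and orientation-independent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    polygon = np.asarray(polygon, dtype=float)
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        if not np.any(crosses):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (x < x_int)
    return inside


def _polygon_area(polygon: np.ndarray) -> float:
    """Signed shoelace area."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def roi_polygon(
    landmarks: LandmarkSet, frame_size: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Palm quadrilateral through landmarks 1, 5, 17, 0 in pixel coordinates.

    Parameters
    ----------
    landmarks
        Normalized landmark set.
    frame_size
        (width, height) in pixels used to scale the normalized coordinates;
        the default leaves them in normalized units.

    Returns
    -------
    (4, 2) array of (x, y) vertices in cyclic order.

    Raises
    ------
    DegenerateROIError
        If the four points are (near-)collinear or coincident.
    """
    w, h = frame_size
    poly = landmarks.points[list(ROI_LANDMARK_INDICES)] * np.array([w, h], dtype=float)
    scale = max(1.0, float(w) * float(h))
    if abs(_polygon_area(poly)) <= 1e-9 * scale:
        raise DegenerateROIError("ROI landmarks are collinear or coincident")
    return poly


def _interior_mask(shape_hw: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centers fall inside the polygon.

    Pixel (row r, col c) has center (c + 0.5, r + 0.5) in 0-based pixel
    coordinates.
    """
    hh, ww = shape_hw
    cols, rows = np.meshgrid(np.arange(ww), np.arange(hh))
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    return points_in_polygon(centers, polygon).reshape(hh, ww)


def channel_means(
    frames: FrameSequence | np.ndarray,
    polygon: np.ndarray,
    fps: float | None = None,
) -> RGBTrace:
    """Per-frame arithmetic mean of each channel over the polygon interior.

    An empty frame sequence yields an empty trace (no error); a polygon with
    no interior pixel raises :class:`DegenerateROIError`.
    """
    if isinstance(frames, FrameSequence):
        fps = frames.fps if fps is None else fps
        arr = frames.frames
    else:
        arr = np.asarray(frames)
        if fps is None:
            raise InvalidArgumentError("fps required when frames is a bare array")
    if arr.shape[0] == 0:
        return RGBTrace(values=np.empty((0, 3)), fps=fps)
    mask = _interior_mask(arr.shape[1:3], polygon)
    if not mask.any():
        raise DegenerateROIError("polygon contains no pixel centers")
    vals = arr[:, mask, :].astype(float).mean(axis=1)
    return RGBTrace(values=vals, fps=fps)


def normalize_trace(trace: RGBTrace) -> RGBTrace:
    """Z-score each channel over the whole capture window.

    Uses the population standard deviation (divide by n), matching the
    centering/whitening convention of the ICA stage. A constant channel maps
    to all zeros.
    """
    if len(trace) < 2:
        raise InvalidArgumentError("normalization needs at least 2 frames")
    vals = trace.values
    centered = vals - vals.mean(axis=0)
    sd = vals.std(axis=0)  # population SD
    out = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return RGBTrace(values=out, fps=trace.fps)
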