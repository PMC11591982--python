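"""Peak/valley detection and the Epeak/Evalley features.

The blood-pressure formulas consume two scalars per measurement: the mean
retained peak intensity (Epeak) and the mean retained valley intensity
(Evalley) of the pulse wave. Extrema are found by strict 3-point
comparison (with plateau runs collapsed to their first sample, which
matters for 8-bit data), then a refractory filter discards any
peak/adjacent-trough pair closer than 0.25 s — scattered extrema from
perturbations — and finally a 10-window procedure averages one peak and
one valley value per 1-second window over a 10-second measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, NoBeatsError
from .synthetic_data import PulseTrace

__all__ = [
    "PeakValleySummary",
    "detect_extrema",
    "detect_peaks_valleys",
    "average_peaks",
    "average_valleys",
    "ten_window_summary",
]

#: minimum peak–trough spacing in seconds
DEFAULT_MIN_INTERVAL_S = 0.25


@dataclass(frozen=True)
class PeakValleySummary:
    """Retained extrema and their averages for one measurement.

    ``hd``/``hl`` are the retained peak/valley value sequences (sizes
    ``n1``/``n2``); ``e_peak``/``e_valley`` are the measurement features;
    ``windows_used`` counts the 1-second windows that contributed.
    """

    hd: np.ndarray
    hl: np.ndarray
    e_peak: float
    e_valley: float
    windows_used: int

    @property
    def n1(self) -> int:
        return int(self.hd.size)

    @property
    def n2(self) -> int:
        return int(self.hl.size)

    def to_dict(self) -> dict:
        return {
            "e_peak": self.e_peak,
            "e_valley": self.e_valley,
            "n1": self.n1,
            "n2": self.n2,
            "windows_used": self.windows_used,
        }


def _raw_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima/minima, plateaus collapsed.

    Equal-value runs are reduced to their first sample before the 3-point
    comparison, so a flat-topped peak still counts once.
    """
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # run-length collapse
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate([[0], change + 1])  # first index of each run
    vals = x[starts]
    if vals.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    mid = vals[1:-1]
    peaks = (mid > vals[:-2]) & (mid > vals[2:])
    valleys = (mid < vals[:-2]) & (mid < vals[2:])
    return starts[1:-1][peaks], starts[1:-1][valleys]


def _filter_extrema(
    x: np.ndarray,
    peak_idx: np.ndarray,
    valley_idx: np.ndarray,
    min_gap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Refractory filter: drop too-close peak/adjacent-trough pairs.

    Processing is greedy left-to-right: when an adjacent opposite-type pair
    is closer than ``min_gap`` samples, both members are discarded
    immediately (so a discarded member cannot veto a later, valid
    extremum). Same-type runs left behind by the removals are collapsed to
    their most extreme member. The two passes repeat until stable, which
    guarantees the output alternates and respects the spacing.
    """
    events = sorted(
        [(int(i), +1) for i in peak_idx] + [(int(i), -1) for i in valley_idx]
    )
    changed = True
    while changed and events:
        changed = False
        # pass 1: greedy removal of close opposite-type pairs
        kept: list[tuple[int, int]] = []
        for idx, kind in events:
            if kept and kept[-1][1] != kind and idx - kept[-1][0] < min_gap:
                kept.pop()
                changed = True
                continue
            kept.append((idx, kind))
        # pass 2: collapse same-type neighbours to the more extreme one
        collapsed: list[tuple[int, int]] = []
        for idx, kind in kept:
            if collapsed and collapsed[-1][1] == kind:
                prev_idx = collapsed[-1][0]
                better = x[idx] > x[prev_idx] if kind == +1 else x[idx] < x[prev_idx]
                if better:
                    collapsed[-1] = (idx, kind)
                changed = True
                continue
            collapsed.append((idx, kind))
        events = collapsed
    p = np.array([i for i, k in events if k == +1], dtype=int)
    v = np.array([i for i, k in events if k == -1], dtype=int)
    return p, v


def detect_extrema(
    trace: PulseTrace, min_interval_s: float = DEFAULT_MIN_INTERVAL_S
) -> tuple[np.ndarray, np.ndarray]:
    """Retained (peak_indices, valley_indices) after the refractory filter."""
    if min_interval_s < 0:
        raise InvalidArgumentError("min_interval_s must be non-negative")
    x = trace.samples
    peaks, valleys = _raw_extrema(x)
    min_gap = int(round(min_interval_s * trace.fps))
    if min_gap > 0:
        peaks, valleys = _filter_extrema(x, peaks, valleys, min_gap)
    return peaks, valleys


def detect_peaks_valleys(
    trace: PulseTrace, min_interval_s: float = DEFAULT_MIN_INTERVAL_S
) -> tuple[np.ndarray, np.ndarray]:
    """Retained peak and valley *values* (HD, HL) after filtering."""
    p, v = detect_extrema(trace, min_interval_s)
    return trace.samples[p], trace.samples[v]


def average_peaks(hd: np.ndarray) -> float:
    """Epeak: arithmetic mean of the retained peak values."""
    hd = np.asarray(hd, dtype=float)
    if hd.size == 0:
        raise NoBeatsError("no retained peaks to average")
    return float(hd.mean())


def average_valleys(hl: np.ndarray) -> float:
    """Evalley: arithmetic mean of the retained valley values."""
    hl = np.asarray(hl, dtype=float)
    if hl.size == 0:
        raise NoBeatsError("no retained valleys to average")
    return float(hl.mean())


def ten_window_summary(
    trace: PulseTrace,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
    n_windows: int = 10,
) -> PeakValleySummary:
    """Ten-window measurement procedure.

    The first ``n_windows`` seconds are split into consecutive 1-second
    windows. Per window, extrema are detected, filtered and averaged to one
    peak value and one valley value; the measurement features are the means
    of the per-window values. Windows yielding no surviving extrema are
    skipped; ``windows_used`` records how many actually contributed.
    """
    if n_windows < 1:
        raise InvalidArgumentError("n_windows must be >= 1")
    win = int(round(trace.fps))  # samples per 1-second window
    if len(trace) < n_windows * win:
        raise InvalidArgumentError(
            f"trace of {trace.duration:.2f} s is shorter than the "
            f"{n_windows} s measurement"
        )
    all_hd, all_hl = [], []
    win_peaks, win_valleys = [], []
    used = 0
    for w in range(n_windows):
        seg = trace.samples[w * win : (w + 1) * win]
        sub = PulseTrace(samples=seg, fps=trace.fps)
        hd, hl = detect_peaks_valleys(sub, min_interval_s)
        if hd.size or hl.size:
            used += 1
        if hd.size:
            all_hd.append(hd)
            win_peaks.append(hd.mean())
        if hl.size:
            all_hl.append(hl)
            win_valleys.append(hl.mean())
    if used == 0:
        raise NoBeatsError("no window produced any retained extremum")
    hd = np.concatenate(all_hd) if all_hd else np.empty(0)
    hl = np.concatenate(all_hl) if all_hl else np.empty(0)
    return PeakValleySummary(
        hd=hd,
        hl=hl,
        e_peak=float(np.mean(win_peaks)) if win_peaks else float("nan"),
        e_valley=float(np.mean(win_valleys)) if win_valleys else float("nan"),
        windows_used=used,
    )
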