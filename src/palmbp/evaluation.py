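"""Accuracy metrics and device-validation verdicts.

MAE, MAPE and RMSE against the reference device, mean ± SD of signed
errors with a normal-approximation 95% confidence interval, the AAMI
pass/fail criterion (mean absolute error <= 5 mmHg and error SD <= 8 mmHg)
and BHS-style letter grading from the cumulative percentages of absolute
errors within 5/10/15 mmHg.

The BHS thresholds (A: >= 60/85/95%, B: >= 50/75/90%, C: >= 40/65/85%) are
the published protocol values and are overridable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "MetricsReport",
    "mae",
    "mape",
    "rmse",
    "aami_check",
    "bhs_grade",
    "mean_ci",
    "summarize",
    "BHS_THRESHOLDS",
    "AAMI_MAE_LIMIT",
    "AAMI_SD_LIMIT",
]

AAMI_MAE_LIMIT = 5.0  # mmHg
AAMI_SD_LIMIT = 8.0  # mmHg

#: grade -> minimum cumulative % within (5, 10, 15) mmHg
BHS_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(predicted, dtype=float).ravel()
    if a.size == 0:
        raise InvalidArgumentError("empty input")
    if a.size != f.size:
        raise InvalidArgumentError(f"length mismatch: {a.size} vs {f.size}")
    return a, f


def mae(actual, predicted) -> float:
    """Mean absolute error (1/N) sum |A_i - F_i|."""
    a, f = _pair(actual, predicted)
    return float(np.mean(np.abs(a - f)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent."""
    a, f = _pair(actual, predicted)
    if np.any(a == 0):
        raise InvalidArgumentError("MAPE undefined: an actual value is zero")
    return float(np.mean(np.abs(a - f) / np.abs(a)) * 100.0)


def rmse(actual, predicted) -> float:
    """Root mean square error sqrt((1/N) sum (F_i - A_i)^2)."""
    a, f = _pair(actual, predicted)
    return float(np.sqrt(np.mean((f - a) ** 2)))


def aami_check(errors) -> tuple[str, float, float]:
    """AAMI verdict on signed errors: (``"PASS"|"FAIL"``, mae, sd).

    PASS requires mean |error| <= 5 mmHg and sample SD (n-1 denominator)
    <= 8 mmHg.
    """
    e = np.asarray(errors, dtype=float).ravel()
    if e.size < 2:
        raise InvalidArgumentError("AAMI check needs at least 2 errors")
    m = float(np.mean(np.abs(e)))
    sd = float(np.std(e, ddof=1))
    verdict = "PASS" if (m <= AAMI_MAE_LIMIT and sd <= AAMI_SD_LIMIT) else "FAIL"
    return verdict, m, sd


def bhs_grade(
    errors, thresholds: dict[str, tuple[float, float, float]] = BHS_THRESHOLDS
) -> tuple[str, tuple[float, float, float]]:
    """BHS letter grade and the cumulative percentages (P5, P10, P15)."""
    e = np.abs(np.asarray(errors, dtype=float).ravel())
    if e.size == 0:
        raise InvalidArgumentError("BHS grading needs at least 1 error")
    pcts = tuple(float(np.mean(e <= lim) * 100.0) for lim in (5.0, 10.0, 15.0))
    for grade in ("A", "B", "C"):
        if all(p >= t for p, t in zip(pcts, thresholds[grade])):
            return grade, pcts
    return "D", pcts


def mean_ci(values, z: float = 1.96) -> tuple[float, float, float]:
    """(mean, lo, hi): normal-approximation CI, mean ± z * SD / sqrt(n)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InvalidArgumentError("confidence interval needs n >= 2")
    m = float(np.mean(v))
    half = z * float(np.std(v, ddof=1)) / math.sqrt(v.size)
    return m, m - half, m + half


@dataclass(frozen=True)
class MetricsReport:
    """Full accuracy summary of predicted vs device pressures."""

    n: int
    mae: float
    mape: float
    rmse: float
    mean_error: float
    sd_error: float
    ci95_mean_error: tuple[float, float]
    aami: str
    aami_mae: float
    aami_sd: float
    bhs_grade: str
    bhs_percentages: tuple[float, float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95_mean_error"] = list(d["ci95_mean_error"])
        d["bhs_percentages"] = list(d["bhs_percentages"])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        d = dict(d)
        d["ci95_mean_error"] = tuple(d["ci95_mean_error"])
        d["bhs_percentages"] = tuple(d["bhs_percentages"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        return cls.from_dict(json.loads(s))


def summarize(actual, predicted) -> MetricsReport:
    """All metrics at once, on signed errors predicted - actual."""
    a, f = _pair(actual, predicted)
    errors = f - a
    verdict, a_mae, a_sd = aami_check(errors)
    grade, pcts = bhs_grade(errors)
    m, lo, hi = mean_ci(errors)
    return MetricsReport(
        n=int(a.size),
        mae=mae(a, f),
        mape=mape(a, f),
        rmse=rmse(a, f),
        mean_error=m,
        sd_error=float(np.std(errors, ddof=1)),
        ci95_mean_error=(lo, hi),
        aami=verdict,
        aami_mae=a_mae,
        aami_sd=a_sd,
        bhs_grade=grade,
        bhs_percentages=pcts,
    )
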