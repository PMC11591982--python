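"""Blood-pressure calibration and prediction.

Two estimator families map (pulse feature, BMI) to pressure in mmHg:

* the empirical formula ``BP = a0 + a1*x + BMI*(1 + a2*x)`` with ``x`` the
  Epeak feature for systolic pressure and Evalley for diastolic, its three
  coefficients fitted per BMI interval by the hybrid NM-PSO optimizer
  minimizing mean squared error against a cuff device;
* the multivariate linear regression ``BP = g0 + g1*BMI + g2*x``, fitted by
  ordinary least squares.

Both targets (SBP, DBP) are fitted independently. Coefficients are
scale-dependent on the preprocessing that produced the features, which is
why the pipeline layer binds them to a preprocessing fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidArgumentError,
    OutOfRangeError,
    SingularMatrixError,
)
from .nmpso import NMPSOConfig, nmpso_minimize
from .synthetic_data import SubjectRecord

__all__ = [
    "BPFormulaParams",
    "RegressionParams",
    "BMIRecord",
    "DEFAULT_BMI_INTERVALS",
    "FIT_X_BOUNDS",
    "compute_bmi",
    "formula_value",
    "predict_formula",
    "fit_nmpso",
    "fit_regression",
    "predict_regression",
    "bmi_interval_lookup",
]

#: BMI stratification (kg/m^2), Taiwanese MOHW convention; overridable.
DEFAULT_BMI_INTERVALS: tuple[tuple[float, float], ...] = (
    (10.0, 18.5),
    (18.5, 24.0),
    (24.0, 27.0),
    (27.0, 60.0),
)

#: coefficient search box for NM-PSO fitting — symmetric, because intercept
#: corrections can be negative
FIT_X_BOUNDS: tuple[float, float] = (-120.0, 120.0)


@dataclass(frozen=True)
class BPFormulaParams:
    """Empirical formula coefficients for one BMI interval and one target."""

    alpha0: float
    alpha1: float
    alpha2: float
    target: str = "SBP"  # "SBP" | "DBP"
    bmi_interval: tuple[float, float] = (10.0, 60.0)
    fit_mse: float | None = None

    def __post_init__(self) -> None:
        for a in (self.alpha0, self.alpha1, self.alpha2):
            if not np.isfinite(a):
                raise InvalidArgumentError("coefficients must be finite")
        if self.target not in ("SBP", "DBP"):
            raise InvalidArgumentError(f"target must be SBP or DBP, got {self.target!r}")
        lo, hi = self.bmi_interval
        if not hi > lo:
            raise InvalidArgumentError("bmi_interval must satisfy hi > lo")

    @property
    def alpha(self) -> tuple[float, float, float]:
        return (self.alpha0, self.alpha1, self.alpha2)


@dataclass(frozen=True)
class RegressionParams:
    """OLS coefficients BP = gamma0 + gamma1*BMI + gamma2*feature."""

    gamma0: float
    gamma1: float
    gamma2: float
    target: str = "SBP"

    def __post_init__(self) -> None:
        for g in (self.gamma0, self.gamma1, self.gamma2):
            if not np.isfinite(g):
                raise InvalidArgumentError("coefficients must be finite")
        if self.target not in ("SBP", "DBP"):
            raise InvalidArgumentError(f"target must be SBP or DBP, got {self.target!r}")

    @property
    def gamma(self) -> tuple[float, float, float]:
        return (self.gamma0, self.gamma1, self.gamma2)


@dataclass(frozen=True)
class BMIRecord:
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if not height > 0 or not weight > 0:
        raise InvalidArgumentError("height and weight must be positive")
    return weight / height**2


def formula_value(alpha, x, bmi):
    """Vectorized empirical formula: a0 + a1*x + BMI*(1 + a2*x).

    ``alpha`` is any 3-sequence or a :class:`BPFormulaParams`.
    """
    if isinstance(alpha, BPFormulaParams):
        alpha = alpha.alpha
    a0, a1, a2 = (float(a) for a in alpha)
    x = np.asarray(x, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    return a0 + a1 * x + bmi * (1.0 + a2 * x)


def predict_formula(x: float, bmi: float, params: BPFormulaParams) -> float:
    """Empirical-formula BP for one subject (x = Epeak for SBP, Evalley for DBP)."""
    return float(formula_value(params, x, bmi))


def _records_arrays(records: Sequence[SubjectRecord], target: str):
    bmi = np.array([r.bmi for r in records])
    if target == "SBP":
        x = np.array([r.e_peak for r in records])
        y = np.array([r.sbp_device for r in records])
    elif target == "DBP":
        x = np.array([r.e_valley for r in records])
        y = np.array([r.dbp_device for r in records])
    else:
        raise InvalidArgumentError(f"target must be SBP or DBP, got {target!r}")
    return x, bmi, y


def _check_identifiable(x: np.ndarray, bmi: np.ndarray, label: str) -> None:
    # the formula is linear in (a0, a1, a2) with design [1, x, x*bmi]
    design = np.column_stack([np.ones_like(x), x, x * bmi])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateFitError(
            f"{label}: design [1, x, x*BMI] is rank deficient "
            "(coefficients non-identifiable; features lack spread)"
        )


def fit_nmpso(
    records: Sequence[SubjectRecord],
    target: str,
    bmi_intervals: Sequence[tuple[float, float]] = DEFAULT_BMI_INTERVALS,
    config: NMPSOConfig | None = None,
    n_restarts: int = 3,
) -> list[BPFormulaParams]:
    """Fit the empirical formula per BMI interval with the hybrid optimizer.

    Fitness is the mean squared error between the formula output and the
    device reading over the interval's records (consistent with the RMSE
    reporting metric). Intervals containing no records are skipped;
    intervals with fewer than 3 records (3 unknowns) raise.

    The default configuration widens the search box to symmetric bounds
    and runs 300 iterations: the coefficient landscape is an
    ill-conditioned quadratic valley (the x and x*BMI regressors are
    highly correlated), which the simplex traverses slowly. The optimizer
    is restarted ``n_restarts`` times from seeds derived from the
    configured one, keeping the best run, since an unlucky initial swarm
    can collapse the simplex far from the optimum.
    """
    if config is None:
        config = NMPSOConfig(x_bounds=FIT_X_BOUNDS, n_iter=300)
    if n_restarts < 1:
        raise InvalidArgumentError("n_restarts must be >= 1")
    out: list[BPFormulaParams] = []
    for lo, hi in bmi_intervals:
        sub = [r for r in records if lo <= r.bmi < hi]
        if not sub:
            continue
        if len(sub) < 3:
            raise InsufficientDataError(
                f"BMI interval [{lo}, {hi}) has {len(sub)} record(s); need >= 3"
            )
        x, bmi, y = _records_arrays(sub, target)
        _check_identifiable(x, bmi, f"BMI interval [{lo}, {hi})")

        def mse(alpha: np.ndarray) -> float:
            resid = formula_value(alpha, x, bmi) - y
            return float(np.mean(resid**2))

        res = min(
            (
                nmpso_minimize(mse, n_dim=3, config=replace(config, seed=config.seed + 97 * j))
                for j in range(n_restarts)
            ),
            key=lambda r: r.f_best,
        )
        out.append(
            BPFormulaParams(
                alpha0=float(res.x_best[0]),
                alpha1=float(res.x_best[1]),
                alpha2=float(res.x_best[2]),
                target=target,
                bmi_interval=(float(lo), float(hi)),
                fit_mse=res.f_best,
            )
        )
    if not out:
        raise InsufficientDataError("no BMI interval contains any record")
    return out


def fit_regression(records: Sequence[SubjectRecord], target: str) -> RegressionParams:
    """OLS fit of BP = g0 + g1*BMI + g2*feature.

    Solved by a rank-revealing least-squares decomposition, mathematically
    equal to the normal equations ``(x'x)^-1 x'y``.
    """
    if len(records) < 3:
        raise InsufficientDataError(f"regression needs >= 3 records, got {len(records)}")
    x, bmi, y = _records_arrays(records, target)
    design = np.column_stack([np.ones_like(x), bmi, x])
    if np.linalg.matrix_rank(design) < 3:
        raise SingularMatrixError(
            "design [1, BMI, feature] is rank deficient (columns collinear)"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return RegressionParams(
        gamma0=float(beta[0]), gamma1=float(beta[1]), gamma2=float(beta[2]), target=target
    )


def predict_regression(bmi: float, e_value: float, params: RegressionParams) -> float:
    """Regression BP = gamma0 + gamma1*BMI + gamma2*feature."""
    return float(params.gamma0 + params.gamma1 * bmi + params.gamma2 * e_value)


def bmi_interval_lookup(
    bmi: float, table: Sequence[BPFormulaParams]
) -> BPFormulaParams:
    """Return the table entry whose half-open interval [lo, hi) contains bmi.

    A boundary value belongs to the upper interval. No extrapolation: a BMI
    outside every interval raises :class:`OutOfRangeError`.
    """
    if not table:
        raise InvalidArgumentError("empty parameter table")
    for params in sorted(table, key=lambda p: p.bmi_interval[0]):
        lo, hi = params.bmi_interval
        if lo <= bmi < hi:
            return params
    raise OutOfRangeError(f"BMI {bmi} outside all calibrated intervals")
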