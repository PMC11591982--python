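"""Blind and semi-blind source separation for pulse-wave denoising.

The normalized R/G/B traces are a linear mixture of the blood-volume pulse
with ambient-light and motion artifacts. This module implements the
standard FastICA chain — centering, eigenvalue whitening with a relative
noise-rejection threshold, deflationary fixed-point estimation — plus the
fast path when the mixing matrix is known (semi-blind: the unmixing matrix
is simply the pseudo-inverse), and a band-power rule to pick the component
that carries the cardiac pulse.

Notation: observed X (channels x samples), centered X̂ = X - E[X],
whitened Z = V X̂ with cov(Z) = I, unmixing rows W_i, components Y = W Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, NoSignalError, SingularMatrixError
from .synthetic_data import PulseTrace

__all__ = [
    "ICAConfig",
    "ICAResult",
    "center",
    "whiten",
    "fastica",
    "semiblind_unmix",
    "select_pulse_component",
]

#: physiologic heart-rate band, Hz (42–180 bpm)
DEFAULT_PULSE_BAND = (0.7, 3.0)


@dataclass(frozen=True)
class ICAConfig:
    """FastICA settings.

    ``contrast`` selects the nonlinearity G used in the fixed-point update:
    ``"logcosh"`` (g = tanh, the robust default) or ``"cube"`` (kurtosis
    based, g = u^3). ``var_threshold`` is the relative eigenvalue cutoff of
    the whitening step: components carrying less than that fraction of the
    total variance are treated as noise and dropped.
    """

    n_components: int = 3
    max_iter: int = 200
    tol: float = 1e-6
    var_threshold: float = 1e-6
    contrast: str = "logcosh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise InvalidArgumentError("n_components must be >= 1")
        if not self.tol > 0:
            raise InvalidArgumentError("tol must be positive")
        if not 0 <= self.var_threshold < 1:
            raise InvalidArgumentError("var_threshold must be in [0, 1)")
        if self.contrast not in ("logcosh", "cube"):
            raise InvalidArgumentError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class ICAResult:
    mean: np.ndarray  # E[X] per channel
    whitening: np.ndarray  # V, (retained, channels)
    whitened: np.ndarray = field(repr=False)  # Z
    unmixing: np.ndarray  # W, rows unit-norm
    components: np.ndarray = field(repr=False)  # Y = W Z
    n_iter: int = 0
    converged: bool = True


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each channel's mean; return (X̂, E[X])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise InvalidArgumentError("centering needs at least 2 samples per channel")
    mean = X.mean(axis=1, keepdims=True)
    return X - mean, mean.ravel()


def whiten(Xhat: np.ndarray, var_threshold: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue whitening with relative noise rejection.

    Eigenvectors of the sample covariance whose eigenvalue is below
    ``var_threshold`` times the total variance are dropped; the retained
    directions are rescaled to unit variance, so cov(Z) = I on them.
    """
    Xhat = np.atleast_2d(np.asarray(Xhat, dtype=float))
    n = Xhat.shape[1]
    cov = Xhat @ Xhat.T / n
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = float(eigval.sum())
    keep = eigval > max(var_threshold * total, 0.0)
    keep &= eigval > 0
    if not keep.any():
        raise NoSignalError("all variance rejected by whitening threshold")
    V = (eigvec[:, keep] / np.sqrt(eigval[keep])).T
    return V @ Xhat, V


def _contrast(name: str):
    if name == "logcosh":
        def g(u):
            return np.tanh(u)

        def g_prime(u):
            return 1.0 - np.tanh(u) ** 2
    else:  # cube
        def g(u):
            return u ** 3

        def g_prime(u):
            return 3.0 * u ** 2
    return g, g_prime


def fastica(Z: np.ndarray, config: ICAConfig = ICAConfig()) -> ICAResult:
    """Deflationary fixed-point FastICA on whitened data.

    One unit at a time, the fixed-point update
    ``w <- E[Z g(w'Z)] - E[g'(w'Z)] w`` is applied with Gram–Schmidt
    decorrelation against previously extracted rows and renormalization,
    until ``|<w_new, w_old>| > 1 - tol`` or ``max_iter`` is reached. A
    non-converged unit is reported through ``converged=False`` rather than
    raised, since partial separations are still usable downstream.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    d, n = Z.shape
    if config.n_components > d:
        raise InvalidArgumentError(
            f"n_components={config.n_components} exceeds {d} whitened dimensions"
        )
    g, g_prime = _contrast(config.contrast)
    rng = np.random.default_rng(config.seed)
    W = np.zeros((config.n_components, d))
    total_iter = 0
    converged = True
    for i in range(config.n_components):
        w = rng.standard_normal(d)
        w /= np.linalg.norm(w)
        unit_converged = False
        for _ in range(config.max_iter):
            total_iter += 1
            wx = w @ Z
            w_new = (Z * g(wx)).mean(axis=1) - g_prime(wx).mean() * w
            if i > 0:  # decorrelate against already-found rows
                w_new -= W[:i].T @ (W[:i] @ w_new)
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                w_new = rng.standard_normal(d)
                w_new /= np.linalg.norm(w_new)
            else:
                w_new /= nrm
            if abs(w_new @ w) > 1 - config.tol:
                w = w_new
                unit_converged = True
                break
            w = w_new
        W[i] = w
        converged &= unit_converged
    Y = W @ Z
    return ICAResult(
        mean=np.zeros(d),
        whitening=np.eye(d),
        whitened=Z,
        unmixing=W,
        components=Y,
        n_iter=total_iter,
        converged=converged,
    )


def run_ica(X: np.ndarray, config: ICAConfig = ICAConfig()) -> ICAResult:
    """Full chain on raw channels: center, whiten, FastICA.

    ``n_components`` is capped at the number of dimensions surviving the
    whitening threshold.
    """
    Xhat, mean = center(X)
    Z, V = whiten(Xhat, config.var_threshold)
    cfg = replace(config, n_components=min(config.n_components, Z.shape[0]))
    res = fastica(Z, cfg)
    return ICAResult(
        mean=mean,
        whitening=V,
        whitened=Z,
        unmixing=res.unmixing,
        components=res.components,
        n_iter=res.n_iter,
        converged=res.converged,
    )


def semiblind_unmix(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Unmix with a known mixing matrix: S_est = pinv(A) @ (X - E[X]).

    Exact (up to numerical precision) on noise-free mixtures.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularMatrixError("mixing matrix is rank deficient")
    Xhat, _ = center(X)
    return np.linalg.pinv(A) @ Xhat


def select_pulse_component(
    Y: np.ndarray,
    fps: float,
    band: tuple[float, float] = DEFAULT_PULSE_BAND,
) -> PulseTrace:
    """Pick the component with the largest band-power fraction in ``band``.

    The winner is sign-aligned so that its sharper excursions point upward
    (flip when mean(peaks) + mean(valleys) < 0), making peak/valley features
    comparable across captures.
    """
    from .pulse_features import detect_peaks_valleys

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 1 or Y.shape[1] < 2:
        raise InvalidArgumentError("need at least one component with >= 2 samples")
    lo, hi = band
    if not 0 <= lo < hi:
        raise InvalidArgumentError("band must satisfy 0 <= lo < hi")
    if hi >= fps / 2:
        raise InvalidArgumentError(
            f"band upper edge {hi} Hz at or above Nyquist ({fps / 2} Hz)"
        )
    freqs = np.fft.rfftfreq(Y.shape[1], d=1.0 / fps)
    power = np.abs(np.fft.rfft(Y - Y.mean(axis=1, keepdims=True), axis=1)) ** 2
    in_band = (freqs >= lo) & (freqs <= hi)
    total = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, power[:, in_band].sum(axis=1) / total, 0.0)
    best = Y[int(np.argmax(frac))]
    trace = PulseTrace(samples=best, fps=fps)
    hd, hl = detect_peaks_valleys(trace)
    if hd.size and hl.size and hd.mean() + hl.mean() < 0:
        trace = PulseTrace(samples=-best, fps=fps)
    return trace
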