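"""Hybrid Nelder–Mead / particle-swarm minimizer (NM-PSO).

For an N-dimensional problem the swarm holds 3N+1 particles. Each
iteration sorts particles by fitness, refines the best N+1 with one
Nelder–Mead simplex step (reflection / expansion / contraction / shrink),
then moves only the poorer 2N particles with the global-best PSO velocity
update. The simplex phase gives fast local convergence; the swarm phase
keeps enough diversity to escape local minima.

Default coefficients: reflection alpha=1, expansion gamma=2, contraction
beta=0.5, inertia w=0.5, acceleration c1=c2=1.5, 100 iterations, speed and
position bounded by 120. The position box is overridable because fitted
blood-pressure coefficients may need negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, ObjectiveError

__all__ = [
    "NMPSOConfig",
    "Particle",
    "SimplexState",
    "NMPSOResult",
    "nm_step",
    "pso_step",
    "nmpso_minimize",
]


@dataclass(frozen=True)
class NMPSOConfig:
    """Optimizer settings.

    ``n_particles`` defaults to 3N+1 for problem dimension N when left as
    ``None``. ``v_bounds=(0, 120)`` is read as a speed-magnitude clamp
    ``|v| <= 120`` per dimension; a hard v >= 0 would forbid leftward
    motion. ``x_bounds`` is a per-dimension position box.
    """

    alpha: float = 1.0  # reflection
    gamma: float = 2.0  # expansion
    beta: float = 0.5  # contraction
    w: float = 0.5  # inertia weight
    c1: float = 1.5
    c2: float = 1.5
    n_particles: int | None = None
    n_iter: int = 100
    v_bounds: tuple[float, float] = (0.0, 120.0)
    x_bounds: tuple[float, float] = (0.0, 120.0)
    seed: int = 0
    shrink: float = 0.5  # canonical Nelder–Mead sigma
    spread_tol: float = 1e-10  # early-stop fitness spread

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ConfigurationError("reflection alpha must be positive")
        if not self.gamma > self.alpha:
            raise ConfigurationError("expansion gamma must exceed alpha")
        if not 0 < self.beta < 1:
            raise ConfigurationError("contraction beta must be in (0, 1)")
        if self.n_particles is not None and self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        if self.v_bounds[1] < self.v_bounds[0] or self.x_bounds[1] <= self.x_bounds[0]:
            raise ConfigurationError("bounds must be ordered")

    @property
    def v_max(self) -> float:
        return float(self.v_bounds[1])


@dataclass
class Particle:
    """Position, velocity and personal best of one swarm member."""

    x: np.ndarray
    v: np.ndarray
    f: float
    pbest: np.ndarray
    pbest_f: float


@dataclass(frozen=True)
class SimplexState:
    """N+1 simplex vertices with fitness, sorted ascending.

    ``best`` (Pl), ``second`` (Ps, the second-best in this scheme's usage)
    and ``worst`` (Ph) index the sorted vertex list.
    """

    vertices: np.ndarray  # (N+1, N)
    fitness: np.ndarray  # (N+1,)

    def __post_init__(self) -> None:
        verts = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        fit = np.asarray(self.fitness, dtype=float)
        if verts.shape[0] != verts.shape[1] + 1:
            raise ConfigurationError(
                f"a simplex in R^{verts.shape[1]} needs {verts.shape[1] + 1} vertices"
            )
        order = np.argsort(fit, kind="stable")
        object.__setattr__(self, "vertices", verts[order])
        object.__setattr__(self, "fitness", fit[order])

    @property
    def best(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def second(self) -> np.ndarray:
        return self.vertices[1]

    @property
    def worst(self) -> np.ndarray:
        return self.vertices[-1]


def _eval(f: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    val = float(f(np.asarray(x, dtype=float)))
    if not np.isfinite(val):
        raise ObjectiveError(f"objective returned non-finite value {val} at {x}")
    return val


def nm_step(
    simplex: SimplexState,
    f: Callable[[np.ndarray], float],
    config: NMPSOConfig = NMPSOConfig(),
) -> SimplexState:
    """One Nelder–Mead iteration on a sorted simplex.

    Reflect the worst vertex Ph through the centroid of the rest; expand if
    the reflection beats the best vertex Pl (keeping the better of the
    two); accept the reflection outright if it beats the second-best Ps;
    otherwise contract toward Ph, and if even that fails to improve on Ph,
    shrink every non-best vertex halfway toward Pl.
    """
    verts, fit = simplex.vertices, simplex.fitness
    centroid = verts[:-1].mean(axis=0)
    x_r = centroid + config.alpha * (centroid - verts[-1])
    f_r = _eval(f, x_r)
    if f_r < fit[0]:
        x_e = centroid + config.gamma * (x_r - centroid)
        f_e = _eval(f, x_e)
        new_x, new_f = (x_e, f_e) if f_e < f_r else (x_r, f_r)
        verts, fit = verts.copy(), fit.copy()
        verts[-1], fit[-1] = new_x, new_f
    elif f_r < fit[1]:
        verts, fit = verts.copy(), fit.copy()
        verts[-1], fit[-1] = x_r, f_r
    else:
        x_c = centroid + config.beta * (verts[-1] - centroid)
        f_c = _eval(f, x_c)
        if f_c < fit[-1]:
            verts, fit = verts.copy(), fit.copy()
            verts[-1], fit[-1] = x_c, f_c
        else:  # shrink all but the best toward Pl
            verts = verts.copy()
            verts[1:] = verts[0] + config.shrink * (verts[1:] - verts[0])
            fit = np.array([fit[0]] + [_eval(f, v) for v in verts[1:]])
    return SimplexState(vertices=verts, fitness=fit)


def pso_step(
    particles: Sequence[Particle],
    gbest: np.ndarray,
    config: NMPSOConfig,
    rng: np.random.Generator,
    f: Callable[[np.ndarray], float] | None = None,
) -> list[Particle]:
    """Global-best PSO velocity/position update, in place on copies.

    ``v <- w v + rand1 c1 (Pbest - x) + rand2 c2 (Gbest - x)`` with fresh
    uniforms per particle per dimension, velocity magnitude clamped to
    ``v_bounds[1]``, position clamped to ``x_bounds``. When ``f`` is given
    the new positions are evaluated and personal bests refreshed.
    """
    gbest = np.asarray(gbest, dtype=float)
    out: list[Particle] = []
    lo, hi = config.x_bounds
    for p in particles:
        r1 = rng.random(p.x.shape)
        r2 = rng.random(p.x.shape)
        v = (
            config.w * p.v
            + r1 * config.c1 * (p.pbest - p.x)
            + r2 * config.c2 * (gbest - p.x)
        )
        v = np.clip(v, -config.v_max, config.v_max)
        x = np.clip(p.x + v, lo, hi)
        fx = _eval(f, x) if f is not None else p.f
        q = Particle(x=x, v=v, f=fx, pbest=p.pbest.copy(), pbest_f=p.pbest_f)
        if f is not None and fx < q.pbest_f:
            q.pbest, q.pbest_f = x.copy(), fx
        out.append(q)
    return out


@dataclass(frozen=True)
class NMPSOResult:
    x_best: np.ndarray
    f_best: float
    history: np.ndarray = field(repr=False)  # best fitness per iteration
    n_particles: int = 0
    n_iter: int = 0


def nmpso_minimize(
    f: Callable[[np.ndarray], float],
    n_dim: int,
    config: NMPSOConfig = NMPSOConfig(),
) -> NMPSOResult:
    """Minimize ``f`` over the position box with the hybrid scheme.

    3N+1 particles are initialized uniformly in the box (seeded). Each
    iteration sorts particles by fitness, applies one Nelder–Mead step to
    the simplex formed by the best N+1 (their velocities reset to zero when
    moved), then applies the PSO update to the poorer 2N only. Stops early
    when the fitness spread over all particles falls below ``spread_tol``.
    """
    if n_dim < 1:
        raise ConfigurationError("n_dim must be >= 1")
    n_particles = config.n_particles or 3 * n_dim + 1
    if n_particles < n_dim + 2:
        raise ConfigurationError(
            f"need at least {n_dim + 2} particles for an N+1 simplex plus one"
        )
    rng = np.random.default_rng(config.seed)
    lo, hi = config.x_bounds
    xs = rng.uniform(lo, hi, size=(n_particles, n_dim))
    particles = []
    for x in xs:
        fx = _eval(f, x)
        particles.append(
            Particle(x=x, v=np.zeros(n_dim), f=fx, pbest=x.copy(), pbest_f=fx)
        )
    history = []
    it = 0
    for it in range(1, config.n_iter + 1):
        particles.sort(key=lambda p: p.f)  # stable: ties by current order
        # Nelder–Mead phase on the best N+1
        elite = particles[: n_dim + 1]
        simplex = SimplexState(
            vertices=np.array([p.x for p in elite]),
            fitness=np.array([p.f for p in elite]),
        )
        simplex = nm_step(simplex, f, config)
        for p, x, fx in zip(elite, simplex.vertices, simplex.fitness):
            if not np.array_equal(p.x, x):
                p.v = np.zeros(n_dim)  # no velocity rule for NM moves
            x_in = np.clip(x, lo, hi)
            if not np.array_equal(x_in, x):  # clipped point needs a fresh fitness
                fx = _eval(f, x_in)
            p.x, p.f = x_in, fx
            if fx < p.pbest_f:
                p.pbest, p.pbest_f = p.x.copy(), fx
        # PSO phase on the poorer 2N, attracted to the global best
        gbest_p = min(particles, key=lambda p: p.pbest_f)
        tail = pso_step(particles[n_dim + 1 :], gbest_p.pbest, config, rng, f)
        particles = particles[: n_dim + 1] + tail
        fits = np.array([p.f for p in particles])
        history.append(float(min(p.pbest_f for p in particles)))
        if fits.max() - fits.min() < config.spread_tol:
            break
    best = min(particles, key=lambda p: p.pbest_f)
    return NMPSOResult(
        x_best=best.pbest.copy(),
        f_best=float(best.pbest_f),
        history=np.array(history),
        n_particles=n_particles,
        n_iter=it,
    )
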