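"""Hybrid Nelder–Mead / particle-swarm optimizer."""

import numpy as np
import pytest

from palmbp.errors import ConfigurationError, ObjectiveError
from palmbp.nmpso import NMPSOConfig, Particle, SimplexState, nm_step, nmpso_minimize, pso_step


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def rosenbrock(x):
    x = np.asarray(x)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


BOX = dict(x_bounds=(-5.0, 5.0), v_bounds=(0.0, 5.0))


class _ForcedRandoms:
    """Stub generator returning a fixed value from random()."""

    def __init__(self, value):
        self.value = value

    def random(self, shape):
        return np.full(shape, self.value)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(alpha=0.0),
            dict(gamma=0.5),  # must exceed alpha=1
            dict(beta=1.5),
            dict(n_iter=0),
            dict(x_bounds=(1.0, 1.0)),
        ],
    )
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            NMPSOConfig(**kw)


class TestNMStep:
    def test_hand_computed_reflection_on_sphere(self):
        # worst vertex (1,1) reflects through centroid (0.5,0.5) to (0,0),
        # f=0 beats the best so expansion (-0.5,-0.5) is tried (f=0.5) and
        # the reflection is kept
        simplex = SimplexState(
            vertices=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            fitness=np.array([1.0, 1.0, 2.0]),
        )
        out = nm_step(simplex, sphere)
        assert np.allclose(out.best, [0.0, 0.0])
        assert out.fitness[0] == pytest.approx(0.0)

    def test_degenerate_simplex_is_a_fixed_point(self):
        pt = np.array([2.0, 3.0])
        simplex = SimplexState(
            vertices=np.tile(pt, (3, 1)), fitness=np.full(3, sphere(pt))
        )
        out = nm_step(simplex, sphere)
        assert np.allclose(out.vertices, simplex.vertices)

    def test_best_fitness_never_degrades(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            verts = rng.uniform(-3, 3, size=(4, 3))
            fit = np.array([sphere(v) for v in verts])
            simplex = SimplexState(vertices=verts, fitness=fit)
            out = nm_step(simplex, sphere)
            assert out.fitness[0] <= simplex.fitness[0] + 1e-15

    def test_nan_objective_raises(self):
        simplex = SimplexState(
            vertices=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            fitness=np.array([1.0, 1.0, 2.0]),
        )
        with pytest.raises(ObjectiveError):
            nm_step(simplex, lambda x: float("nan"))


class TestPSOStep:
    def test_stationary_at_consensus(self):
        x = np.array([1.0, 2.0])
        p = Particle(x=x.copy(), v=np.zeros(2), f=sphere(x), pbest=x.copy(), pbest_f=sphere(x))
        cfg = NMPSOConfig(**BOX)
        (q,) = pso_step([p], gbest=x, config=cfg, rng=_ForcedRandoms(1.0))
        assert np.allclose(q.v, 0) and np.allclose(q.x, x)

    def test_hand_computed_update_with_forced_randoms(self):
        # w=0.5, c1=c2=1.5, v=0, x=2, pbest=2, gbest=0, rand=1:
        # v = 0 + 0 + 1*1.5*(0-2) = -3; x = 2-3 = -1, clamped to 0
        cfg = NMPSOConfig(w=0.5, c1=1.5, c2=1.5, x_bounds=(0.0, 120.0), v_bounds=(0.0, 120.0))
        p = Particle(
            x=np.array([2.0]), v=np.zeros(1), f=4.0, pbest=np.array([2.0]), pbest_f=4.0
        )
        (q,) = pso_step([p], gbest=np.array([0.0]), config=cfg, rng=_ForcedRandoms(1.0))
        assert q.v[0] == pytest.approx(-3.0)
        assert q.x[0] == pytest.approx(0.0)  # clamped at the lower bound

    def test_zero_randoms_leave_only_inertia(self):
        cfg = NMPSOConfig(**BOX)
        p = Particle(
            x=np.array([1.0, -1.0]),
            v=np.array([0.4, -0.2]),
            f=2.0,
            pbest=np.array([0.0, 0.0]),
            pbest_f=0.0,
        )
        (q,) = pso_step([p], gbest=np.zeros(2), config=cfg, rng=_ForcedRandoms(0.0))
        assert np.allclose(q.v, cfg.w * np.array([0.4, -0.2]))
        assert np.allclose(q.x, p.x + q.v)

    def test_velocity_magnitude_clamped(self):
        cfg = NMPSOConfig(x_bounds=(-100.0, 100.0), v_bounds=(0.0, 1.0))
        p = Particle(
            x=np.array([50.0]), v=np.zeros(1), f=0.0, pbest=np.array([50.0]), pbest_f=0.0
        )
        (q,) = pso_step([p], gbest=np.array([-50.0]), config=cfg, rng=_ForcedRandoms(1.0))
        assert abs(q.v[0]) <= 1.0

    def test_matches_reference_global_best_pso(self):
        # same update equations written independently, same random stream
        cfg = NMPSOConfig(**BOX, seed=0)
        rng_a = np.random.default_rng(123)
        rng_b = np.random.default_rng(123)
        xs = np.random.default_rng(5).uniform(-5, 5, size=(6, 2))
        particles = [
            Particle(x=x.copy(), v=np.zeros(2), f=sphere(x), pbest=x.copy(), pbest_f=sphere(x))
            for x in xs
        ]
        gbest = min(particles, key=lambda p: p.pbest_f).pbest.copy()
        ref_x, ref_v = xs.copy(), np.zeros_like(xs)
        ref_pbest = xs.copy()
        for _ in range(5):
            particles = pso_step(particles, gbest, cfg, rng_a, f=sphere)
            for i in range(len(ref_x)):
                r1, r2 = rng_b.random(2), rng_b.random(2)
                ref_v[i] = (
                    cfg.w * ref_v[i]
                    + r1 * cfg.c1 * (ref_pbest[i] - ref_x[i])
                    + r2 * cfg.c2 * (gbest - ref_x[i])
                )
                ref_v[i] = np.clip(ref_v[i], -cfg.v_max, cfg.v_max)
                ref_x[i] = np.clip(ref_x[i] + ref_v[i], *cfg.x_bounds)
                if sphere(ref_x[i]) < sphere(ref_pbest[i]):
                    ref_pbest[i] = ref_x[i].copy()
            gbest = min(
                (p for p in particles), key=lambda p: p.pbest_f
            ).pbest.copy()
            assert np.allclose(np.array([p.x for p in particles]), ref_x)


class TestMinimize:
    def test_three_n_plus_one_particles(self):
        res = nmpso_minimize(sphere, 3, NMPSOConfig(seed=0, n_iter=5, **BOX))
        assert res.n_particles == 10

    def test_sphere_reaches_global_minimum(self):
        res = nmpso_minimize(sphere, 2, NMPSOConfig(seed=0, n_iter=100, **BOX))
        assert res.f_best <= 1e-6

    def test_rosenbrock_best_of_five_seeds(self):
        best = min(
            nmpso_minimize(
                rosenbrock, 2, NMPSOConfig(seed=s, n_iter=300, **BOX)
            ).f_best
            for s in range(5)
        )
        assert best <= 1e-3

    def test_history_is_monotone_non_increasing(self):
        res = nmpso_minimize(rosenbrock, 2, NMPSOConfig(seed=1, n_iter=60, **BOX))
        assert np.all(np.diff(res.history) <= 1e-15)

    def test_best_position_stays_inside_bounds(self):
        # shifted sphere pulls the optimum to the corner of the box
        f = lambda x: sphere(np.asarray(x) - 10.0)  # noqa: E731
        res = nmpso_minimize(f, 2, NMPSOConfig(seed=2, n_iter=50, **BOX))
        assert np.all(res.x_best >= -5.0) and np.all(res.x_best <= 5.0)
        assert np.allclose(res.x_best, [5.0, 5.0], atol=1e-6)

    def test_deterministic_given_seed(self):
        a = nmpso_minimize(rosenbrock, 2, NMPSOConfig(seed=3, n_iter=50, **BOX))
        b = nmpso_minimize(rosenbrock, 2, NMPSOConfig(seed=3, n_iter=50, **BOX))
        assert a.f_best == b.f_best
        assert np.array_equal(a.x_best, b.x_best)
        assert np.array_equal(a.history, b.history)

    def test_pure_nelder_mead_loop_agrees_with_scipy(self):
        # with the whole set as simplex and no swarm phase, repeated nm_step
        # is plain Nelder-Mead; compare final fitness against scipy's
        from scipy.optimize import minimize

        rng = np.random.default_rng(0)
        verts = rng.uniform(-3, 3, size=(3, 2))
        simplex = SimplexState(
            vertices=verts, fitness=np.array([sphere(v) for v in verts])
        )
        for _ in range(200):
            simplex = nm_step(simplex, sphere)
        ref = minimize(
            sphere,
            verts[0],
            method="Nelder-Mead",
            options={"initial_simplex": verts, "xatol": 1e-12, "fatol": 1e-12},
        )
        assert abs(simplex.fitness[0] - ref.fun) <= 1e-6
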