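"""Trap force, work accumulation, Jarzynski estimators and PMF curves."""

import numpy as np
import pytest

from ifacedyn import (
    BrownianPullSpec,
    K_BOLTZMANN,
    PullingProtocol,
    PullingRecord,
    ReplicaEnsemble,
    Structure,
    Trajectory,
    accumulate_work,
    build_spring_network,
    force_distance_profile,
    jarzynski_delta_f,
    pmf_curve,
    pull_direction,
    simulate_brownian_pull,
    trap_force,
)
from ifacedyn.structure_io import Atom

KT300 = K_BOLTZMANN * 300.0


def _protocol(**kw):
    kw.setdefault("pull_velocity", 10.0)
    kw.setdefault("spring_constant", 10.0)
    return PullingProtocol(**kw)


class TestTrapForce:
    def test_zero_at_start(self):
        assert trap_force(_protocol(), 0.0, 0.0, x0=0.0) == 0.0

    def test_direct_evaluation(self):
        # trap moved 1 Å ahead of a stationary coordinate: F = 10·1.0
        assert trap_force(_protocol(), 0.1, 0.0, x0=0.0) == pytest.approx(10.0)

    def test_zero_when_tracking(self):
        proto = _protocol()
        t = 0.37
        assert trap_force(proto, t, proto.pull_velocity * t, x0=0.0) == pytest.approx(0.0)

    def test_direction_normalised(self):
        proto = PullingProtocol(direction=np.array([3.0, 4.0, 0.0]))
        assert np.linalg.norm(proto.direction) == pytest.approx(1.0, abs=1e-12)


class TestAccumulateWork:
    def test_constant_force_rectangle(self):
        times = np.linspace(0.0, 1.0, 11)
        w = accumulate_work(times, np.full(11, 3.0), pull_velocity=2.0)
        # trap displacement d = v·t = 2 Å -> W = F·d = 6
        assert w[-1] == pytest.approx(6.0)
        assert w[0] == 0.0

    def test_linear_force_triangle(self):
        times = np.linspace(0.0, 1.0, 101)
        forces = 8.0 * times
        w = accumulate_work(times, forces, pull_velocity=2.0)
        assert w[-1] == pytest.approx(8.0 * 2.0 / 2.0)

    def test_smooth_force_matches_closed_form(self):
        """Dense trapezoid vs the analytic integral of F(t) = 2 + sin(t)."""
        times = np.linspace(0.0, 2.0, 200_001)
        v = 3.0
        w = accumulate_work(times, 2.0 + np.sin(times), v)
        exact = v * (2.0 * 2.0 + (1.0 - np.cos(2.0)))
        assert w[-1] == pytest.approx(exact, rel=1e-8)

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1, 51))
        forces = rng.normal(size=51)
        w_full = accumulate_work(times, forces, 1.5)
        w_head = accumulate_work(times[:26], forces[:26], 1.5)
        w_tail = accumulate_work(times[25:], forces[25:], 1.5)
        assert w_full[-1] == pytest.approx(w_head[-1] + w_tail[-1], rel=1e-12)

    def test_non_monotonic_times_rejected(self):
        with pytest.raises(ValueError):
            accumulate_work(np.array([0.0, 1.0, 0.5]), np.zeros(3), 1.0)


class TestJarzynski:
    def test_zero_variance_returns_common_work(self):
        works = np.full(12, 7.25)
        for method in ("cumulant2", "exponential"):
            assert jarzynski_delta_f(works, 300.0, method) == pytest.approx(7.25)

    def test_two_point_closed_form(self):
        works = np.array([0.0, 2.0 * KT300] * 6)
        # mean kT, population variance kT² -> cumulant kT − kT/2
        assert jarzynski_delta_f(works, 300.0, "cumulant2") == pytest.approx(
            KT300 / 2.0, rel=1e-12
        )
        exact = -KT300 * np.log((1.0 + np.exp(-2.0)) / 2.0)
        assert jarzynski_delta_f(works, 300.0, "exponential") == pytest.approx(
            exact, rel=1e-12
        )

    def test_gaussian_closed_form(self):
        """Gaussian work with σ² = 2·k_B·T·(1 kcal/mol): ΔF = μ − σ²/(2k_BT)."""
        rng = np.random.default_rng(123)
        mu, var = 5.0, 2.0 * KT300
        works = rng.normal(mu, np.sqrt(var), 100_000)
        expected = mu - 1.0
        assert jarzynski_delta_f(works, 300.0, "cumulant2") == pytest.approx(
            expected, abs=0.05
        )
        assert jarzynski_delta_f(works, 300.0, "exponential") == pytest.approx(
            expected, abs=0.05
        )

    def test_few_replicas_warns_not_errors(self):
        with pytest.warns(UserWarning, match="replicas"):
            jarzynski_delta_f(np.array([1.0, 2.0, 3.0]), 300.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_delta_f(np.array([1.0]), 300.0)


def _deterministic_record(replica_id=0):
    proto = _protocol()
    times = np.linspace(0.0, 1.0, 101)
    forces = 2.0 * times
    work = accumulate_work(times, forces, proto.pull_velocity)
    return PullingRecord(times=times, positions=proto.pull_velocity * times,
                         forces=forces, work=work, replica_id=replica_id), proto


class TestPMFCurve:
    def test_single_replica_equals_work(self):
        rec, proto = _deterministic_record()
        with pytest.warns(UserWarning):
            ens = ReplicaEnsemble(records=[rec, rec], protocol=proto)
        curve = pmf_curve(ens)
        np.testing.assert_allclose(curve.delta_f, rec.work, atol=1e-12)
        np.testing.assert_allclose(curve.delta_f_exp, rec.work, atol=1e-10)

    def test_starts_at_zero(self):
        spec = BrownianPullSpec(n_replicas=10, seed=0, dt=1e-4,
                                protocol=_protocol(duration=0.1))
        ens, _ = simulate_brownian_pull(spec)
        curve = pmf_curve(ens)
        assert curve.lam[0] == 0.0 and curve.delta_f[0] == 0.0

    def test_jarzynski_bound_and_replica_permutation(self):
        spec = BrownianPullSpec(potential=("harmonic", 2.0), n_replicas=16, seed=3,
                                dt=1e-4, protocol=_protocol(duration=0.5))
        ens, _ = simulate_brownian_pull(spec)
        curve = pmf_curve(ens)
        assert np.all(curve.delta_f <= curve.mean_work + 1e-9)
        shuffled = ReplicaEnsemble(records=list(reversed(ens.records)),
                                   protocol=ens.protocol)
        curve2 = pmf_curve(shuffled)
        np.testing.assert_allclose(curve2.delta_f, curve.delta_f, rtol=1e-12)
        np.testing.assert_allclose(curve2.delta_f_exp, curve.delta_f_exp, rtol=1e-12)

    def test_lambda_max_truncates(self):
        rec, proto = _deterministic_record()
        with pytest.warns(UserWarning):
            ens = ReplicaEnsemble(records=[rec, rec], protocol=proto)
        curve = pmf_curve(ens, lambda_max=5.0)
        assert curve.lam[-1] <= 5.0 < proto.pull_velocity * rec.times[-1]

    def test_grid_mismatch_rejected(self):
        rec, proto = _deterministic_record()
        other = PullingRecord(times=rec.times + 0.5, positions=rec.positions,
                              forces=rec.forces, work=rec.work, replica_id=1)
        with pytest.raises(ValueError, match="grid"):
            ReplicaEnsemble(records=[rec, other], protocol=proto)

    def test_estimator_error_shrinks_with_velocity(self):
        """Composite-harmonic recovery improves as pulling slows down."""
        truth = 1.0 * 10.0 * 4.0 / (2.0 * 11.0)   # κkλ²/(2(κ+k)) at λ = 2
        errors = []
        for v, dur in ((4.0, 0.5), (1.0, 2.0), (0.1, 20.0)):
            errs = []
            for seed in (21, 22, 23):
                spec = BrownianPullSpec(
                    potential=("harmonic", 1.0), n_replicas=50, seed=seed,
                    dt=2e-4, record_stride=50,
                    protocol=_protocol(pull_velocity=v, duration=dur),
                )
                ens, _ = simulate_brownian_pull(spec)
                curve = pmf_curve(ens)
                i = int(np.argmin(np.abs(curve.lam - 2.0)))
                errs.append(abs(curve.delta_f[i] - truth))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]
        assert errors[1] < errors[0]


class TestForceDistanceProfile:
    def _marker_structure(self):
        atoms = [
            Atom(1, "CA", "C", 591, "LYS", "A", [0.0, 0.0, 0.0]),
            Atom(2, "CA", "C", 595, "ARG", "A", [6.0, 0.0, 0.0]),
        ]
        return Structure(atoms)

    def test_static_trajectory_zero_distance(self):
        s = self._marker_structure()
        rec, proto = _deterministic_record()
        frames = np.broadcast_to(s.coords, (rec.times.size, 2, 3)).copy()
        traj = Trajectory(list(s.atoms), frames)
        with pytest.warns(UserWarning):
            ens = ReplicaEnsemble(records=[rec, rec], protocol=proto)
        profile = force_distance_profile(ens, [traj, traj], "A")
        assert np.all(profile["distance_A"] == 0.0)

    def test_rigid_translation_gives_displacement_norm(self):
        s = self._marker_structure()
        rec, proto = _deterministic_record()
        n = rec.times.size
        u = np.outer(np.linspace(0, 3.0, n), np.array([0.6, 0.8, 0.0]))
        frames = np.broadcast_to(s.coords, (n, 2, 3)) + u[:, None, :]
        traj = Trajectory(list(s.atoms), frames)
        with pytest.warns(UserWarning):
            ens = ReplicaEnsemble(records=[rec, rec], protocol=proto)
        profile = force_distance_profile(ens, [traj, traj], "A")
        np.testing.assert_allclose(
            profile["distance_A"], np.linalg.norm(u, axis=1), atol=1e-12
        )

    def test_replica_average_matches_hand_construction(self):
        s = self._marker_structure()
        proto = _protocol()
        times = np.linspace(0.0, 1.0, 11)
        records, trajs, dists = [], [], []
        rng = np.random.default_rng(8)
        for r in range(10):
            slope = float(rng.uniform(0.5, 2.0))
            forces = np.full_like(times, float(rng.uniform(1, 3)))
            work = accumulate_work(times, forces, proto.pull_velocity)
            records.append(PullingRecord(times=times, positions=times, forces=forces,
                                         work=work, replica_id=r))
            u = np.outer(slope * times, np.array([0.0, 0.0, 1.0]))
            frames = np.broadcast_to(s.coords, (11, 2, 3)) + u[:, None, :]
            trajs.append(Trajectory(list(s.atoms), frames))
            dists.append(slope * times)
        ens = ReplicaEnsemble(records=records, protocol=proto)
        profile = force_distance_profile(ens, trajs, "A")
        np.testing.assert_allclose(profile["distance_A"], np.mean(dists, axis=0),
                                   atol=1e-12)
        np.testing.assert_allclose(
            profile["force_kcal_mol_A"],
            np.mean([r.forces for r in records], axis=0), atol=1e-12,
        )

    def test_pull_direction_from_markers(self):
        s = self._marker_structure()
        d = pull_direction(s, "A", residue_from=595, residue_to=591)
        np.testing.assert_allclose(d, [-1.0, 0.0, 0.0], atol=1e-12)


class TestSpringNetwork:
    def _chain(self, xs):
        return Structure([
            Atom(i + 1, "CA", "C", 604 + i, "GLY", "A", [x, 0.0, 0.0])
            for i, x in enumerate(xs)
        ])

    def test_collinear_example(self):
        net = build_spring_network(self._chain([0.0, 5.0, 11.0]), "A")
        assert len(net) == 2
        np.testing.assert_allclose(sorted(net.rest_lengths), [5.0, 6.0])

    def test_boundary_inclusive(self):
        net = build_spring_network(self._chain([0.0, 7.0]), "A")
        assert len(net) == 1

    def test_too_few_calpha_rejected(self):
        with pytest.raises(ValueError):
            build_spring_network(self._chain([0.0]), "A")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        import math

        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 25, size=(50, 3))
        s = Structure([
            Atom(i + 1, "CA", "C", 604 + i, "GLY", "A", p)
            for i, p in enumerate(pts)
        ])
        net = build_spring_network(s, "A")
        expected = {
            (i, j)
            for i in range(50)
            for j in range(i + 1, 50)
            if math.dist(pts[i], pts[j]) <= 7.0
        }
        assert {tuple(sorted(p)) for p in net.pairs} == expected
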