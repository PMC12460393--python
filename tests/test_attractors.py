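"""Directed Hausdorff distances and attractor estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fatedyn as fd
from fatedyn.attractors import (NonautonomousSetFibres, PointCloudSet,
                                directed_hausdorff, estimate_global_attractor,
                                forward_convergence, pullback_convergence,
                                random_pullback_estimate, transient_length)
from fatedyn.core import AutonomousSystem, Process
from fatedyn.driving import SymbolSequence
from fatedyn.timesets import TimeStructure


def brute_force_directed_hausdorff(V, W):
    """Independent double-loop oracle."""
    best_outer = 0.0
    for v in V:
        best_inner = min(float(np.linalg.norm(np.asarray(v) - np.asarray(w))) for w in W)
        best_outer = max(best_outer, best_inner)
    return best_outer


class TestDirectedHausdorff:
    def test_distance_to_self_is_zero(self):
        V = PointCloudSet(np.random.default_rng(0).uniform(size=(50, 3)))
        assert directed_hausdorff(V, V) == 0.0

    def test_asymmetry_two_point_example(self):
        V = PointCloudSet([[0.0], [2.0]])
        W = PointCloudSet([[0.0]])
        assert directed_hausdorff(V, W) == 2.0
        assert directed_hausdorff(W, V) == 0.0

    def test_subset_has_zero_forward_distance(self):
        rng = np.random.default_rng(1)
        V = PointCloudSet(rng.uniform(size=(100, 2)))
        W = PointCloudSet(np.vstack([V.points, [[5.0, 5.0]]]))
        assert directed_hausdorff(V, W) == 0.0
        assert directed_hausdorff(W, V) > 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            directed_hausdorff(PointCloudSet([[0.0]]), PointCloudSet([[0.0, 1.0]]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), nv=st.integers(1, 40), nw=st.integers(1, 40),
           dim=st.integers(1, 3))
    def test_matches_brute_force_oracle(self, seed, nv, nw, dim):
        rng = np.random.default_rng(seed)
        V = rng.uniform(-2, 2, size=(nv, dim))
        W = rng.uniform(-2, 2, size=(nw, dim))
        ours = directed_hausdorff(PointCloudSet(V), PointCloudSet(W))
        assert ours == pytest.approx(brute_force_directed_hausdorff(V, W), abs=1e-12)

    def test_matches_scipy_on_random_clouds(self):
        from scipy.spatial.distance import directed_hausdorff as scipy_dh
        rng = np.random.default_rng(2)
        V = rng.uniform(size=(60, 2))
        W = rng.uniform(size=(80, 2))
        assert directed_hausdorff(PointCloudSet(V), PointCloudSet(W)) == pytest.approx(
            scipy_dh(V, W)[0], abs=1e-12)


def _relax_to_one_system():
    # x' = -(x - 1): global attractor {1}
    return AutonomousSystem(
        dim=1, theta=lambda l, x: 1.0 + (np.asarray(x, float) - 1.0) * np.exp(-l),
        time=TimeStructure(span=5.0))


class TestGlobalAttractor:
    def test_linear_relaxation_contracts_to_one(self):
        B0 = PointCloudSet.from_interval(-5, 5, 20)
        A, rep = estimate_global_attractor(_relax_to_one_system(), B0, t_max=30.0)
        assert rep.verdict == "pass"
        assert directed_hausdorff(A, PointCloudSet([[1.0]])) < 1e-6
        assert rep.invariance_residual < 1e-6

    def test_halving_map_contracts_to_origin(self):
        halving = AutonomousSystem(
            dim=1, theta=lambda l, x: np.asarray(x, float) * 0.5 ** l,
            time=TimeStructure(kind="discrete", span=4))
        B0 = PointCloudSet.from_interval(-1, 1, 15)
        A, rep = estimate_global_attractor(halving, B0, t_max=60, n_steps=60)
        assert rep.verdict == "pass"
        assert np.max(np.abs(A.points)) < 1e-9

    def test_exponential_growth_reports_no_bounded_attractor(self):
        growth = AutonomousSystem(dim=1, theta=lambda l, x: np.asarray(x, float) * np.exp(l))
        _, rep = estimate_global_attractor(growth, PointCloudSet([[1.0]]), t_max=60,
                                           n_steps=30)
        assert rep.verdict == "fail"
        assert "no bounded attractor" in rep.message


class TestForwardConvergence:
    def test_relaxation_process_attracted_to_constant_fibres(self):
        proc = fd.load_fixture("relax_process")
        B = PointCloudSet.from_interval(-5, 5, 20)
        horizon = [5.0, 10.0, 20.0]
        candidate = NonautonomousSetFibres({t: PointCloudSet([[1.0]]) for t in horizon})
        rep = forward_convergence(proc, B, start=0.0, candidate=candidate,
                                  horizon=horizon, tol=1e-6)
        assert rep.verdict == "pass"
        # closed form: sup_{x in [-5,5]} e^{-t} |x - 1| = 6 e^{-t}
        assert rep.final_distance == pytest.approx(6 * np.exp(-20), rel=1e-6)

    def test_candidate_equal_to_evolved_cloud_has_zero_distance(self):
        proc = fd.load_fixture("relax_process")
        B = PointCloudSet.from_interval(-2, 2, 10)
        horizon = [1.0, 3.0]
        fibres = {}
        for t in horizon:
            pts = np.asarray([proc.phi(0.0, t, x) for x in B.points])
            fibres[t] = PointCloudSet(pts.reshape(-1, 1))
        rep = forward_convergence(proc, B, 0.0, NonautonomousSetFibres(fibres), horizon)
        assert all(d == 0.0 for _, d in rep.history)

    def test_unbounded_growth_fails_against_bounded_candidate(self):
        proc = fd.load_fixture("aging_growth_process")
        B = PointCloudSet.from_interval(0.5, 5, 10)
        horizon = [10.0, 100.0, 1000.0]
        candidate = NonautonomousSetFibres({t: PointCloudSet([[1.0]]) for t in horizon})
        rep = forward_convergence(proc, B, start=1.0, candidate=candidate,
                                  horizon=horizon, tol=1e-6)
        assert rep.verdict == "fail"

    def test_missing_fibre_raises(self):
        proc = fd.load_fixture("relax_process")
        with pytest.raises(KeyError):
            forward_convergence(proc, PointCloudSet([[0.0]]), 0.0,
                                NonautonomousSetFibres({1.0: PointCloudSet([[1.0]])}),
                                horizon=[2.0])


class TestPullbackConvergence:
    def test_relaxation_process_pullback_fibre_is_one(self):
        proc = fd.load_fixture("relax_process")
        B = PointCloudSet.from_interval(-5, 5, 20)
        cloud, rep = pullback_convergence(proc, B, target=0.0,
                                          starts=[-k for k in range(1, 31)], tol=1e-6)
        assert rep.verdict == "pass"
        assert directed_hausdorff(cloud, PointCloudSet([[1.0]])) < 1e-6

    def test_successive_distances_decay_geometrically(self):
        proc = fd.load_fixture("relax_process")
        B = PointCloudSet.from_interval(-5, 5, 20)
        _, rep = pullback_convergence(proc, B, target=0.0,
                                      starts=[-k for k in range(1, 16)], tol=1e-12)
        d = [x for _, x in rep.history]
        ratios = [d[i + 1] / d[i] for i in range(6)]
        assert ratios == pytest.approx([np.exp(-1)] * 6, rel=1e-6)

    def test_autonomous_pullback_equals_forward_global_estimate(self):
        # wrap the autonomous relaxation as a process and compare both routes
        auto = _relax_to_one_system()
        proc = Process(dim=1, phi=lambda s, t, x: auto.theta(t - s, x),
                       time=TimeStructure(span=5.0))
        B = PointCloudSet.from_interval(-5, 5, 20)
        A_fwd, _ = estimate_global_attractor(auto, B, t_max=30.0, n_steps=30)
        A_pb, _ = pullback_convergence(proc, B, target=0.0,
                                       starts=[-k for k in range(1, 31)], tol=1e-6)
        gap = max(directed_hausdorff(A_fwd, A_pb), directed_hausdorff(A_pb, A_fwd))
        assert gap < 1e-6

    def test_aging_growth_pullback_blows_up(self):
        proc = fd.load_fixture("aging_growth_process")
        B = PointCloudSet.from_interval(0.5, 5, 10)
        _, rep = pullback_convergence(proc, B, target=1.0,
                                      starts=[1.0 / k for k in range(1, 20)], tol=1e-6)
        assert rep.verdict == "fail"

    def test_starts_must_recede(self):
        proc = fd.load_fixture("relax_process")
        with pytest.raises(ValueError):
            pullback_convergence(proc, PointCloudSet([[0.0]]), 0.0, starts=[-1, -1])


class TestRandomPullback:
    def test_affine_contraction_matches_geometric_series_oracle(self, affine_contraction):
        depth = 40
        B = PointCloudSet([[0.0], [1.0], [0.37]])
        cloud, rep = random_pullback_estimate(affine_contraction, omega_seed=21,
                                              depths=list(range(1, depth + 1)), B=B,
                                              tol=1e-9)
        omega = SymbolSequence(n=2, sided="two", scheme=affine_contraction.scheme, seed=21)
        b = omega.read_block(-np.arange(1, depth + 1)) - 1  # symbols 1/2 -> bits 0/1
        series = float(np.sum(b * 0.5 ** np.arange(1, depth + 1)))
        assert rep.verdict == "pass"
        # the image of x = 0 is exactly the truncated dyadic series
        assert float(cloud.points.ravel()[0]) == series

    def test_depth_k_fibres_contract_geometrically(self, affine_contraction):
        B = PointCloudSet.from_interval(0, 1, 10)
        _, rep = random_pullback_estimate(affine_contraction, omega_seed=22,
                                          depths=list(range(1, 21)), B=B, tol=1e-12)
        diam = B.diameter()
        for k, d in rep.history:
            assert d <= 0.5 ** (k - 1) * diam + 1e-12

    def test_singleton_alphabet_matches_deterministic_pullback(self):
        rms = fd.RandomMapSystem(maps=[lambda x: np.asarray(x, float) / 2],
                                 domain=(0.0, 1.0),
                                 scheme=fd.BernoulliScheme(p=(1.0,), sided="two"))
        B = PointCloudSet.from_interval(0, 1, 10)
        cloud, _ = random_pullback_estimate(rms, omega_seed=23,
                                            depths=list(range(1, 40)), B=B, tol=1e-9)
        halving = AutonomousSystem(
            dim=1, theta=lambda l, x: np.asarray(x, float) * 0.5 ** l,
            time=TimeStructure(kind="discrete", span=4))
        A, _ = estimate_global_attractor(halving, B, t_max=40, n_steps=40, tol=1e-9)
        gap = max(directed_hausdorff(cloud, A), directed_hausdorff(A, cloud))
        assert gap < 1e-9

    def test_expanding_maps_fail(self):
        # doubling maps, clipped far outside the region the clouds ever reach
        rms = fd.RandomMapSystem(
            maps=[lambda x: np.clip(np.asarray(x, float) * 2.0, -1e12, 1e12)] * 2,
            domain=(-1e12, 1e12),
            scheme=fd.BernoulliScheme(p=(0.5, 0.5), sided="two"))
        B = PointCloudSet.from_interval(-1, 1, 10)
        _, rep = random_pullback_estimate(rms, omega_seed=24,
                                          depths=list(range(1, 12)), B=B, tol=1e-9)
        assert rep.verdict == "fail"

    def test_one_sided_driving_is_rejected(self, quadratic_halving):
        with pytest.raises(ValueError, match="two-sided"):
            random_pullback_estimate(quadratic_halving, 0, [1, 2],
                                     PointCloudSet([[0.5]]))


class TestTransientLength:
    def test_constant_trajectory_is_one_open_residence(self):
        t = np.arange(100.0)
        xs = np.full((100, 1), 1.0)
        res = transient_length(t, xs, [PointCloudSet([[0.0]]), PointCloudSet([[1.0]])],
                               radius=0.2)
        assert res == [(1, 0.0, None)]

    def test_crafted_two_segment_path_has_one_transition(self):
        t = np.arange(2000.0)
        xs = np.concatenate([np.full(1000, -1.0), np.full(1000, 1.0)])[:, None]
        res = transient_length(t, xs, [PointCloudSet([[-1.0]]), PointCloudSet([[1.0]])],
                               radius=0.2)
        assert res == [(0, 0.0, 1000.0), (1, 1000.0, None)]

    def test_deterministic_double_well_orbit_settles_without_exit(self):
        from fatedyn.landscape import integrate_ode
        t = np.linspace(0, 20, 400)
        traj = integrate_ode(lambda x: x - x ** 3, [0.9], t)
        res = transient_length(t, traj, [PointCloudSet([[-1.0]]), PointCloudSet([[1.0]])],
                               radius=0.2)
        assert len(res) == 1
        assert res[0][0] == 1 and res[0][2] is None

    def test_overlapping_reference_sets_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            transient_length([0.0], [[0.0]],
                             [PointCloudSet([[0.0]]), PointCloudSet([[0.1]])],
                             radius=0.2)
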