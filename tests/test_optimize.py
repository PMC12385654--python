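"""SMPSO: constriction, archive maintenance, fronts and scenario queries."""

import numpy as np
import pytest

import wolfberry as wb
from wolfberry.design import Factor, FactorSpace
from wolfberry.optimize import ParetoArchive, _polynomial_mutation, update_particle
from wolfberry.surrogates import rsm_evaluate


def _unit_space(d=1):
    return FactorSpace(tuple(Factor(f"x{i}", "", 0.0, 1.0) for i in range(d)))


class TestConstrictionFactor:
    def test_low_phi_branch(self):
        assert wb.constriction_factor(1.5, 1.5) == 1.0

    def test_closed_form(self):
        # phi = 4.1: 2 / |2 - 4.1 - sqrt(0.41)|
        assert wb.constriction_factor(2.05, 2.05) == pytest.approx(0.7299, abs=1e-3)

    def test_bounded_in_unit_interval(self):
        for phi in np.linspace(0.0, 10.0, 101):
            chi = wb.constriction_factor(phi / 2, phi / 2)
            assert 0.0 < chi <= 1.0

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            wb.constriction_factor(-1.0, 2.0)


class TestUpdateParticle:
    def test_fixed_point(self):
        x = np.array([0.4, 0.6])
        nx, nv = update_particle(
            x, np.zeros(2), x, x, 2.05, 2.05, 0.5, 0.5, np.zeros(2), np.ones(2)
        )
        np.testing.assert_array_equal(nx, x)
        np.testing.assert_array_equal(nv, np.zeros(2))

    def test_velocity_clamp(self, rng):
        lower, upper = np.zeros(3), np.ones(3)
        for _ in range(200):
            x = rng.random(3)
            v = rng.normal(scale=5.0, size=3)
            nx, nv = update_particle(
                x, v, rng.random(3), rng.random(3),
                rng.uniform(1.5, 2.5), rng.uniform(1.5, 2.5),
                rng.random(), rng.random(), lower, upper,
            )
            assert np.all(np.abs(nv) <= 0.5 + 1e-12)
            assert np.all(nx >= 0.0) and np.all(nx <= 1.0)

    def test_hand_computed_step(self):
        # r1 = r2 = 1, c1 = c2 = 2.05 -> chi = 0.7298...
        x = np.array([0.5])
        v = np.array([0.1])
        pbest = np.array([0.6])
        guide = np.array([0.8])
        chi = wb.constriction_factor(2.05, 2.05)
        raw_v = chi * (0.1 + 2.05 * (0.6 - 0.5) + 2.05 * (0.8 - 0.5))
        expected_v = min(raw_v, 0.5)
        nx, nv = update_particle(
            x, v, pbest, guide, 2.05, 2.05, 1.0, 1.0, np.zeros(1), np.ones(1)
        )
        assert nv[0] == pytest.approx(expected_v, abs=1e-9)
        assert nx[0] == pytest.approx(min(0.5 + expected_v, 1.0), abs=1e-9)

    def test_boundary_reverses_velocity(self):
        x = np.array([0.95])
        nx, nv = update_particle(
            x, np.array([0.4]), x, np.array([1.0]), 1.0, 1.0, 1.0, 1.0,
            np.zeros(1), np.ones(1),
        )
        assert nx[0] == 1.0
        assert nv[0] < 0


def _crowding_eviction_oracle(points, capacity):
    """Sequential insertion with min-crowding eviction, bi-objective."""
    kept: list[np.ndarray] = []
    for p in points:
        kept.append(np.asarray(p, float))
        if len(kept) > capacity:
            F = np.array(kept)
            crowd = np.zeros(len(kept))
            for j in range(2):
                span = F[:, j].max() - F[:, j].min()
                srt = np.argsort(F[:, j], kind="stable")
                crowd[srt[0]] = crowd[srt[-1]] = np.inf
                if span > 0:
                    for k in range(1, len(srt) - 1):
                        crowd[srt[k]] += (F[srt[k + 1], j] - F[srt[k - 1], j]) / span
            kept.pop(int(np.argmin(crowd)))
    return kept


class TestArchive:
    def test_dominated_candidate_rejected(self):
        arch = ParetoArchive(capacity=10)
        wb.archive_insert(arch, np.array([0.5]), np.array([2.0, 2.0]))
        assert not wb.archive_insert(arch, np.array([0.1]), np.array([1.0, 1.0]))
        assert arch.size == 1

    def test_dominating_candidate_sweeps(self):
        arch = ParetoArchive(capacity=10)
        wb.archive_insert(arch, np.array([0.1]), np.array([1.0, 2.0]))
        wb.archive_insert(arch, np.array([0.2]), np.array([2.0, 1.0]))
        wb.archive_insert(arch, np.array([0.3]), np.array([3.0, 3.0]))
        assert arch.size == 1
        np.testing.assert_array_equal(arch.objectives[0], [3.0, 3.0])

    def test_capacity_eviction_matches_oracle(self):
        # 10 mutually non-dominated points on a line, capacity 3
        t = np.linspace(0, 1, 10)
        objs = np.column_stack([t, 1.0 - t])
        arch = ParetoArchive(capacity=3)
        for i, o in enumerate(objs):
            wb.archive_insert(arch, np.array([float(i)]), o)
        expected = _crowding_eviction_oracle(objs, 3)
        got = sorted(o[0] for o in arch.objectives)
        want = sorted(o[0] for o in expected)
        np.testing.assert_allclose(got, want, atol=1e-12)
        # extremes survive: the survivors span the full range
        assert got[0] == 0.0 and got[-1] == 1.0

    def test_nonfinite_rejected(self):
        arch = ParetoArchive()
        with pytest.raises(ValueError):
            wb.archive_insert(arch, np.array([0.0]), np.array([np.inf, 1.0]))


class TestRunSMPSO:
    def test_constant_evaluator_single_point(self):
        prob = wb.MOOProblem(
            evaluate=lambda x: np.array([1.0, 1.0]), space=_unit_space(2)
        )
        arch = wb.run_smpso(prob, wb.SMPSOConfig(seed=0))
        assert arch.size == 1

    def test_toy_front(self):
        prob = wb.MOOProblem(
            evaluate=lambda x: np.array([x[0], 1.0 - x[0] ** 2]), space=_unit_space(1)
        )
        arch = wb.run_smpso(prob, wb.SMPSOConfig(swarm_size=12, generations=50, seed=1))
        F = np.array(arch.objectives)
        assert np.abs(F[:, 1] - (1.0 - F[:, 0] ** 2)).max() <= 1e-2
        # coverage of the front, not just a cluster
        assert np.ptp(F[:, 0]) > 0.5

    def test_archive_nondominated_brute_force(self):
        prob = wb.MOOProblem(
            evaluate=lambda x: np.array([x[0], x[1], 1.0 - x[0] - 0.5 * x[1]]),
            space=_unit_space(2),
        )
        arch = wb.run_smpso(prob, wb.SMPSOConfig(seed=2))
        F = np.array(arch.objectives)
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not (np.all(F[i] >= F[j]) and np.any(F[i] > F[j]))

    def test_seed_determinism(self):
        prob = wb.MOOProblem(
            evaluate=lambda x: np.array([x[0], 1.0 - x[0] ** 2]), space=_unit_space(1)
        )
        a = wb.run_smpso(prob, wb.SMPSOConfig(seed=9))
        b = wb.run_smpso(prob, wb.SMPSOConfig(seed=9))
        np.testing.assert_array_equal(np.array(a.objectives), np.array(b.objectives))
        np.testing.assert_array_equal(np.array(a.positions), np.array(b.positions))


class TestSelectOptimal:
    def test_singleton(self):
        arch = ParetoArchive()
        wb.archive_insert(arch, np.array([0.3]), np.array([1.0, 2.0]))
        pos, obj = wb.select_optimal(arch)
        np.testing.assert_array_equal(pos, [0.3])

    def test_knee_selection(self):
        arch = ParetoArchive()
        # extreme points (1, 0) and (0, 1), knee at (0.8, 0.8)
        wb.archive_insert(arch, np.array([0.0]), np.array([1.0, 0.0]))
        wb.archive_insert(arch, np.array([0.5]), np.array([0.8, 0.8]))
        wb.archive_insert(arch, np.array([1.0]), np.array([0.0, 1.0]))
        pos, obj = wb.select_optimal(arch)
        np.testing.assert_array_equal(obj, [0.8, 0.8])

    def test_tie_break_deterministic(self):
        arch = ParetoArchive()
        wb.archive_insert(arch, np.array([0.0]), np.array([1.0, 0.0]))
        wb.archive_insert(arch, np.array([1.0]), np.array([0.0, 1.0]))
        pos_a, _ = wb.select_optimal(arch)
        pos_b, _ = wb.select_optimal(arch)
        np.testing.assert_array_equal(pos_a, pos_b)

    def test_empty_archive(self):
        with pytest.raises(ValueError):
            wb.select_optimal(ParetoArchive())


class TestScenarioQuery:
    @pytest.fixture()
    def rsm_problem(self, ref_rsm):
        return wb.MOOProblem(evaluate=lambda x: rsm_evaluate(ref_rsm, x))

    def test_conditions_within_bounds(self, rsm_problem, space):
        conditions, _ = wb.scenario_query(rsm_problem, 10.0, wb.SMPSOConfig(seed=0))
        for factor in space.factors:
            assert factor.lower <= conditions[factor.name] <= factor.upper

    def test_frozen_time_exact(self, rsm_problem):
        conditions, _ = wb.scenario_query(rsm_problem, 10.0, wb.SMPSOConfig(seed=1))
        assert conditions["time"] == 10.0

    def test_self_consistency_with_surface(self, rsm_problem, ref_rsm, space):
        conditions, objectives = wb.scenario_query(rsm_problem, 10.0, wb.SMPSOConfig(seed=2))
        raw = np.array([conditions[f.name] for f in space.factors])
        unit = (raw - space.lower) / (space.upper - space.lower)
        np.testing.assert_allclose(objectives, rsm_evaluate(ref_rsm, unit), atol=1e-9)

    def test_invalid_frozen_time(self, rsm_problem):
        with pytest.raises(ValueError):
            wb.scenario_query(rsm_problem, 40.0)


def test_polynomial_mutation_stays_in_bounds(rng):
    lower, upper = np.zeros(3), np.ones(3)
    for _ in range(100):
        x = rng.random(3)
        y = _polynomial_mutation(x, lower, upper, 20.0, rng)
        assert np.all(y >= 0.0) and np.all(y <= 1.0)


def test_moo_problem_frozen_validation():
    with pytest.raises(ValueError):
        wb.MOOProblem(evaluate=lambda x: x, frozen={"time": 99.0})
    with pytest.raises(ValueError):
        wb.MOOProblem(evaluate=lambda x: x, frozen={"bogus": 1.0})
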