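"""Genetic-algorithm optimizer: cost function, generations, convergence."""
import numpy as np
import pytest

import wmstitch as ws
from wmstitch import ga
from wmstitch.configuration import StitchSolution
from wmstitch.geometry import LandmarkSet
from wmstitch.pipeline import _EdgeCache

from conftest import gt_solution


def _two_fragment_solution(offsets=((0.0, 0.0), (0.0, 0.0)), rotations=(0.0, 0.0)):
    """Minimal hand-built solution with two fragments and one pair."""
    from wmstitch.configuration import Placement, make_configuration
    from wmstitch.transform import RigidTransform

    config = make_configuration(
        {"a": ws.Placement("L", 0), "b": ws.Placement("R", 0)}, "a"
    )
    transforms = {
        "a": RigidTransform(rotations[0], offsets[0], (0.0, 0.0), 1.0),
        "b": RigidTransform(rotations[1], offsets[1], (0.0, 0.0), 1.0),
    }
    return StitchSolution(transforms, config, np.nan, 1.0)


class TestPairCost:
    def test_coincident_landmarks_cost_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 4.0]])
        sol = _two_fragment_solution()
        assert ws.pair_cost(LandmarkSet("a", pts), LandmarkSet("b", pts.copy()), sol) == 0.0

    def test_constant_3_4_offset_costs_five(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 5.0]])
        sol = _two_fragment_solution(offsets=((0.0, 0.0), (3.0, 4.0)))
        cost = ws.pair_cost(LandmarkSet("a", pts), LandmarkSet("b", pts.copy()), sol)
        assert cost == pytest.approx(5.0)

    def test_matches_bruteforce_distance_loop(self):
        """Mean landmark distance equals an independently coded loop."""
        rng = np.random.default_rng(12)
        pa = rng.uniform(-30, 30, (7, 2))
        pb = rng.uniform(-30, 30, (7, 2))
        sol = _two_fragment_solution(
            offsets=((1.0, -2.0), (0.5, 3.0)), rotations=(10.0, -25.0)
        )
        got = ws.pair_cost(LandmarkSet("a", pa), LandmarkSet("b", pb), sol)

        # oracle: transform point-by-point with explicit trigonometry
        total = 0.0
        for i in range(7):
            qs = []
            for (fid, p) in (("a", pa[i]), ("b", pb[i])):
                t = sol.transforms[fid]
                th = np.deg2rad(t.rotation_deg)
                x = p[0] * np.cos(th) - p[1] * np.sin(th) + t.translation[0]
                y = p[0] * np.sin(th) + p[1] * np.cos(th) + t.translation[1]
                qs.append((x, y))
            total += np.hypot(qs[0][0] - qs[1][0], qs[0][1] - qs[1][1])
        assert got == pytest.approx(total / 7, rel=1e-12)

    def test_mismatched_k_rejected(self):
        sol = _two_fragment_solution()
        with pytest.raises(ValueError, match="identical k"):
            ws.pair_cost(
                LandmarkSet("a", np.zeros((3, 2))), LandmarkSet("b", np.zeros((4, 2))), sol
            )


class TestTotalCost:
    def test_single_pair_equals_pair_cost(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0]])
        sol = _two_fragment_solution(offsets=((0.0, 0.0), (3.0, 4.0)))
        pairs = [ga.PairLandmarks("a", pts, "b", pts.copy(), 1)]
        assert ws.total_cost(sol, pairs) == pytest.approx(5.0)

    def test_mean_over_pairs(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0]])
        sol = _two_fragment_solution(offsets=((0.0, 0.0), (0.0, 2.0)))
        pairs = [
            ga.PairLandmarks("a", pts, "b", pts.copy(), 1),  # cost 2
            ga.PairLandmarks("a", pts, "b", pts + [0.0, 2.0], 1),  # cost 4
        ]
        assert ws.total_cost(sol, pairs) == pytest.approx(3.0)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="j = 0"):
            ws.total_cost(_two_fragment_solution(), [])


class TestMakeGeneration:
    def test_population_size_is_40(self):
        params = ga.GAParams()
        rng = np.random.default_rng(0)
        pop = ws.make_generation(
            np.zeros((2, 9)), params, ga.MutationBounds(3.0, 5.0), rng
        )
        assert pop.shape == (40, 9)

    def test_zero_bounds_clone_parents(self):
        params = ga.GAParams()
        rng = np.random.default_rng(0)
        parents = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        pop = ws.make_generation(parents, params, ga.MutationBounds(0.0, 0.0), rng)
        assert all(
            np.array_equal(row, parents[0]) or np.array_equal(row, parents[1])
            for row in pop
        )

    def test_mutations_respect_bounds(self):
        params = ga.GAParams()
        rng = np.random.default_rng(3)
        bounds = ga.MutationBounds(2.0, 7.0)
        parents = np.zeros((2, 6))
        pop = ws.make_generation(parents, params, bounds, rng)
        mutants = pop[2:]
        assert np.abs(mutants[:, [0, 3]]).max() <= 2.0  # rotations
        assert np.abs(mutants[:, [1, 2, 4, 5]]).max() <= 7.0  # translations

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ga.GAParams(population=39)
        with pytest.raises(ValueError):
            ga.GAParams(patience_generations=300, max_generations=200)


class TestOptimizeLevel:
    def _setup(self, zero_perturbation_case, misalign=None):
        """GT-placed solution on the unperturbed case, optionally misaligned."""
        from dataclasses import replace

        case = zero_perturbation_case
        frags = {f.id: f for f in case.fragments}
        solution = gt_solution(case)
        fid = None
        if misalign:
            fid = [f for f in solution.transforms if f != solution.configuration.anchor][0]
            t = solution.transforms[fid]
            transforms = dict(solution.transforms)
            transforms[fid] = replace(
                t,
                rotation_deg=t.rotation_deg + misalign[0],
                translation=(
                    t.translation[0] + misalign[1],
                    t.translation[1] + misalign[2],
                ),
            )
            solution = StitchSolution(
                transforms, solution.configuration, np.nan, solution.level_factor
            )
        cache = _EdgeCache(frags)
        edges = cache.edges_for([solution.configuration])
        pairs = ga.level_landmark_pairs(solution, edges, 1.0, 32)
        return solution, pairs, fid

    def test_best_cost_trace_non_increasing(self, zero_perturbation_case):
        solution, pairs, _ = self._setup(zero_perturbation_case, misalign=(5.0, 8.0, -3.0))
        params = ga.GAParams(max_generations=60, patience_generations=50, rng_seed=1)
        _, trace = ws.optimize_level(
            solution, pairs, params, ga.MutationBounds(1.5, 4.0), np.random.default_rng(1)
        )
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_already_optimal_not_made_worse(self, zero_perturbation_case):
        solution, pairs, _ = self._setup(zero_perturbation_case)
        initial = ws.total_cost(solution, pairs)
        params = ga.GAParams(max_generations=55, patience_generations=50, rng_seed=2)
        best, _ = ws.optimize_level(
            solution, pairs, params, ga.MutationBounds(0.01, 0.01), np.random.default_rng(2)
        )
        assert best.cost <= initial + 1e-12

    def test_recovers_known_misalignment(self, zero_perturbation_case):
        """A 5 deg / (8, -3) px misalignment is undone to 1 deg / 2 px."""
        solution, pairs, fid = self._setup(zero_perturbation_case, misalign=(5.0, 8.0, -3.0))
        reference = gt_solution(zero_perturbation_case)
        params = ga.GAParams(rng_seed=5)
        best, _ = ws.optimize_level(
            solution, pairs, params, ga.MutationBounds(1.0, 2.0), np.random.default_rng(5)
        )
        got = best.transforms[fid]
        want = reference.transforms[fid]
        assert abs(got.rotation_deg - want.rotation_deg) <= 1.0
        assert np.hypot(
            got.translation[0] - want.translation[0],
            got.translation[1] - want.translation[1],
        ) <= 2.0

    def test_identical_seed_identical_result(self, zero_perturbation_case):
        solution, pairs, _ = self._setup(zero_perturbation_case, misalign=(4.0, -5.0, 2.0))
        params = ga.GAParams(max_generations=80, patience_generations=50, rng_seed=9)
        runs = [
            ws.optimize_level(
                solution, pairs, params, ga.MutationBounds(1.0, 2.0), np.random.default_rng(9)
            )
            for _ in range(2)
        ]
        (a, ta), (b, tb) = runs
        assert a.cost == b.cost
        assert ta == tb
        for fid in a.transforms:
            assert a.transforms[fid] == b.transforms[fid]


class TestMultiresolution:
    def test_physical_cost_never_increases_across_levels(self, stitched_result):
        traces = stitched_result.solutions[0].traces
        final_um = [t.final_cost * t.spacing_um for t in traces]
        assert final_um[-1] <= final_um[0] + 1e-9

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ga.ResolutionSchedule((1.0, 2.0))

    def test_multiresolution_beats_coarse_only(self):
        """Ground-truth error after the full schedule is below coarse-only,
        in the median over synthetic quartered cases."""
        deltas = []
        for seed in (31, 32, 33, 34, 35):
            case = ws.make_case(seed, 4)
            frags = list(case.fragments)
            full = ws.run_case(
                frags, seed=seed, top_n_solutions=1, gt_case=case, render_output=False
            )
            coarse_only = ws.run_case(
                frags,
                seed=seed,
                top_n_solutions=1,
                gt_case=case,
                render_output=False,
                schedule=ga.ResolutionSchedule((20.0,)),
            )
            full_err = full.solutions[0].gt_report.median_mm
            coarse_err = coarse_only.solutions[0].gt_report.median_mm
            deltas.append(coarse_err - full_err)
        assert np.median(deltas) > 0
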