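"""Registration-error metrics: unit conversions, ground-truth scoring."""
import numpy as np
import pytest

import wmstitch as ws
from wmstitch import evaluate

from conftest import gt_solution


class TestAbsoluteError:
    def test_five_px_at_250um_is_1p25mm(self):
        a = np.zeros((10, 2))
        b = a + [3.0, 4.0]  # 5 px apart
        errs = ws.absolute_error([(a, b)], spacing_um=250.0)
        assert np.allclose(errs, 1.25)

    def test_zero_distances(self):
        a = np.random.default_rng(0).uniform(0, 10, (5, 2))
        errs = ws.absolute_error([(a, a.copy())], spacing_um=100.0)
        assert np.allclose(errs, 0.0)

    def test_median_of_known_distances(self):
        # distances 1..5 px at 1000 um/px -> median 3 mm
        a = np.zeros((5, 2))
        b = np.column_stack([np.arange(1.0, 6.0), np.zeros(5)])
        errs = ws.absolute_error([(a, b)], spacing_um=1000.0)
        assert np.median(errs) == pytest.approx(3.0)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            ws.absolute_error([], spacing_um=16.0)


class TestRelativeError:
    def test_1mm_on_40x50mm_section(self):
        assert ws.relative_error(1.0, (40.0, 50.0)) == pytest.approx(100 / 45)

    def test_zero_error(self):
        assert ws.relative_error(0.0, (40.0, 50.0)) == 0.0

    def test_doubling_dimensions_halves_relative_error(self):
        r1 = ws.relative_error(1.0, (30.0, 40.0))
        r2 = ws.relative_error(1.0, (60.0, 80.0))
        assert r2 == pytest.approx(r1 / 2)


class TestAutoLandmarks:
    def test_ten_pairs_per_adjacent_edge_pair(self, stitched_result, perturbed_case):
        sol = stitched_result.solutions[0].solution
        frags = {f.id: f for f in perturbed_case.fragments}
        from wmstitch.pipeline import _EdgeCache

        cache = _EdgeCache(frags)
        edges = cache.edges_for([sol.configuration])
        pairs = ws.auto_landmarks(sol, edges, n_points=10)
        assert len(pairs) == 4
        for a, b in pairs:
            assert a.shape == (10, 2) and b.shape == (10, 2)

    def test_post_hoc_shift_moves_every_pair_by_5px(self, zero_perturbation_case):
        """With perfectly interlocking edges, shifting one fragment by
        (3, 4) px makes every one of its pair distances exactly 5 px."""
        from dataclasses import replace

        case = zero_perturbation_case
        sol = gt_solution(case)
        # perfectly interlocking stitch edges: both sides of each cut use the
        # recorded ground-truth cut polyline (identical once placed)
        edges = {}
        for pair, cfg_pair in zip(case.landmark_pairs, sol.configuration.adjacent_pairs):
            assert {pair.fragment_a, pair.fragment_b} == {
                cfg_pair.fragment_a,
                cfg_pair.fragment_b,
            }
            for fid, side in (
                (cfg_pair.fragment_a, cfg_pair.side_a),
                (cfg_pair.fragment_b, cfg_pair.side_b),
            ):
                pts = pair.points_a if fid == pair.fragment_a else pair.points_b
                order = np.argsort(pts[:, pair.axis], kind="stable")
                edges[(fid, side)] = ws.StitchEdge(fid, side, pts[order])
        base = ws.auto_landmarks(sol, edges, n_points=10)

        shifted_fid = [f for f in sol.transforms if f != sol.configuration.anchor][0]
        t = sol.transforms[shifted_fid]
        transforms = dict(sol.transforms)
        transforms[shifted_fid] = replace(
            t, translation=(t.translation[0] + 3.0, t.translation[1] + 4.0)
        )
        shifted_sol = ws.StitchSolution(transforms, sol.configuration, 0.0, 1.0)
        shifted = ws.auto_landmarks(shifted_sol, edges, n_points=10)
        for pair_idx, pair in enumerate(sol.configuration.adjacent_pairs):
            d_base = np.linalg.norm(base[pair_idx][0] - base[pair_idx][1], axis=1)
            d_shift = np.linalg.norm(shifted[pair_idx][0] - shifted[pair_idx][1], axis=1)
            if shifted_fid in (pair.fragment_a, pair.fragment_b):
                # edges interlock exactly before the shift, so after it every
                # distance is the shift magnitude
                assert np.allclose(d_base, 0.0, atol=1e-9)
                assert np.allclose(d_shift, 5.0, atol=1e-9)
            else:
                assert np.allclose(d_shift, d_base)


class TestGroundTruthError:
    def test_gt_transforms_score_zero(self, zero_perturbation_case):
        report = ws.ground_truth_error(gt_solution(zero_perturbation_case),
                                       zero_perturbation_case)
        assert report.mode == "ground_truth"
        assert report.comparable
        assert report.median_mm == pytest.approx(0.0, abs=1e-12)

    def test_extra_shift_on_one_fragment(self, zero_perturbation_case):
        """A (0, 4) px extra shift at 250 um/px errs that fragment's pairs by 1 mm."""
        from dataclasses import replace

        case = zero_perturbation_case
        sol = gt_solution(case)
        fid = [f for f in sol.transforms if f != sol.configuration.anchor][0]
        t = sol.transforms[fid]
        transforms = dict(sol.transforms)
        transforms[fid] = replace(t, translation=(t.translation[0], t.translation[1] + 4.0))
        shifted = ws.StitchSolution(transforms, sol.configuration, 0.0, 1.0)
        frags = {
            f.id: ws.TissueFragment(f.id, f.image, f.mask, 250.0) for f in case.fragments
        }
        report = ws.ground_truth_error(shifted, case, frags)
        expected = {
            True: 1.0,  # pairs touching the shifted fragment
            False: 0.0,
        }
        for pair in case.landmark_pairs:
            touches = fid in (pair.fragment_a, pair.fragment_b)
            ta = shifted.transforms[pair.fragment_a]
            tb = shifted.transforms[pair.fragment_b]
            d = np.linalg.norm(ta.apply(pair.points_a) - tb.apply(pair.points_b), axis=1)
            assert np.allclose(d * 250.0 / 1000.0, expected[touches], atol=1e-9)
        assert 0.0 <= report.median_mm <= 1.0

    def test_global_rigid_motion_invariance(self, zero_perturbation_case):
        """Rotating + translating the whole reconstruction leaves errors unchanged."""
        case = zero_perturbation_case
        sol = gt_solution(case)
        from wmstitch.transform import RigidTransform

        motion = RigidTransform(17.0, (40.0, -25.0), (100.0, 80.0))
        moved = ws.StitchSolution(
            {
                fid: RigidTransform.from_matrix(motion.matrix @ t.matrix, t.center, 1.0)
                for fid, t in sol.transforms.items()
            },
            sol.configuration,
            0.0,
            1.0,
        )
        a = ws.ground_truth_error(sol, case)
        b = ws.ground_truth_error(moved, case)
        assert b.median_mm == pytest.approx(a.median_mm, abs=1e-9)

    def test_wrong_configuration_flagged_not_comparable(self, stitched_result,
                                                        perturbed_case):
        sol = stitched_result.solutions[0].solution
        # forge a solution with two fragments' slots swapped
        ids = list(sol.configuration.placements)
        wrong_slots = {fid: p.slot for fid, p in sol.configuration.placements.items()}
        wrong_slots[ids[0]], wrong_slots[ids[1]] = wrong_slots[ids[1]], wrong_slots[ids[0]]
        placements = {
            fid: ws.Placement(wrong_slots[fid], p.rotation_state)
            for fid, p in sol.configuration.placements.items()
        }
        wrong_config = ws.make_configuration(placements, sol.configuration.anchor)
        wrong = ws.StitchSolution(sol.transforms, wrong_config, sol.cost, 1.0)
        report = ws.ground_truth_error(wrong, perturbed_case)
        assert not report.comparable
        assert "not_comparable" in report.note

    def test_auto_and_ground_truth_agree_on_stitched_case(self, stitched_result):
        """The two error modes agree within 0.5 mm median on a real stitch."""
        best = stitched_result.solutions[0]
        assert best.gt_report.comparable
        assert abs(best.report.median_mm - best.gt_report.median_mm) <= 0.5
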