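import numpy as np
import pytest

import wmstitch as ws


@pytest.fixture(scope="session")
def quarter_disc_mask():
    """Quarter disc with straight sides on the left and top of its bbox."""
    yy, xx = np.mgrid[0:200, 0:200]
    return (xx**2 + yy**2) <= 180**2


@pytest.fixture(scope="session")
def unperturbed_case():
    """Quartered synthetic case left in the WMS frame (identity ground truth)."""
    wms = ws.generate_wms(3, (512, 512), 16.0)
    return ws.cut_wms(wms, 4, 0.03, seed=2)


@pytest.fixture(scope="session")
def zero_perturbation_case(unperturbed_case):
    """Quartered case on per-fragment canvases, translations only."""
    return ws.perturb_case(
        unperturbed_case, seed=9, max_rot_deg=0, max_shift_frac=0.05, flip_prob=0
    )


@pytest.fixture(scope="session")
def perturbed_case():
    """Fully perturbed quartered case (rotations up to +-20 deg)."""
    return ws.make_case(7, 4)


@pytest.fixture(scope="session")
def stitched_result(perturbed_case):
    """Pipeline output for the perturbed case, best solution only."""
    return ws.run_case(
        list(perturbed_case.fragments),
        seed=7,
        top_n_solutions=1,
        gt_case=perturbed_case,
        render_output=True,
        tile_size=256,
    )


def gt_solution(case, level_factor=1.0):
    """Stitch solution built directly from a case's ground-truth transforms."""
    from wmstitch.configuration import Placement, StitchSolution, make_configuration
    from wmstitch.transform import RigidTransform

    frags = {f.id: f for f in case.fragments}
    placements = {fid: ws.Placement(case.slots[fid], 0) for fid in frags}
    config = make_configuration(placements, next(iter(frags)))
    transforms = {
        fid: RigidTransform.from_matrix(
            case.gt_transforms[fid].matrix, frags[fid].centroid(), 1.0
        )
        for fid in frags
    }
    return StitchSolution(transforms, config, 0.0, 1.0).rescaled(level_factor)
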