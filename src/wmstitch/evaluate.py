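"""Registration-error metrics for stitched whole-mount reconstructions.

Two modes: *auto landmarks* picks ten evenly spaced points along each pair
of stitched edges and measures their residual separation (an approximation,
since the points are chosen on the result itself), while *ground truth*
scores synthetic digitally-cut cases on the exact corresponding points
recorded along every cut.  Errors are reported in mm as median (IQR), plus
a relative error as a percentage of the mean whole-mount dimension.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .configuration import StitchSolution, oriented_landmarks, placed_masks
from .geometry import StitchEdge, TissueFragment
from .synthetic import SyntheticCase


@dataclass
class RegistrationReport:
    """Median (IQR) landmark registration error for one reconstruction."""

    mode: str  # auto_landmarks | ground_truth
    errors_mm: np.ndarray
    wms_size_mm: tuple[float, float]
    comparable: bool = True
    note: str = ""

    @property
    def median_mm(self) -> float:
        return float(np.median(self.errors_mm)) if len(self.errors_mm) else float("nan")

    @property
    def iqr_mm(self) -> float:
        if not len(self.errors_mm):
            return float("nan")
        q1, q3 = np.percentile(self.errors_mm, [25, 75])
        return float(q3 - q1)

    @property
    def relative_error_pct(self) -> float:
        return relative_error(self.median_mm, self.wms_size_mm)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "comparable": self.comparable,
            "n_landmarks": int(len(self.errors_mm)),
            "absolute_error_mm": {"median": self.median_mm, "iqr": self.iqr_mm},
            "relative_error_pct": self.relative_error_pct,
            "wms_size_mm": list(self.wms_size_mm),
            "note": self.note,
        }


def auto_landmarks(
    solution: StitchSolution,
    edges: dict[tuple[str, str], StitchEdge],
    n_points: int = 10,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Evenly spaced corresponding points on every stitched edge pair.

    Returns per adjacent pair the two placed ``(n_points, 2)`` arrays,
    index-paired along the shared axis.  Degenerate edges are skipped.
    """
    out = []
    for pair in solution.configuration.adjacent_pairs:
        try:
            lm = []
            for fid, side in ((pair.fragment_a, pair.side_a), (pair.fragment_b, pair.side_b)):
                t = solution.transforms[fid]
                lms = oriented_landmarks(edges[(fid, side)].polyline, t, pair.axis, n_points, fid)
                lm.append(t.apply(lms.points))
            out.append((lm[0], lm[1]))
        except ValueError:
            continue  # degenerate edge: skip the pair
    return out


def absolute_error(pairs: list[tuple[np.ndarray, np.ndarray]], spacing_um: float) -> np.ndarray:
    """Per-landmark Euclidean distances converted to mm."""
    if not pairs:
        raise ValueError("no landmark pairs to evaluate")
    dists = np.concatenate([np.linalg.norm(a - b, axis=1) for a, b in pairs])
    return dists * spacing_um / 1000.0


def relative_error(absolute_mm: float, wms_size_mm: tuple[float, float]) -> float:
    """Absolute error as % of the mean whole-mount dimension."""
    mean_dim = (wms_size_mm[0] + wms_size_mm[1]) / 2.0
    if mean_dim <= 0:
        raise ValueError("WMS size must be positive")
    return 100.0 * absolute_mm / mean_dim


def wms_size_mm(
    fragments: dict[str, TissueFragment], solution: StitchSolution
) -> tuple[float, float]:
    """Placed tissue bounding box in mm (width, height)."""
    masks, _ = placed_masks(fragments, solution.transforms)
    union = np.zeros(next(iter(masks.values())).shape, bool)
    for m in masks.values():
        union |= m
    ys, xs = np.nonzero(union)
    spacing = next(iter(fragments.values())).spacing_um
    return (
        float((xs.max() - xs.min() + 1) * spacing / 1000.0),
        float((ys.max() - ys.min() + 1) * spacing / 1000.0),
    )


def evaluation_report(
    solution: StitchSolution,
    fragments: dict[str, TissueFragment],
    edges: dict[tuple[str, str], StitchEdge],
    n_points: int = 10,
) -> RegistrationReport:
    """Auto-landmark registration error of a final stitch (approximation)."""
    pairs = auto_landmarks(solution, edges, n_points)
    spacing = next(iter(fragments.values())).spacing_um
    errs = absolute_error(pairs, spacing)
    return RegistrationReport(
        "auto_landmarks",
        errs,
        wms_size_mm(fragments, solution),
        note="landmarks picked on the result itself; approximation, not exact",
    )


def _expected_slots(case: SyntheticCase, solution: StitchSolution) -> bool:
    """Check the estimated arrangement matches the ground-truth cut layout."""
    placements = solution.configuration.placements
    return all(placements[fid].slot == slot for fid, slot in case.slots.items()) and not any(
        placements[fid].flip for fid in placements
    )


def ground_truth_error(
    solution: StitchSolution,
    case: SyntheticCase,
    fragments: dict[str, TissueFragment] | None = None,
) -> RegistrationReport:
    """Exact registration error of a synthetic case.

    Every recorded landmark pair corresponds to one physical point on a
    cut; both copies are mapped through the estimated placements and their
    residual separation (which a perfect stitch reduces to zero) is reported
    in mm.  Invariant to a global rigid motion of the whole reconstruction.
    If the chosen configuration does not match the ground-truth arrangement
    the report is flagged not comparable.
    """
    fragments = fragments or {f.id: f for f in case.fragments}
    spacing = next(iter(fragments.values())).spacing_um
    level = solution.level_factor
    dists = []
    for pair in case.landmark_pairs:
        ta = solution.transforms[pair.fragment_a]
        tb = solution.transforms[pair.fragment_b]
        pa = ta.apply((pair.points_a + 0.5) / level - 0.5)
        pb = tb.apply((pair.points_b + 0.5) / level - 0.5)
        dists.append(np.linalg.norm(pa - pb, axis=1))
    errs = np.concatenate(dists) * spacing * level / 1000.0
    comparable = _expected_slots(case, solution)
    return RegistrationReport(
        "ground_truth",
        errs,
        wms_size_mm(fragments, solution),
        comparable=comparable,
        note="" if comparable else "not_comparable: configuration differs from ground truth",
    )
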