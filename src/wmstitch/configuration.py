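"""Enumerate, filter and rank candidate fragment arrangements.

Reassembly is a jigsaw with strong priors: quadrant fragments occupy the
four slots UL/UR/LL/LR of an ellipse-like section and every stitch edge must
pair with one edge of a neighbouring fragment so the adjacencies form a
single closed loop.  With one fragment anchored and each of the other three
free to take any of four 90-degree rotation states there are exactly
4^3 = 64 candidate reconstructions; for two halves there is a single one and
the search is bypassed.  Candidates are filtered (loop constraint, at most
20% pairwise overlap) and ranked by the mean Euclidean distance between
paired stitch edges at a heavily downsampled level.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    LandmarkSet,
    StitchEdge,
    TissueFragment,
    resample_polyline,
)
from .transform import RigidTransform, warp_mask

QUAD_SLOTS = ("UL", "UR", "LL", "LR")
HALF_SLOTS = ("L", "R")

#: stitch-edge sides each slot exposes, in the assembled (WMS) frame
SLOT_SIDES = {
    "UL": frozenset({"right", "bottom"}),
    "UR": frozenset({"bottom", "left"}),
    "LL": frozenset({"top", "right"}),
    "LR": frozenset({"left", "top"}),
    "L": frozenset({"right"}),
    "R": frozenset({"left"}),
}
_SLOT_OF_SIDES = {v: k for k, v in SLOT_SIDES.items()}

#: quadrant adjacency cycle: (slot_a, its WMS-frame side, slot_b, side, axis)
QUAD_PAIR_TABLE = [
    ("UL", "right", "UR", "left", 1),
    ("UR", "bottom", "LR", "top", 0),
    ("LR", "left", "LL", "right", 1),
    ("LL", "top", "UL", "bottom", 0),
]
HALF_PAIR_TABLE = [("L", "right", "R", "left", 1)]

_ROT90 = {"right": "bottom", "bottom": "left", "left": "top", "top": "right"}


class InfeasibleConfigurationError(RuntimeError):
    """No feasible arrangement; manual --edges/--flip overrides may help."""


def rotate_side(side: str, rotation_state: int) -> str:
    """Side label after rotating the fragment by a multiple of 90 degrees."""
    for _ in range((rotation_state // 90) % 4):
        side = _ROT90[side]
    return side


@dataclass(frozen=True)
class Placement:
    slot: str
    rotation_state: int  # 0/90/180/270, counter-clockwise in the raster frame
    flip: bool = False


@dataclass(frozen=True)
class AdjacentEdgePair:
    """One stitch-edge pairing, with sides in each fragment's own frame."""

    fragment_a: str
    side_a: str
    fragment_b: str
    side_b: str
    axis: int  # shared ordering axis of the paired edges (0 = x, 1 = y)


@dataclass(frozen=True)
class CandidateConfiguration:
    """One way of reassembling the fragments (slots + rotation states)."""

    n: int
    placements: dict[str, Placement]
    adjacent_pairs: tuple[AdjacentEdgePair, ...]
    anchor: str
    index: int = 0  # enumeration order, used as the final tie-break

    @property
    def loop_ok(self) -> bool:
        """True when slots are a bijection, closing the adjacency cycle."""
        slots = [p.slot for p in self.placements.values()]
        return len(set(slots)) == self.n and bool(self.adjacent_pairs)


@dataclass(frozen=True)
class StitchSolution:
    """Per-fragment rigid transforms at one resolution level.

    The anchor fragment is pinned to the identity, leaving (n - 1) * 3 free
    parameters (one rotation, two translations per remaining fragment).
    """

    transforms: dict[str, RigidTransform]
    configuration: CandidateConfiguration
    cost: float
    level_factor: float

    def rescaled(self, new_factor: float) -> "StitchSolution":
        return StitchSolution(
            {fid: t.rescaled(new_factor) for fid, t in self.transforms.items()},
            self.configuration,
            self.cost * self.level_factor / new_factor,
            new_factor,
        )


@dataclass(frozen=True)
class FeasibilityReport:
    loop_ok: bool
    max_overlap_fraction: float
    edge_distance_score: float

    @property
    def feasible(self) -> bool:
        return self.loop_ok and self.max_overlap_fraction <= 0.20


@dataclass(frozen=True)
class RankedEntry:
    configuration: CandidateConfiguration
    solution: StitchSolution
    score: float
    report: FeasibilityReport


@dataclass
class RankedSolutions:
    """Feasible candidates sorted by ascending edge-alignment score."""

    entries: list[RankedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def scores(self) -> list[float]:
        return [e.score for e in self.entries]


def _pairs_for(placements: dict[str, Placement], n: int) -> tuple[AdjacentEdgePair, ...]:
    slots = {p.slot: fid for fid, p in placements.items()}
    if len(slots) != n:
        return ()
    table = QUAD_PAIR_TABLE if n == 4 else HALF_PAIR_TABLE
    pairs = []
    for slot_a, wside_a, slot_b, wside_b, axis in table:
        fa, fb = slots[slot_a], slots[slot_b]
        pairs.append(
            AdjacentEdgePair(
                fa,
                rotate_side(wside_a, -placements[fa].rotation_state % 360),
                fb,
                rotate_side(wside_b, -placements[fb].rotation_state % 360),
                axis,
            )
        )
    return tuple(pairs)


def make_configuration(placements: dict[str, Placement], anchor: str, index: int = 0) -> CandidateConfiguration:
    """Build a configuration (e.g. user-forced) from explicit placements."""
    n = len(placements)
    if n not in (2, 4):
        raise ValueError("only 2 or 4 fragments are supported")
    return CandidateConfiguration(n, dict(placements), _pairs_for(placements, n), anchor, index)


def enumerate_candidates(labels: dict[str, "EdgeLabelPair"]) -> list[CandidateConfiguration]:
    """All candidate arrangements given per-fragment stitch-edge labels.

    Four fragments: the first fragment is anchored in rotation state 0 (its
    label pair fixes its slot) and each remaining fragment independently
    takes one of the four rotation states, its rotated label determining its
    slot — exactly 64 candidates, including infeasible ones whose slots
    collide.  Two fragments: the single possible arrangement.
    """
    ids = list(labels)
    n = len(ids)
    if n not in (2, 4):
        raise ValueError(f"unsupported fragment count {n}; only 2 or 4 fragments")

    def slot_for(fid: str, state: int) -> str:
        sides = frozenset(rotate_side(s, state) for s in labels[fid].sides)
        return _SLOT_OF_SIDES[sides]

    anchor = ids[0]
    if n == 2:
        a_side = next(iter(labels[anchor].sides))
        b_side = next(iter(labels[ids[1]].sides))
        target = rotate_side(a_side, 180)  # opposite side faces the anchor
        state = next(s for s in (0, 90, 180, 270) if rotate_side(b_side, s) == target)
        placements = {
            anchor: Placement(slot_for(anchor, 0), 0),
            ids[1]: Placement(slot_for(ids[1], state), state),
        }
        return [make_configuration(placements, anchor, 0)]

    candidates = []
    for idx, states in enumerate(itertools.product((0, 90, 180, 270), repeat=n - 1)):
        placements = {anchor: Placement(slot_for(anchor, 0), 0)}
        for fid, state in zip(ids[1:], states):
            placements[fid] = Placement(slot_for(fid, state), state)
        candidates.append(
            CandidateConfiguration(n, placements, _pairs_for(placements, n), anchor, idx)
        )
    return candidates


def oriented_landmarks(
    edge_poly: np.ndarray,
    transform: RigidTransform,
    axis: int,
    k: int,
    fragment_id: str = "",
) -> LandmarkSet:
    """Resample ``k`` landmarks on an edge, ordered ascending along ``axis``
    in the *placed* frame so paired edges correspond index-wise."""
    placed_ends = transform.apply(np.vstack([edge_poly[0], edge_poly[-1]]))
    poly = edge_poly if placed_ends[0, axis] <= placed_ends[1, axis] else edge_poly[::-1]
    return resample_polyline(poly, k, fragment_id=fragment_id)


def _align_edge(
    placed_partner: np.ndarray, placed_own: np.ndarray, max_extra_rot_deg: float = 45.0
) -> np.ndarray:
    """Rigid map (3x3) bringing an ordered edge onto its partner edge.

    Least-squares rotation (clamped so a candidate cannot drift into a
    neighbouring 90-degree rotation state) about the edge mean, plus the
    translation that makes the edge midpoints coincide.
    """
    mean_a = placed_partner.mean(axis=0)
    mean_q = placed_own.mean(axis=0)
    a0 = placed_partner - mean_a
    q0 = placed_own - mean_q
    h = q0.T @ a0
    theta = np.rad2deg(np.arctan2(h[0, 1] - h[1, 0], h[0, 0] + h[1, 1]))
    theta = float(np.clip(theta, -max_extra_rot_deg, max_extra_rot_deg))
    from .transform import rotation_matrix

    rot = rotation_matrix(theta)
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = mean_a - rot @ mean_q
    return m


def coarse_place(
    candidate: CandidateConfiguration,
    fragments: dict[str, TissueFragment],
    edges: dict[tuple[str, str], StitchEdge],
    k: int = 32,
    min_edge_px: float = 4.0,
) -> StitchSolution:
    """Closed-form initial placement for a candidate at a coarse level.

    Each fragment is rotated by its rotation state about its mask centroid;
    walking the adjacency cycle outward from the anchor, every fragment is
    rigidly aligned so its stitch edge matches the already-placed partner
    edge in order: midpoints coincide and the least-squares residual over
    the ordered landmarks is minimized.
    """
    if not candidate.loop_ok:
        raise InfeasibleConfigurationError("slot assignment is not a bijection")
    factor = next(iter(fragments.values())).level_factor
    for pair in candidate.adjacent_pairs:
        for fid, side in ((pair.fragment_a, pair.side_a), (pair.fragment_b, pair.side_b)):
            if edges[(fid, side)].arclength() < min_edge_px:
                raise InfeasibleConfigurationError(
                    f"stitch edge {fid}:{side} degenerate at this level"
                )

    transforms: dict[str, RigidTransform] = {}
    for fid, frag in fragments.items():
        state = candidate.placements[fid].rotation_state
        transforms[fid] = RigidTransform(
            float(state), (0.0, 0.0), tuple(frag.centroid()), factor
        )
    placed = {candidate.anchor}
    pending = list(candidate.adjacent_pairs)
    while len(placed) < candidate.n:
        progressed = False
        for pair in pending:
            known, new, side_known, side_new = None, None, None, None
            if pair.fragment_a in placed and pair.fragment_b not in placed:
                known, new = pair.fragment_a, pair.fragment_b
                side_known, side_new = pair.side_a, pair.side_b
            elif pair.fragment_b in placed and pair.fragment_a not in placed:
                known, new = pair.fragment_b, pair.fragment_a
                side_known, side_new = pair.side_b, pair.side_a
            else:
                continue
            lm_known = oriented_landmarks(
                edges[(known, side_known)].polyline, transforms[known], pair.axis, k
            )
            lm_new = oriented_landmarks(
                edges[(new, side_new)].polyline, transforms[new], pair.axis, k
            )
            align = _align_edge(
                transforms[known].apply(lm_known.points),
                transforms[new].apply(lm_new.points),
            )
            transforms[new] = RigidTransform.from_matrix(
                align @ transforms[new].matrix, transforms[new].center, factor
            )
            placed.add(new)
            progressed = True
        if not progressed:
            raise InfeasibleConfigurationError("adjacency pairs do not connect all fragments")

    solution = StitchSolution(transforms, candidate, np.nan, factor)
    cost = configuration_score(solution, edges, k)
    return StitchSolution(transforms, candidate, cost, factor)


def configuration_score(
    solution: StitchSolution,
    edges: dict[tuple[str, str], StitchEdge],
    k: int = 32,
    squared: bool = False,
) -> float:
    """Mean over adjacent pairs of the mean index-wise landmark distance."""
    dists = []
    for pair in solution.configuration.adjacent_pairs:
        ta = solution.transforms[pair.fragment_a]
        tb = solution.transforms[pair.fragment_b]
        lm_a = oriented_landmarks(edges[(pair.fragment_a, pair.side_a)].polyline, ta, pair.axis, k)
        lm_b = oriented_landmarks(edges[(pair.fragment_b, pair.side_b)].polyline, tb, pair.axis, k)
        d = np.linalg.norm(ta.apply(lm_a.points) - tb.apply(lm_b.points), axis=1)
        dists.append(np.mean(d**2) if squared else d.mean())
    return float(np.mean(dists))


def overlap_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap as a fraction of the smaller fragment: |A n B| / min(|A|, |B|)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na == 0 or nb == 0:
        raise ValueError("overlap undefined for an empty mask")
    inter = int((mask_a & mask_b).sum())
    return inter / min(na, nb)


def placed_masks(
    fragments: dict[str, TissueFragment],
    transforms: dict[str, RigidTransform],
    margin: int = 2,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Warp all fragment masks onto a common canvas; returns masks + origin."""
    corners_all = []
    for fid, frag in fragments.items():
        h, w = frag.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
        corners_all.append(transforms[fid].apply(corners))
    corners_all = np.vstack(corners_all)
    lo = np.floor(corners_all.min(axis=0)).astype(int) - margin
    hi = np.ceil(corners_all.max(axis=0)).astype(int) + margin
    shape = (hi[1] - lo[1] + 1, hi[0] - lo[0] + 1)
    masks = {
        fid: warp_mask(frag.mask, transforms[fid].matrix, shape, origin=(lo[0], lo[1]))
        for fid, frag in fragments.items()
    }
    return masks, lo.astype(float)


def max_adjacent_overlap(solution: StitchSolution, fragments: dict[str, TissueFragment]) -> float:
    masks, _ = placed_masks(fragments, solution.transforms)
    worst = 0.0
    for pair in solution.configuration.adjacent_pairs:
        worst = max(worst, overlap_fraction(masks[pair.fragment_a], masks[pair.fragment_b]))
    return worst


def filter_and_rank(
    candidates: list[CandidateConfiguration],
    fragments: dict[str, TissueFragment],
    edges: dict[tuple[str, str], StitchEdge],
    k: int = 32,
    overlap_threshold: float = 0.20,
    squared: bool = False,
) -> RankedSolutions:
    """Keep loop-closing candidates with bounded overlap, ranked by score.

    Ties break on smaller maximum overlap, then enumeration order.
    """
    entries = []
    for cand in candidates:
        if not cand.loop_ok:
            continue
        try:
            solution = coarse_place(cand, fragments, edges, k)
        except InfeasibleConfigurationError:
            continue
        overlap = max_adjacent_overlap(solution, fragments)
        score = (
            configuration_score(solution, edges, k, squared=True) if squared else solution.cost
        )
        report = FeasibilityReport(True, overlap, score)
        if report.feasible:
            entries.append(RankedEntry(cand, solution, score, report))
    entries.sort(key=lambda e: (e.score, e.report.max_overlap_fraction, e.configuration.index))
    if not entries:
        raise InfeasibleConfigurationError(
            "no feasible fragment configuration found; consider manual "
            "--edges or --flip overrides"
        )
    return RankedSolutions(entries)


def top_n(ranked: RankedSolutions, n: int) -> RankedSolutions:
    """First ``min(n, len)`` ranked solutions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return RankedSolutions(ranked.entries[:n])
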