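"""Coarse-to-fine genetic-algorithm refinement of the stitch transforms.

Each candidate reconstruction is refined by minimizing the mean Euclidean
distance between k evenly sampled landmarks on every pair of adjacent stitch
edges,

    C_pair(f1, f2) = (1/k) sum_i || p_{f1,i} - p_{f2,i} ||_2
    C_total(S)     = (1/j) sum over the j adjacent pairs of C_pair,

over the (n - 1) * 3 free parameters (rotation + translation per
non-anchor fragment).  Every generation evaluates 40 solutions: the two
best survivors of the previous generation plus 38 bounded mutations of
them; a level ends when the best cost has not improved for 50 consecutive
generations (or at the generation cap).  The whole procedure runs over a
descending schedule of resolution levels, propagating and rescaling the
best solution between levels while shrinking the mutation bounds, so coarse
levels close the gap and fine levels fine-tune the interlock.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .configuration import StitchSolution, oriented_landmarks
from .geometry import LandmarkSet, StitchEdge, TissueFragment
from .transform import scale_points


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings (population 40 = 2 parents + 38 variants)."""

    population: int = 40
    n_parents: int = 2
    n_variants: int = 38
    patience_generations: int = 50
    max_generations: int = 200
    k_landmarks: int = 32
    rng_seed: int = 0

    def __post_init__(self):
        if self.population != self.n_parents + self.n_variants:
            raise ValueError("population must equal n_parents + n_variants")
        if self.patience_generations > self.max_generations:
            raise ValueError("patience cannot exceed max_generations")


@dataclass(frozen=True)
class MutationBounds:
    """Per-level caps on a single mutation step."""

    rotation_deg: float
    translation_px: float


@dataclass(frozen=True)
class ResolutionSchedule:
    """Descending downsampling factors, coarse to fine.

    The default desk-scale schedule keeps the canonical 2560:853:284:128
    whole-slide ratios, expressed relative to the finest working level.
    """

    factors: tuple[float, ...] = (20.0, 853 / 128, 284 / 128, 1.0)

    def __post_init__(self):
        if len(self.factors) < 1 or any(
            a <= b for a, b in zip(self.factors, self.factors[1:])
        ):
            raise ValueError("schedule factors must be strictly decreasing")


@dataclass(frozen=True)
class PairLandmarks:
    """Fixed fragment-frame landmark sets for one adjacent edge pair."""

    fragment_a: str
    points_a: np.ndarray  # (k, 2)
    fragment_b: str
    points_b: np.ndarray
    axis: int


@dataclass
class LevelTrace:
    factor: float
    spacing_um: float
    initial_cost: float
    final_cost: float
    generations: int
    best_costs: list[float] = field(default_factory=list)


def pair_cost(lm_a: LandmarkSet, lm_b: LandmarkSet, solution: StitchSolution) -> float:
    """Mean Euclidean distance between index-paired landmarks after placement."""
    if len(lm_a.points) != len(lm_b.points):
        raise ValueError("landmark sets must have identical k")
    pa = solution.transforms[lm_a.fragment_id].apply(lm_a.points)
    pb = solution.transforms[lm_b.fragment_id].apply(lm_b.points)
    return float(np.linalg.norm(pa - pb, axis=1).mean())


def total_cost(solution: StitchSolution, pairs: list[PairLandmarks]) -> float:
    """Mean of the pair costs over the j adjacent pairs."""
    if not pairs:
        raise ValueError("solution has no adjacent pairs (j = 0)")
    costs = [
        pair_cost(
            LandmarkSet(p.fragment_a, p.points_a),
            LandmarkSet(p.fragment_b, p.points_b),
            solution,
        )
        for p in pairs
    ]
    return float(np.mean(costs))


def make_generation(
    parents: np.ndarray, params: GAParams, bounds: MutationBounds, rng: np.random.Generator
) -> np.ndarray:
    """Next population: both parents unchanged plus bounded mutants.

    ``parents`` is ``(2, d)`` with the free parameters laid out as
    ``(rotation_deg, tx, ty)`` per non-anchor fragment.  Every mutant
    perturbs every free parameter by an independent uniform draw within the
    level's mutation bounds.
    """
    parents = np.atleast_2d(np.asarray(parents, dtype=float))
    if parents.shape[0] != params.n_parents:
        raise ValueError(f"expected {params.n_parents} parents")
    d = parents.shape[1]
    scale = np.tile(
        [bounds.rotation_deg, bounds.translation_px, bounds.translation_px], d // 3
    )
    base = parents[rng.integers(0, params.n_parents, size=params.n_variants)]
    mutants = base + rng.uniform(-1.0, 1.0, size=(params.n_variants, d)) * scale
    return np.vstack([parents, mutants])


class _CostModel:
    """Vectorized C_total over a population of parameter vectors."""

    def __init__(self, solution: StitchSolution, pairs: list[PairLandmarks]):
        self.anchor = solution.configuration.anchor
        self.free = [fid for fid in solution.transforms if fid != self.anchor]
        self.transforms = solution.transforms
        self.pairs = pairs
        # concatenate each fragment's landmark points once
        self.frag_points: dict[str, np.ndarray] = {}
        self.slices: dict[tuple[int, str], slice] = {}
        per_frag: dict[str, list[np.ndarray]] = {}
        for i, p in enumerate(pairs):
            for which, fid, pts in (("a", p.fragment_a, p.points_a), ("b", p.fragment_b, p.points_b)):
                lst = per_frag.setdefault(fid, [])
                start = sum(len(x) for x in lst)
                lst.append(np.asarray(pts, dtype=float))
                self.slices[(i, which)] = slice(start, start + len(pts))
        for fid, lst in per_frag.items():
            self.frag_points[fid] = np.vstack(lst)

    def params_of(self, solution: StitchSolution) -> np.ndarray:
        vec = []
        for fid in self.free:
            t = solution.transforms[fid]
            vec.extend([t.rotation_deg, t.translation[0], t.translation[1]])
        return np.asarray(vec, dtype=float)

    def solution_with(self, x: np.ndarray, template: StitchSolution, cost: float) -> StitchSolution:
        transforms = dict(template.transforms)
        for i, fid in enumerate(self.free):
            base = template.transforms[fid]
            transforms[fid] = replace(
                base,
                rotation_deg=float(x[3 * i]),
                translation=(float(x[3 * i + 1]), float(x[3 * i + 2])),
            )
        return StitchSolution(transforms, template.configuration, cost, template.level_factor)

    def costs(self, population: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(population)
        n = pop.shape[0]
        placed: dict[str, np.ndarray] = {}
        for i, fid in enumerate(self.free):
            pts = self.frag_points.get(fid)
            if pts is None:
                continue
            theta = np.deg2rad(pop[:, 3 * i])
            c, s = np.cos(theta), np.sin(theta)
            rot = np.empty((n, 2, 2))
            rot[:, 0, 0], rot[:, 0, 1] = c, -s
            rot[:, 1, 0], rot[:, 1, 1] = s, c
            center = np.asarray(self.transforms[fid].center)
            trans = pop[:, 3 * i + 1 : 3 * i + 3]
            placed[fid] = (
                np.einsum("nij,kj->nki", rot, pts - center) + center + trans[:, None, :]
            )
        if self.anchor in self.frag_points:
            anchor_pts = self.transforms[self.anchor].apply(self.frag_points[self.anchor])
            placed[self.anchor] = np.broadcast_to(
                anchor_pts, (n,) + anchor_pts.shape
            )
        pair_costs = np.empty((n, len(self.pairs)))
        for i, p in enumerate(self.pairs):
            pa = placed[p.fragment_a][:, self.slices[(i, "a")]]
            pb = placed[p.fragment_b][:, self.slices[(i, "b")]]
            pair_costs[:, i] = np.linalg.norm(pa - pb, axis=2).mean(axis=1)
        return pair_costs.mean(axis=1)


def optimize_level(
    initial: StitchSolution,
    pairs: list[PairLandmarks],
    params: GAParams,
    bounds: MutationBounds,
    rng: np.random.Generator,
) -> tuple[StitchSolution, list[float]]:
    """Run the GA at one resolution level; returns best solution + cost trace.

    Elitism (the two parents survive unchanged) makes the best-cost trace
    non-increasing.
    """
    model = _CostModel(initial, pairs)
    x0 = model.params_of(initial)
    parents = np.vstack([x0, x0])
    parent_costs = model.costs(parents)
    best_x, best_cost = parents[0], float(parent_costs[0])
    trace = [best_cost]
    stall = 0
    generations = 0
    for _ in range(params.max_generations):
        generations += 1
        population = make_generation(parents, params, bounds, rng)
        costs = model.costs(population)
        order = np.argsort(costs, kind="stable")
        parents = population[order[: params.n_parents]]
        gen_best = float(costs[order[0]])
        if gen_best < best_cost - 1e-12:
            best_cost = gen_best
            best_x = population[order[0]]
            stall = 0
        else:
            stall += 1
        trace.append(best_cost)
        if stall >= params.patience_generations:
            break
    return model.solution_with(best_x, initial, best_cost), trace


def level_landmark_pairs(
    solution: StitchSolution,
    native_edges: dict[tuple[str, str], StitchEdge],
    factor: float,
    k: int,
) -> list[PairLandmarks]:
    """Fix the landmark sets for one level.

    Edge polylines detected at the native working resolution are rescaled
    to the level, oriented along each pair's shared axis under the current
    placement, and resampled to ``k`` evenly spaced landmarks that then move
    rigidly with their fragment during optimization.
    """
    pairs = []
    for pair in solution.configuration.adjacent_pairs:
        out = {}
        for which, fid, side in (
            ("a", pair.fragment_a, pair.side_a),
            ("b", pair.fragment_b, pair.side_b),
        ):
            poly = scale_points(native_edges[(fid, side)].polyline, 1.0, factor)
            lm = oriented_landmarks(poly, solution.transforms[fid], pair.axis, k, fid)
            out[which] = lm.points
        pairs.append(
            PairLandmarks(pair.fragment_a, out["a"], pair.fragment_b, out["b"], pair.axis)
        )
    return pairs


def default_mutation_bounds(
    fragments: dict[str, TissueFragment], schedule: ResolutionSchedule
) -> list[MutationBounds]:
    """Per-level bounds: +-3 deg and +-3% of the coarse diagonal, halved at
    each finer level (translation expressed in that level's pixels)."""
    diag_native = max(float(np.hypot(*f.shape)) for f in fragments.values())
    bounds = []
    for i, f in enumerate(schedule.factors):
        bounds.append(
            MutationBounds(3.0 / 2**i, 0.03 * diag_native / (2**i * f))
        )
    return bounds


def optimize_multiresolution(
    coarse: StitchSolution,
    pyramids: dict[str, dict[float, TissueFragment]],
    native_edges: dict[tuple[str, str], StitchEdge],
    schedule: ResolutionSchedule,
    params: GAParams,
    bounds: list[MutationBounds] | None = None,
) -> tuple[StitchSolution, list[LevelTrace]]:
    """Refine a coarse placement over the full resolution schedule.

    The best solution of each level is rescaled and propagated to the next
    finer level; mutation bounds shrink so fine levels only fine-tune.
    """
    if bounds is None:
        fragments_fine = {
            fid: levels[schedule.factors[-1]] for fid, levels in pyramids.items()
        }
        bounds = default_mutation_bounds(fragments_fine, schedule)
    rng = np.random.default_rng(params.rng_seed)
    solution = coarse
    traces = []
    for level_bounds, factor in zip(bounds, schedule.factors):
        solution = solution.rescaled(factor)
        pairs = level_landmark_pairs(solution, native_edges, factor, params.k_landmarks)
        spacing = next(iter(pyramids.values()))[factor].spacing_um
        initial_cost = total_cost(solution, pairs)
        solution, trace = optimize_level(solution, pairs, params, level_bounds, rng)
        traces.append(
            LevelTrace(factor, spacing, initial_cost, solution.cost, len(trace) - 1, trace)
        )
    return solution, traces
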