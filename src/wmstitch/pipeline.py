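"""End-to-end orchestration: classify -> configure -> optimize -> render -> evaluate.

``run_case`` is the library entry point the CLI wraps: it takes 2 or 4
fragments with tissue masks, labels their stitch edges (geometric
classifier or manual override), searches feasible arrangements (bypassed
for two fragments, where only one arrangement exists), refines the top-N of
them with the multi-resolution genetic algorithm and renders/evaluates one
reconstruction per propagated solution.  A single master seed fans out to
all stochastic stages.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import classify, configuration, evaluate, ga, geometry, render
from .classify import EdgeLabelPair
from .configuration import (
    InfeasibleConfigurationError,
    Placement,
    RankedEntry,
    RankedSolutions,
    StitchSolution,
)
from .geometry import StitchEdge, TissueFragment
from .synthetic import SyntheticCase
from .transform import scale_points

logger = logging.getLogger("wmstitch")

EXIT_OK = 0
EXIT_INFEASIBLE = 2
EXIT_IO_ERROR = 3


@dataclass
class SolutionResult:
    """One propagated reconstruction: transforms, traces, reports, raster."""

    rank: int
    coarse_score: float
    solution: StitchSolution
    traces: list[ga.LevelTrace]
    report: evaluate.RegistrationReport | None = None
    gt_report: evaluate.RegistrationReport | None = None
    image: np.ndarray | None = None
    tissue_mask: np.ndarray | None = None
    paths: dict[str, str] = field(default_factory=dict)


@dataclass
class CaseResult:
    labels: dict[str, EdgeLabelPair]
    ranked: RankedSolutions | None
    solutions: list[SolutionResult]
    log: list[str] = field(default_factory=list)


def derive_seed(master_seed: int, stream: int) -> int:
    """Stable sub-seed below 2**31 for one stage of the pipeline."""
    return int(np.random.SeedSequence([master_seed, stream]).generate_state(1)[0] % 2**31)


class _EdgeCache:
    """Lazy per-fragment contour + stitch-edge extraction at native scale."""

    def __init__(self, fragments: dict[str, TissueFragment]):
        self.fragments = fragments
        self._contours: dict[str, geometry.Contour] = {}
        self._edges: dict[tuple[str, str], StitchEdge] = {}

    def contour(self, fid: str) -> geometry.Contour:
        if fid not in self._contours:
            self._contours[fid] = geometry.extract_contour(self.fragments[fid].mask)
        return self._contours[fid]

    def edge(self, fid: str, side: str) -> StitchEdge:
        key = (fid, side)
        if key not in self._edges:
            (edge,) = geometry.edges_from_labels(self.contour(fid), side, fragment_id=fid)
            self._edges[key] = edge
        return self._edges[key]

    def edges_for(self, candidates) -> dict[tuple[str, str], StitchEdge]:
        out = {}
        for cand in candidates:
            for pair in cand.adjacent_pairs:
                for fid, side in ((pair.fragment_a, pair.side_a), (pair.fragment_b, pair.side_b)):
                    out[(fid, side)] = self.edge(fid, side)
        return out

    def scaled(self, edges: dict[tuple[str, str], StitchEdge], factor: float):
        return {
            key: StitchEdge(e.fragment_id, e.side, scale_points(e.polyline, 1.0, factor))
            for key, e in edges.items()
        }


def _label_fragments(
    fragments: dict[str, TissueFragment],
    edge_overrides: dict[str, str],
    n: int,
    log: list[str],
) -> dict[str, EdgeLabelPair]:
    labels = {}
    for fid, frag in fragments.items():
        if fid in edge_overrides:
            labels[fid] = classify.manual_label(edge_overrides[fid])
        else:
            labels[fid] = classify.classify_edges_geometric(frag.mask, n)
            if labels[fid].confidence < 0.5:
                msg = (
                    f"fragment {fid}: low edge-label confidence "
                    f"{labels[fid].confidence:.2f}; consider --edges {fid}=..."
                )
                logger.warning(msg)
                log.append(msg)
    return labels


def run_case(
    fragments: list[TissueFragment],
    *,
    top_n_solutions: int = 4,
    seed: int = 0,
    ga_params: ga.GAParams | None = None,
    schedule: ga.ResolutionSchedule | None = None,
    edge_overrides: dict[str, str] | None = None,
    flip_ids: tuple[str, ...] = (),
    force_config: dict[str, tuple[str, int]] | None = None,
    gt_case: SyntheticCase | None = None,
    render_output: bool = True,
    tile_size: int = 1024,
    out_dir: str | os.PathLike | None = None,
) -> CaseResult:
    """Reconstruct one case; returns one result per propagated solution.

    ``force_config`` maps fragment id to ``(slot, rotation_state)`` and
    bypasses both classification and enumeration.  ``gt_case`` (a perturbed
    synthetic case) adds exact ground-truth registration reports.
    """
    log: list[str] = []
    n = len(fragments)
    if n not in (2, 4):
        raise ValueError("run_case supports exactly 2 or 4 fragments")
    frags = {f.id: (f.hflip() if f.id in flip_ids else f) for f in fragments}
    schedule = schedule or ga.ResolutionSchedule()
    params = ga_params or ga.GAParams()
    cache = _EdgeCache(frags)

    # --- stage 1: stitch-edge labels + candidate arrangements -----------
    ranked: RankedSolutions | None = None
    if force_config is not None:
        placements = {fid: Placement(slot, rot) for fid, (slot, rot) in force_config.items()}
        anchor = next(iter(frags))
        cand = configuration.make_configuration(placements, anchor)
        labels = {
            fid: classify.manual_label(tuple(sorted({p.side_a for p in cand.adjacent_pairs if p.fragment_a == fid} | {p.side_b for p in cand.adjacent_pairs if p.fragment_b == fid})))
            for fid in frags
        }
        candidates = [cand]
        log.append("forced configuration: enumeration bypassed")
    else:
        labels = _label_fragments(frags, edge_overrides or {}, n, log)
        candidates = configuration.enumerate_candidates(labels)
        if n == 2:
            log.append("two fragments: configuration enumeration bypassed")
        else:
            log.append(f"enumerated {len(candidates)} candidate configurations")

    native_edges = cache.edges_for(candidates)
    coarse_factor = schedule.factors[0]
    pyramids = {
        fid: dict(zip(schedule.factors, geometry.build_pyramid(f, schedule.factors)))
        for fid, f in frags.items()
    }
    coarse_frags = {fid: levels[coarse_factor] for fid, levels in pyramids.items()}
    coarse_edges = cache.scaled(native_edges, coarse_factor)

    if force_config is not None or n == 2:
        entries = []
        for cand in candidates:
            sol = configuration.coarse_place(cand, coarse_frags, coarse_edges, params.k_landmarks)
            overlap = configuration.max_adjacent_overlap(sol, coarse_frags)
            entries.append(
                RankedEntry(
                    cand,
                    sol,
                    sol.cost,
                    configuration.FeasibilityReport(True, overlap, sol.cost),
                )
            )
        ranked = RankedSolutions(entries)
    else:
        ranked = configuration.filter_and_rank(
            candidates, coarse_frags, coarse_edges, params.k_landmarks
        )
        log.append(f"{len(ranked)} feasible configurations after filtering")
    propagated = configuration.top_n(ranked, top_n_solutions)

    # --- stage 2+3: multi-resolution GA, rendering, evaluation ----------
    results = []
    failures = []
    for rank, entry in enumerate(propagated, start=1):
        try:
            run_params = ga.GAParams(
                population=params.population,
                n_parents=params.n_parents,
                n_variants=params.n_variants,
                patience_generations=params.patience_generations,
                max_generations=params.max_generations,
                k_landmarks=params.k_landmarks,
                rng_seed=derive_seed(seed, rank),
            )
            final, traces = ga.optimize_multiresolution(
                entry.solution, pyramids, native_edges, schedule, run_params
            )
            fine_frags = {fid: levels[schedule.factors[-1]] for fid, levels in pyramids.items()}
            fine_edges = cache.scaled(native_edges, schedule.factors[-1])
            report = evaluate.evaluation_report(final, fine_frags, fine_edges)
            gt_report = evaluate.ground_truth_error(final, gt_case, fine_frags) if gt_case else None
            result = SolutionResult(rank, entry.score, final, traces, report, gt_report)
            if render_output:
                result.image, result.tissue_mask, _ = render.composite(
                    fine_frags, final, tile_size=tile_size
                )
            if out_dir is not None:
                _write_solution(result, fine_frags, out_dir)
            log.append(
                f"solution {rank}: coarse score {entry.score:.2f} px, "
                f"final cost {final.cost:.2f} px, "
                f"auto-landmark error {report.median_mm:.3f} mm"
            )
            results.append(result)
        except Exception as exc:  # keep going with remaining solutions
            failures.append((rank, exc))
            log.append(f"solution {rank} failed: {exc}")
    if not results:
        raise RuntimeError(f"all propagated solutions failed: {failures}")
    return CaseResult(labels, ranked, results, log)


def _write_solution(result: SolutionResult, fragments, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    stem = os.path.join(os.fspath(out_dir), f"reconstruction_rank{result.rank}")
    spacing = next(iter(fragments.values())).spacing_um
    if result.image is not None:
        preview = render.write_pyramid(result.image, stem + ".tiff", spacing)
        result.paths["tiff"] = stem + ".tiff"
        result.paths["preview"] = preview
    manifest = {
        "rank": result.rank,
        "coarse_score_px": result.coarse_score,
        "final_cost_px": result.solution.cost,
        "level_factor": result.solution.level_factor,
        "spacing_um": spacing,
        "transforms": {
            fid: {
                "rotation_deg": t.rotation_deg,
                "translation_px": list(t.translation),
                "center_px": list(t.center),
            }
            for fid, t in result.solution.transforms.items()
        },
        "configuration": {
            fid: {"slot": p.slot, "rotation_state": p.rotation_state, "flip": p.flip}
            for fid, p in result.solution.configuration.placements.items()
        },
        "levels": [
            {
                "factor": tr.factor,
                "spacing_um": tr.spacing_um,
                "initial_cost_px": tr.initial_cost,
                "final_cost_px": tr.final_cost,
                "generations": tr.generations,
            }
            for tr in result.traces
        ],
        "evaluation": result.report.summary() if result.report else None,
        "ground_truth_evaluation": result.gt_report.summary() if result.gt_report else None,
    }
    with open(stem + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    result.paths["manifest"] = stem + ".json"
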