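"""Locate each fragment's stitch edges: geometric default, manual override.

Quartered whole-mount fragments are roughly quarter-ellipses: two borders
are sectioning cuts (straight-ish) and the rest is the curved organ outline.
The classifier therefore only has to decide which two *adjacent* bounding-box
sides the cuts face — one of four classes — or, for halved specimens, which
single side (left or right).  The default backend scores each class by how
straight its candidate border arcs are; a manual override always wins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .geometry import TissueFragment, edges_from_labels, extract_contour, EdgeDetectionError

#: the four quadrant classes: both stitch edges are always on adjacent sides
QUAD_CLASSES = (("left", "top"), ("top", "right"), ("right", "bottom"), ("bottom", "left"))
HALF_CLASSES = (("left",), ("right",))


@dataclass(frozen=True)
class EdgeLabelPair:
    """Stitch-edge side label(s) for one fragment, with provenance."""

    sides: tuple[str, ...]
    confidence: float
    source: str  # geometric | learned | manual

    def __post_init__(self):
        if len(self.sides) == 2:
            from .geometry import SORT_AXIS

            if SORT_AXIS[self.sides[0]] == SORT_AXIS[self.sides[1]]:
                raise ValueError("quadrant labels must name adjacent sides")


def _arc_deviation(polyline: np.ndarray, diag: float) -> float:
    """Maximum perpendicular deviation of an arc from its chord, / bbox diag.

    Near zero for a sectioning cut (slightly curved), large for the organ
    outline arc; normalizing by the mask diagonal makes the score scale-free.
    """
    p0, p1 = polyline[0], polyline[-1]
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return np.inf
    u = chord / norm
    rel = polyline - p0
    d = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
    return float(d.max() / diag)


def classify_edges_geometric(mask: np.ndarray, n_fragments: int) -> EdgeLabelPair:
    """Label the stitch-edge side(s) of a fragment from its mask alone.

    Every class's candidate arcs are extracted the same way the stitching
    stage extracts edges, and the class whose arcs deviate least from their
    chords wins.  Confidence is the relative margin over the runner-up,
    mapped to [0, 1]; below 0.5 a manual override is advisable.  The score
    is a pure function of the mask, so the prediction is deterministic and
    equivariant under 90-degree rotations and mirror flips.
    """
    if n_fragments not in (2, 4):
        raise ValueError("only 2 or 4 fragments are supported")
    contour = extract_contour(mask)
    bbox = contour.bbox()
    diag = float(np.hypot(bbox[2] - bbox[0], bbox[3] - bbox[1]))
    classes = QUAD_CLASSES if n_fragments == 4 else HALF_CLASSES

    min_x, min_y, max_x, max_y = bbox
    side_len = {
        "left": max_y - min_y,
        "right": max_y - min_y,
        "top": max_x - min_x,
        "bottom": max_x - min_x,
    }
    scores = []
    for sides in classes:
        try:
            edges = edges_from_labels(contour, sides)
            # a sectioning cut spans most of its bounding-box side; a short
            # sliver arc near a corner is never a stitch edge
            if any(
                np.linalg.norm(e.polyline[-1] - e.polyline[0]) < 0.3 * side_len[e.side]
                for e in edges
            ):
                scores.append(np.inf)
                continue
            lengths = np.array([e.arclength() for e in edges])
            devs = np.array([_arc_deviation(e.polyline, diag) for e in edges])
            scores.append(float(np.average(devs, weights=lengths)))
        except EdgeDetectionError:
            scores.append(np.inf)
    scores = np.asarray(scores)
    if not np.isfinite(scores).any():
        raise EdgeDetectionError(
            "no stitch-edge corners detectable on this fragment; "
            "specify the stitch edges manually"
        )
    order = np.argsort(scores)
    best, runner = scores[order[0]], scores[order[1]]
    if not np.isfinite(runner):
        confidence = 1.0
    else:
        confidence = float(np.clip((runner - best) / max(runner + best, 1e-12), 0.0, 1.0))
    return EdgeLabelPair(classes[int(order[0])], confidence, "geometric")


def manual_label(sides) -> EdgeLabelPair:
    """Wrap a user-specified side label; always outranks other backends."""
    if isinstance(sides, str):
        sides = tuple(s for s in sides.replace("+", " ").split() if s)
    return EdgeLabelPair(tuple(sides), 1.0, "manual")


def prepare_classifier_input(fragment: TissueFragment, target_um: float = 16.0, size: int = 512) -> np.ndarray:
    """Normalize a fragment image for a learned stitch-edge classifier.

    Resamples to 16 um/px, pads with white to a square and resizes to
    512 x 512 — the canonical input geometry for CNN-based edge labeling.
    """
    if fragment.spacing_um is None or fragment.spacing_um <= 0:
        raise ValueError("fragment pixel spacing is required")
    img = fragment.image
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    img = np.where(fragment.mask[..., None], img, 255).astype(np.uint8)
    zoom = fragment.spacing_um / target_um
    h = max(1, int(round(img.shape[0] * zoom)))
    w = max(1, int(round(img.shape[1] * zoom)))
    if (h, w) != img.shape[:2]:
        img = np.clip(
            np.rint(sktransform.resize(img, (h, w), anti_aliasing=zoom < 1, preserve_range=True)),
            0,
            255,
        ).astype(np.uint8)
    side = max(h, w)
    canvas = np.full((side, side, 3), 255, dtype=np.uint8)
    oy, ox = (side - h) // 2, (side - w) // 2
    canvas[oy : oy + h, ox : ox + w] = img
    if side != size:
        canvas = np.clip(
            np.rint(
                sktransform.resize(canvas, (size, size), anti_aliasing=side > size, preserve_range=True)
            ),
            0,
            255,
        ).astype(np.uint8)
    return canvas
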