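"""Tissue fragments, contours, stitch edges and resolution pyramids.

A *stitch edge* is the stretch of a fragment's border created by sectioning,
along which it must be rejoined to its neighbour.  Edges are addressed by the
side of the fragment's axis-aligned bounding box they face (``left``,
``right``, ``top``, ``bottom``) and their points are kept ordered along the
axis shared with the partner edge (``y`` for left/right, ``x`` for
top/bottom) so that evenly resampled landmarks correspond index-wise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, transform as sktransform

SIDES = ("left", "right", "top", "bottom")
#: axis along which each side's edge points are ordered (0 = x, 1 = y)
SORT_AXIS = {"left": 1, "right": 1, "top": 0, "bottom": 0}


class EdgeDetectionError(RuntimeError):
    """Raised when stitch-edge corners cannot be located on a contour."""


@dataclass
class TissueFragment:
    """One digitized tissue fragment: image, tissue mask and pixel spacing."""

    id: str
    image: np.ndarray
    mask: np.ndarray
    spacing_um: float
    flip_applied: bool = False
    level_factor: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"fragment {self.id!r}: image {self.image.shape[:2]} and "
                f"mask {self.mask.shape} grids differ"
            )
        if not self.mask.any():
            raise ValueError(f"fragment {self.id!r}: empty tissue mask")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def centroid(self) -> np.ndarray:
        """Tissue-mask centroid as ``(x, y)``."""
        ys, xs = np.nonzero(self.mask)
        return np.array([xs.mean(), ys.mean()])

    def hflip(self) -> "TissueFragment":
        """Horizontally mirrored copy (manual flip correction)."""
        return replace(
            self,
            image=self.image[:, ::-1].copy(),
            mask=self.mask[:, ::-1].copy(),
            flip_applied=not self.flip_applied,
        )


@dataclass(frozen=True)
class Contour:
    """Closed, simplified boundary polyline of a tissue mask.

    ``points`` is an ``(n, 2)`` array of ``(x, y)`` vertices with fixed
    positive-shoelace winding; the closing segment back to ``points[0]`` is
    implicit.
    """

    points: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def bbox(self) -> tuple[float, float, float, float]:
        """``(min_x, min_y, max_x, max_y)``."""
        mn = self.points.min(axis=0)
        mx = self.points.max(axis=0)
        return float(mn[0]), float(mn[1]), float(mx[0]), float(mx[1])


@dataclass(frozen=True)
class StitchEdge:
    """Open polyline along a fragment border designated for stitching."""

    fragment_id: str
    side: str
    polyline: np.ndarray

    @property
    def sort_axis(self) -> int:
        return SORT_AXIS[self.side]

    def arclength(self) -> float:
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())


@dataclass(frozen=True)
class LandmarkSet:
    """``k`` points sampled at fixed arclength fractions along a stitch edge."""

    fragment_id: str
    points: np.ndarray
    arclength_fractions: np.ndarray = field(default=None)


def extract_contour(mask: np.ndarray, simplify_tol: float = 1.0) -> Contour:
    """Boundary of the largest connected component of ``mask``, hole-filled.

    The marching-squares boundary is polygon-simplified with a 1 px
    Douglas-Peucker tolerance; winding is normalized.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("no tissue: mask is empty")
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    mask = ndi.binary_fill_holes(mask)
    padded = np.pad(mask, 1).astype(float)
    rings = measure.find_contours(padded, 0.5)
    ring = max(rings, key=len) - 1.0  # undo pad; (row, col)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    pts = measure.approximate_polygon(ring, tolerance=simplify_tol)
    if np.allclose(pts[0], pts[-1]) and len(pts) > 1:
        pts = pts[:-1]
    pts = pts[:, ::-1]  # (x, y)
    closed = np.vstack([pts, pts[:1]])
    area2 = np.sum(closed[:-1, 0] * closed[1:, 1] - closed[1:, 0] * closed[:-1, 1])
    if area2 < 0:
        pts = pts[::-1]
    return Contour(np.ascontiguousarray(pts, dtype=float))


_CORNER_DIRS = {
    "TL": np.array([-1.0, -1.0]),
    "TR": np.array([1.0, -1.0]),
    "BL": np.array([-1.0, 1.0]),
    "BR": np.array([1.0, 1.0]),
}
#: bounding-box corners flanking each side
_SIDE_CORNERS = {
    "left": ("TL", "BL"),
    "right": ("TR", "BR"),
    "top": ("TL", "TR"),
    "bottom": ("BL", "BR"),
}


def _support_vertex(points: np.ndarray, direction: np.ndarray) -> int:
    """Index of the vertex furthest along ``direction`` (bbox-corner support)."""
    return int(np.argmax(points @ direction))


def _corner_angle(points: np.ndarray, idx: int, reach: int) -> float:
    """Interior angle (deg) at a vertex, probed ``reach`` vertices away."""
    n = len(points)
    a = points[(idx - reach) % n] - points[idx]
    b = points[(idx + reach) % n] - points[idx]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 180.0
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(cosang)))


def _arc_between(points: np.ndarray, i: int, j: int) -> np.ndarray:
    """Contour vertices from index ``i`` to ``j`` following vertex order."""
    n = len(points)
    if i <= j:
        return points[i : j + 1]
    return np.vstack([points[i:], points[: j + 1]])


def _side_distance(arc: np.ndarray, side: str, bbox) -> float:
    min_x, min_y, max_x, max_y = bbox
    if side == "left":
        return float(np.mean(arc[:, 0] - min_x))
    if side == "right":
        return float(np.mean(max_x - arc[:, 0]))
    if side == "top":
        return float(np.mean(arc[:, 1] - min_y))
    return float(np.mean(max_y - arc[:, 1]))


def _monotone(polyline: np.ndarray, axis: int) -> np.ndarray:
    """Order points by increasing coordinate along ``axis``, dropping ties."""
    order = np.argsort(polyline[:, axis], kind="stable")
    pts = polyline[order]
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.diff(pts[:, axis]) > 0
    return pts[keep]


def edges_from_labels(
    contour: Contour,
    sides,
    *,
    fragment_id: str = "",
    max_corner_angle: float = 155.0,
) -> list[StitchEdge]:
    """Split a contour into the stitch edges facing the labeled sides.

    Each requested side's edge runs between the contour's support vertices
    toward the two bounding-box corners flanking that side; of the two arcs
    joining them, the one lying closer to that side is kept.  Two adjacent
    requested sides therefore share exactly one corner vertex.  Edge points
    come out ordered along the side's sort axis.
    """
    if isinstance(sides, str):
        sides = (sides,)
    sides = tuple(sides)
    if not 1 <= len(sides) <= 2:
        raise ValueError("labels must name one side or two adjacent sides")
    if len(sides) == 2 and SORT_AXIS[sides[0]] == SORT_AXIS[sides[1]]:
        raise ValueError(f"sides {sides} are opposite, not adjacent")

    pts = contour.points
    bbox = contour.bbox()
    diag = float(np.hypot(bbox[2] - bbox[0], bbox[3] - bbox[1]))
    reach = max(2, len(pts) // 12)

    corner_idx: dict[str, int] = {}
    for side in sides:
        for corner in _SIDE_CORNERS[side]:
            if corner not in corner_idx:
                corner_idx[corner] = _support_vertex(pts, _CORNER_DIRS[corner])

    shared = None
    if len(sides) == 2:
        (shared,) = set(_SIDE_CORNERS[sides[0]]) & set(_SIDE_CORNERS[sides[1]])
        angle = _corner_angle(pts, corner_idx[shared], reach)
        if angle > max_corner_angle:
            raise EdgeDetectionError(
                f"no clear corner between sides {sides} (interior angle "
                f"{angle:.0f} deg); specify the stitch edges manually"
            )

    edges = []
    for side in sides:
        ca, cb = (corner_idx[c] for c in _SIDE_CORNERS[side])
        arc_fwd = _arc_between(pts, ca, cb)
        arc_bwd = _arc_between(pts, cb, ca)
        if len(arc_fwd) < 2 and len(arc_bwd) < 2:
            raise EdgeDetectionError(f"degenerate arc on side {side!r}")
        arc = min(
            (a for a in (arc_fwd, arc_bwd) if len(a) >= 2),
            key=lambda a: _side_distance(a, side, bbox),
        )
        if _side_distance(arc, side, bbox) > 0.45 * diag:
            raise EdgeDetectionError(
                f"arc for side {side!r} does not hug the bounding box; "
                "specify the stitch edges manually"
            )
        poly = _monotone(arc, SORT_AXIS[side])
        if len(poly) < 2:
            raise EdgeDetectionError(f"degenerate stitch edge on side {side!r}")
        edges.append(StitchEdge(fragment_id, side, poly))
    return edges


def polyline_arclength(polyline: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(polyline, float), axis=0), axis=1).sum())


def resample_polyline(polyline: np.ndarray, k: int, *, fragment_id: str = "") -> LandmarkSet:
    """``k`` landmarks at evenly spaced arclength fractions 0 ... 1."""
    if k < 2:
        raise ValueError("need at least 2 landmarks")
    pts = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("polyline has zero arclength")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    fractions = np.linspace(0.0, 1.0, k)
    targets = fractions * total
    xs = np.interp(targets, cum, pts[:, 0])
    ys = np.interp(targets, cum, pts[:, 1])
    return LandmarkSet(fragment_id, np.column_stack([xs, ys]), fractions)


def build_pyramid(fragment: TissueFragment, factors) -> list[TissueFragment]:
    """Downsampled copies of a fragment, one per factor (coarse -> fine).

    Images are area-averaged, masks nearest-resampled and re-thresholded,
    and the pixel spacing scales with the factor.
    """
    factors = list(factors)
    if any(f < 1 for f in factors):
        raise ValueError("pyramid factors must be >= 1")
    if factors != sorted(factors, reverse=True):
        raise ValueError("pyramid factors must be sorted coarse to fine (descending)")
    h, w = fragment.shape
    levels = []
    for f in factors:
        if f == 1:
            levels.append(replace(fragment, level_factor=fragment.level_factor))
            continue
        oh, ow = int(round(h / f)), int(round(w / f))
        if min(oh, ow) < 8:
            raise ValueError(
                f"factor {f} shrinks fragment {fragment.id!r} below 8 px; "
                "use a smaller resolution schedule"
            )
        img = sktransform.resize(
            fragment.image, (oh, ow), anti_aliasing=True, preserve_range=True
        )
        if np.issubdtype(fragment.image.dtype, np.integer):
            img = np.clip(np.rint(img), 0, 255).astype(fragment.image.dtype)
        msk = sktransform.resize(
            fragment.mask.astype(float), (oh, ow), order=0, anti_aliasing=False
        ) > 0.5
        levels.append(
            TissueFragment(
                fragment.id,
                img,
                msk,
                fragment.spacing_um * f,
                flip_applied=fragment.flip_applied,
                level_factor=fragment.level_factor * f,
            )
        )
    return levels
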