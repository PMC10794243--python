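"""Synthetic whole-mount sections with ground-truth fragmentation.

Real whole-mount slides cut into quadrants or halves are scarce and large,
so validation here rests on a generator that emulates the digitally-cut
test-set idea: draw a realistic-looking elliptical "tissue" section, cut it
along slightly curved lines into 2 or 4 fragments, then rotate/translate
(and optionally mirror) each fragment independently while recording the
exact inverse transforms and corresponding landmark pairs along every cut.
A stitching result can then be scored against exact ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .geometry import TissueFragment
from .transform import warp_mask, warp_raster

#: adjacency around the quadrant cycle: (slot_a, slot_b, shared sort axis)
QUAD_ADJACENCY = [("UL", "UR", 1), ("UR", "LR", 0), ("LR", "LL", 1), ("LL", "UL", 0)]
HALF_ADJACENCY = [("L", "R", 1)]


@dataclass(frozen=True)
class SyntheticWMS:
    """An artificial whole-mount section image with its tissue mask."""

    image: np.ndarray  # (H, W, 3) uint8, white background
    mask: np.ndarray  # (H, W) bool
    spacing_um: float
    seed: int


@dataclass(frozen=True)
class GroundTruthTransform:
    """Affine map from a fragment's own canvas back to the WMS frame."""

    matrix: np.ndarray  # 3x3, fragment (x, y) -> WMS (x, y)
    rotation_deg: float  # rotation applied during perturbation
    flip: bool

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]


@dataclass(frozen=True)
class LandmarkPair:
    """Corresponding points along one cut, seen from both fragments.

    ``points_wms`` are coordinates on the cut line in the WMS frame;
    ``points_a``/``points_b`` are the same physical points expressed in each
    fragment's own canvas, so mapping both through perfect placements must
    land them on identical coordinates (zero registration error).
    """

    fragment_a: str
    fragment_b: str
    axis: int  # sort axis shared by the paired stitch edges (0 = x, 1 = y)
    points_wms: np.ndarray
    points_a: np.ndarray
    points_b: np.ndarray


@dataclass
class SyntheticCase:
    """A cut (and possibly perturbed) synthetic whole-mount."""

    wms: SyntheticWMS
    fragments: list[TissueFragment]
    slots: dict[str, str]  # fragment id -> true slot (UL/UR/LL/LR or L/R)
    gt_transforms: dict[str, GroundTruthTransform]
    landmark_pairs: list[LandmarkPair]
    cut_curviness: float
    perturbed: bool = False
    seed: int = 0


def generate_wms(seed: int, size_px=(512, 512), spacing_um: float = 16.0) -> SyntheticWMS:
    """Draw an artificial whole-mount section.

    The tissue is an ellipse with low-order radial irregularities on a white
    canvas; the interior carries a pink base tone, smooth intensity noise and
    scattered dark blobs so that misalignment, blending seams and landmark
    placement are visually checkable.  Deterministic in ``seed``.
    """
    h, w = int(size_px[0]), int(size_px[1])
    if h < 256 or w < 256:
        raise ValueError("canvas must be at least 256 x 256 px")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    rng = np.random.default_rng(seed)

    cx = (w - 1) / 2 + rng.uniform(-0.03, 0.03) * w
    cy = (h - 1) / 2 + rng.uniform(-0.03, 0.03) * h
    a = 0.36 * w * rng.uniform(0.9, 1.1)
    b = 0.36 * h * rng.uniform(0.9, 1.1)
    tilt = np.deg2rad(rng.uniform(-20, 20))
    harmonics = [(m, rng.uniform(0.0, 0.03), rng.uniform(0, 2 * np.pi)) for m in range(2, 7)]

    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    u = (dx * np.cos(tilt) + dy * np.sin(tilt)) / a
    v = (-dx * np.sin(tilt) + dy * np.cos(tilt)) / b
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = np.ones_like(r)
    for m, amp, phase in harmonics:
        bound += amp * np.cos(m * theta + phase)
    mask = r <= bound

    # smooth intensity texture: bounded curvature keeps resampling gentle
    noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 6.0)
    noise = 10.0 * noise / noise.std()

    n_blobs = max(20, int(mask.sum() / 2000))
    blob = np.zeros((h, w))
    for sigma in (3.0, 4.5):
        splat = np.zeros((h, w))
        for _ in range(n_blobs // 2):
            by = rng.uniform(cy - 0.9 * b, cy + 0.9 * b)
            bx = rng.uniform(cx - 0.9 * a, cx + 0.9 * a)
            iy, ix = int(round(by)), int(round(bx))
            if 0 <= iy < h and 0 <= ix < w and mask[iy, ix]:
                splat[iy, ix] += rng.uniform(0.6, 1.0)
        blob += ndi.gaussian_filter(splat, sigma) * (2 * np.pi * sigma**2)
    blob = np.tanh(blob)  # smooth saturation keeps curvature bounded

    base = np.array([228.0, 178.0, 202.0])  # eosin-like pink
    dark = np.array([120.0, 70.0, 140.0])  # hematoxylin-like purple
    img = base[None, None, :] + noise[..., None]
    img = img + blob[..., None] * 0.5 * (dark - base)[None, None, :]
    img = np.clip(img, 0, 255)
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    out[mask] = np.rint(img[mask]).astype(np.uint8)

    frac = mask.mean()
    assert 0.25 <= frac <= 0.75, f"tissue area fraction {frac:.2f} out of range"
    assert ndi.label(mask)[1] == 1
    return SyntheticWMS(out, mask, float(spacing_um), int(seed))


def _bezier_cut(rng, span: int, anchor: float, curviness: float, diam: float) -> np.ndarray:
    """Slightly curved cut as a single-valued function over ``span`` rows/cols.

    Quadratic Bezier whose endpoints sit near ``anchor`` at either end of the
    canvas and whose control point is jittered sideways by
    ``curviness * diam``; returns the cross coordinate per index 0..span-1.
    """
    e0 = anchor + rng.uniform(-0.04, 0.04) * diam
    e1 = anchor + rng.uniform(-0.04, 0.04) * diam
    ctrl = (e0 + e1) / 2 + rng.uniform(-1.0, 1.0) * curviness * diam
    t = np.linspace(0.0, 1.0, 4 * span)
    cross = (1 - t) ** 2 * e0 + 2 * (1 - t) * t * ctrl + t**2 * e1
    along = (1 - t) ** 2 * 0 + 2 * (1 - t) * t * (span - 1) / 2 + t**2 * (span - 1)
    return np.interp(np.arange(span), along, cross)


def _pair_landmarks(part_a: np.ndarray, part_b: np.ndarray, axis: int, n_points: int):
    """Sample points on the boundary between two adjacent fragment masks.

    A landmark is the midpoint between a pixel of one fragment and a
    4-neighbouring pixel of the other, so the points lie exactly on the cut.
    """
    pts = []
    for dy, dx in ((0, 1), (1, 0)):
        for first, second in ((part_a, part_b), (part_b, part_a)):
            a = first[: first.shape[0] - dy, : first.shape[1] - dx]
            b = second[dy:, dx:]
            yy, xx = np.nonzero(a & b)
            if len(yy):
                pts.append(np.column_stack([xx + dx / 2, yy + dy / 2]))
    if not pts:
        return None
    pts = np.vstack(pts)
    pts = pts[np.argsort(pts[:, axis], kind="stable")]
    if len(pts) < n_points:
        return None
    idx = np.linspace(0, len(pts) - 1, n_points).round().astype(int)
    return pts[idx]


def cut_wms(
    wms: SyntheticWMS,
    n_fragments: int,
    curviness: float = 0.03,
    seed: int = 0,
    n_landmarks: int = 10,
) -> SyntheticCase:
    """Digitally cut a whole-mount into 2 halves or 4 quadrants.

    Cut lines are slightly curved (quadratic Bezier, sideways jitter
    ``curviness`` x mask diameter) so the fragments' stitch edges are not
    straight; the fragment masks exactly partition the WMS mask and >= 10
    corresponding landmark pairs are recorded along every cut.
    """
    if n_fragments not in (2, 4):
        raise ValueError("only 2 or 4 fragments are supported")
    h, w = wms.mask.shape
    ys, xs = np.nonzero(wms.mask)
    cx, cy = xs.mean(), ys.mean()
    diam = float(np.hypot(xs.max() - xs.min(), ys.max() - ys.min()))
    area = wms.mask.sum()
    rng = np.random.default_rng(seed)

    last_err = "cut produced an empty fragment"
    for _ in range(5):
        vx = cx + rng.uniform(-0.05, 0.05) * diam
        cut_v = _bezier_cut(rng, h, vx, curviness, diam)  # x = f(y)
        col = np.arange(w)[None, :]
        left = wms.mask & (col < cut_v[:, None])
        if n_fragments == 2:
            parts = {"L": left, "R": wms.mask & ~left}
            adjacency = HALF_ADJACENCY
        else:
            vy = cy + rng.uniform(-0.05, 0.05) * diam
            cut_h = _bezier_cut(rng, w, vy, curviness, diam)  # y = g(x)
            row = np.arange(h)[:, None]
            upper = wms.mask & (row < cut_h[None, :])
            parts = {
                "UL": left & upper,
                "UR": ~left & wms.mask & upper,
                "LL": left & ~upper,
                "LR": ~left & wms.mask & ~upper,
            }
            adjacency = QUAD_ADJACENCY
        if min(p.sum() for p in parts.values()) < 0.05 * area:
            last_err = "cut produced a near-empty fragment"
            continue

        pairs = []
        ok = True
        for slot_a, slot_b, axis in adjacency:
            pts = _pair_landmarks(parts[slot_a], parts[slot_b], axis, n_landmarks)
            if pts is None:
                ok = False
                last_err = f"too few landmark points along cut {slot_a}-{slot_b}"
                break
            pairs.append((slot_a, slot_b, axis, pts))
        if not ok:
            continue

        slot_order = list(parts)
        rng.shuffle(slot_order)
        ids = [f"frag{i}" for i in range(n_fragments)]
        slot_of = dict(zip(ids, slot_order))
        id_of_slot = {s: f for f, s in slot_of.items()}
        fragments = []
        for fid in ids:
            pmask = parts[slot_of[fid]]
            img = np.full_like(wms.image, 255)
            img[pmask] = wms.image[pmask]
            fragments.append(TissueFragment(fid, img, pmask, wms.spacing_um))
        identity = np.eye(3)
        gt = {fid: GroundTruthTransform(identity.copy(), 0.0, False) for fid in ids}
        landmark_pairs = [
            LandmarkPair(id_of_slot[sa], id_of_slot[sb], axis, pts, pts.copy(), pts.copy())
            for sa, sb, axis, pts in pairs
        ]
        return SyntheticCase(
            wms, fragments, slot_of, gt, landmark_pairs, float(curviness), False, int(seed)
        )
    raise RuntimeError(f"failed to cut WMS after 5 attempts: {last_err}")


def perturb_case(
    case: SyntheticCase,
    seed: int = 0,
    max_rot_deg: float = 20.0,
    max_shift_frac: float = 0.05,
    flip_prob: float = 0.0,
    margin: int = 8,
) -> SyntheticCase:
    """Independently rotate/translate/optionally mirror each fragment.

    Emulates what happens to the physical fragments during microscope-slide
    preparation.  Each fragment lands on its own cropped canvas; the
    recorded ground-truth transform maps that canvas back onto the WMS frame
    exactly (bit-exactly for 0/90-degree rotations, where the resampling
    path is pure index shuffling).
    """
    if case.perturbed:
        raise ValueError("case is already perturbed")
    rng = np.random.default_rng(seed)
    h, w = case.wms.mask.shape
    new_fragments = []
    gt = {}
    frag_points: dict[str, dict[int, np.ndarray]] = {f.id: {} for f in case.fragments}

    for frag in case.fragments:
        theta = rng.uniform(-max_rot_deg, max_rot_deg) if max_rot_deg > 0 else 0.0
        sx = int(round(rng.uniform(-max_shift_frac, max_shift_frac) * w)) if max_shift_frac > 0 else 0
        sy = int(round(rng.uniform(-max_shift_frac, max_shift_frac) * h)) if max_shift_frac > 0 else 0
        flip = bool(rng.random() < flip_prob)

        yy, xx = np.nonzero(frag.mask)
        x0, x1 = xx.min(), xx.max()
        y0, y1 = yy.min(), yy.max()
        c_wms = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
        lin = np.array(
            [
                [np.cos(np.deg2rad(theta)), -np.sin(np.deg2rad(theta))],
                [np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta))],
            ]
        )
        if flip:
            lin = lin @ np.diag([-1.0, 1.0])
        half = np.array([(x1 - x0 + 1) / 2.0, (y1 - y0 + 1) / 2.0])
        corners = np.array([[hx, hy] for hx in (-half[0], half[0]) for hy in (-half[1], half[1])])
        extent = np.abs(corners @ lin.T).max(axis=0) * 2
        pad = margin + max(abs(sx), abs(sy))
        cw = int(np.ceil(extent[0])) + 2 * pad
        ch = int(np.ceil(extent[1])) + 2 * pad
        cc = np.array([(cw - 1) / 2.0, (ch - 1) / 2.0])

        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = cc + np.array([sx, sy]) - lin @ c_wms
        if theta % 90 == 0:
            m[:2, 2] = np.rint(m[:2, 2])  # exact index-shuffle path

        img = warp_raster(frag.image, m, (ch, cw), order=1, cval=255)
        msk = warp_mask(frag.mask, m, (ch, cw))
        new_fragments.append(
            TissueFragment(frag.id, img, msk, frag.spacing_um, flip_applied=flip)
        )
        gt[frag.id] = GroundTruthTransform(np.linalg.inv(m), float(theta), flip)
        for i, pair in enumerate(case.landmark_pairs):
            for which in ("a", "b"):
                if getattr(pair, f"fragment_{which}") == frag.id:
                    pts = pair.points_wms @ m[:2, :2].T + m[:2, 2]
                    frag_points[frag.id][(i, which)] = pts

    new_pairs = [
        LandmarkPair(
            p.fragment_a,
            p.fragment_b,
            p.axis,
            p.points_wms,
            frag_points[p.fragment_a][(i, "a")],
            frag_points[p.fragment_b][(i, "b")],
        )
        for i, p in enumerate(case.landmark_pairs)
    ]
    return SyntheticCase(
        case.wms,
        new_fragments,
        dict(case.slots),
        gt,
        new_pairs,
        case.cut_curviness,
        True,
        case.seed,
    )


def composite_with_gt(case: SyntheticCase) -> np.ndarray:
    """Paste perturbed fragments back through their ground-truth transforms."""
    h, w = case.wms.mask.shape
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    for frag in case.fragments:
        m = case.gt_transforms[frag.id].matrix
        img = warp_raster(frag.image, m, (h, w), order=1, cval=255)
        msk = warp_mask(frag.mask, m, (h, w))
        out[msk] = img[msk]
    return out


def make_case(
    seed: int,
    n_fragments: int = 4,
    size_px=(512, 512),
    spacing_um: float = 16.0,
    curviness: float = 0.03,
    max_rot_deg: float = 20.0,
    max_shift_frac: float = 0.05,
    flip_prob: float = 0.0,
) -> SyntheticCase:
    """One-knob convenience: generate, cut and perturb from a master seed.

    Sub-seeds are derived from the master seed by fixed offsets so a case is
    fully reproducible from a single integer.
    """
    wms = generate_wms(seed, size_px, spacing_um)
    case = cut_wms(wms, n_fragments, curviness, seed=seed + 10_000)
    return perturb_case(
        case,
        seed=seed + 20_000,
        max_rot_deg=max_rot_deg,
        max_shift_frac=max_shift_frac,
        flip_prob=flip_prob,
    )
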