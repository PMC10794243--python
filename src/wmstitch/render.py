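"""Tile-based assembly of the final whole-mount with gradient blending.

The optimized rigid transforms are applied tile by tile so the working set
stays bounded by the tile size rather than the (potentially gigapixel)
canvas, and overlap zones between adjacent fragments are blended with a
distance-weighted alpha

    I(x, y) = alpha(x, y) I_A(x, y) + (1 - alpha(x, y)) I_B(x, y)

where alpha is proportional to the proximity of the pixel to each
fragment's exclusive tissue, so the transition tracks the seam.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi
from skimage import transform as sktransform

from .configuration import StitchSolution
from .geometry import TissueFragment
from .transform import warp_mask, warp_raster

BACKGROUND = 255  # white, matching the H&E slide background


@dataclass(frozen=True)
class BlendField:
    """Per-pixel weight of fragment A over an overlap region."""

    overlap: np.ndarray  # bool
    alpha: np.ndarray  # float in [0, 1], meaningful on the overlap

    def __post_init__(self):
        a = self.alpha[self.overlap]
        if a.size and (a.min() < 0 or a.max() > 1):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class TileGrid:
    """Half-open tile boxes covering a canvas."""

    canvas_shape: tuple[int, int]
    tile_size: int = 1024

    def __post_init__(self):
        if self.tile_size < 16:
            raise ValueError("tile_size must be >= 16")

    def boxes(self):
        h, w = self.canvas_shape
        for y0 in range(0, h, self.tile_size):
            for x0 in range(0, w, self.tile_size):
                yield (x0, y0, min(x0 + self.tile_size, w), min(y0 + self.tile_size, h))


def transform_tile(
    fragment: TissueFragment,
    matrix: np.ndarray,
    tile_box: tuple[int, int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Render one target tile of a placed fragment.

    Target pixels are inverse-mapped through the rigid transform
    (``matrix``: fragment frame -> canvas frame); bilinear for the image,
    nearest for the mask, white outside the source.
    """
    x0, y0, x1, y1 = tile_box
    shape = (y1 - y0, x1 - x0)
    img = warp_raster(fragment.image, matrix, shape, order=1, cval=BACKGROUND, origin=(x0, y0))
    msk = warp_mask(fragment.mask, matrix, shape, origin=(x0, y0))
    return img, msk


def compute_alpha(mask_a: np.ndarray, mask_b: np.ndarray) -> BlendField:
    """Distance-weighted blending weights over the overlap of two masks.

    For each overlap pixel, ``dA`` is the Euclidean distance to the nearest
    A-exclusive pixel and ``dB`` likewise for B; ``alpha = dB / (dA + dB)``
    (0.5 where both vanish), so pixels nearer fragment A resemble A.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    overlap = mask_a & mask_b
    alpha = np.zeros(mask_a.shape, dtype=float)
    if not overlap.any():
        return BlendField(overlap, alpha)
    da = ndi.distance_transform_edt(~(mask_a & ~mask_b))
    db = ndi.distance_transform_edt(~(mask_b & ~mask_a))
    denom = da + db
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, db / np.maximum(denom, 1e-12), 0.5)
    alpha[overlap] = a[overlap]
    return BlendField(overlap, alpha)


def _canvas_geometry(fragments, transforms, margin_frac=0.02):
    corners_all = []
    for fid, frag in fragments.items():
        h, w = frag.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        corners_all.append(transforms[fid].apply(corners))
    corners_all = np.vstack(corners_all)
    lo = corners_all.min(axis=0)
    hi = corners_all.max(axis=0)
    margin = margin_frac * float(np.hypot(*(hi - lo)))
    lo = np.floor(lo - margin).astype(int)
    hi = np.ceil(hi + margin).astype(int)
    return (int(hi[1] - lo[1] + 1), int(hi[0] - lo[0] + 1)), lo


def composite(
    fragments: dict[str, TissueFragment],
    solution: StitchSolution,
    tile_size: int = 1024,
    alpha_max_side: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the artificial whole-mount from placed fragments.

    Fragments are added in configuration-cycle order; single-covered pixels
    are copied, overlap pixels blended with the distance-weighted alpha of
    the already-assembled tissue versus the incoming fragment (overlaps of
    more than two fragments therefore blend pairwise, in cycle order).
    Warping runs tile by tile on a ``tile_size`` grid.  Alpha distance
    transforms are evaluated at a bounded working resolution
    (``alpha_max_side`` longest side) and upsampled.

    Returns ``(image, tissue_mask, canvas_origin)``; the origin locates the
    canvas in the placed frame.
    """
    order = [solution.configuration.anchor] + [
        fid for fid in solution.transforms if fid != solution.configuration.anchor
    ]
    shape, origin = _canvas_geometry(fragments, solution.transforms)
    grid = TileGrid(shape, tile_size)

    # placed masks once per fragment (tile-wise), reused for alpha fields
    placed_mask = {}
    for fid in order:
        m = np.zeros(shape, bool)
        mat = solution.transforms[fid].matrix
        for x0, y0, x1, y1 in grid.boxes():
            m[y0:y1, x0:x1] = warp_mask(
                fragments[fid].mask, mat, (y1 - y0, x1 - x0), origin=(x0 + origin[0], y0 + origin[1])
            )
        placed_mask[fid] = m

    scale = min(1.0, alpha_max_side / max(shape))
    canvas = np.full(shape + (3,), BACKGROUND, dtype=np.uint8)
    covered = np.zeros(shape, bool)
    for idx, fid in enumerate(order):
        mat = solution.transforms[fid].matrix
        overlap = covered & placed_mask[fid]
        field = None
        if overlap.any():
            if scale < 1.0:
                small = tuple(int(round(s * scale)) for s in shape)
                a_small = compute_alpha(
                    sktransform.resize(covered.astype(float), small, order=0) > 0.5,
                    sktransform.resize(placed_mask[fid].astype(float), small, order=0) > 0.5,
                ).alpha
                alpha_full = sktransform.resize(a_small, shape, order=1)
                field = BlendField(overlap, np.clip(alpha_full, 0.0, 1.0))
            else:
                field = compute_alpha(covered, placed_mask[fid])
        for x0, y0, x1, y1 in grid.boxes():
            box_mask = placed_mask[fid][y0:y1, x0:x1]
            if not box_mask.any():
                continue
            tile_img, tile_msk = transform_tile(
                fragments[fid], mat, (x0 + origin[0], y0 + origin[1], x1 + origin[0], y1 + origin[1])
            )
            tile_msk &= box_mask
            out = canvas[y0:y1, x0:x1]
            fresh = tile_msk & ~covered[y0:y1, x0:x1]
            out[fresh] = tile_img[fresh]
            if field is not None:
                ov = tile_msk & field.overlap[y0:y1, x0:x1]
                if ov.any():
                    a = field.alpha[y0:y1, x0:x1][ov][:, None]
                    blended = a * out[ov].astype(float) + (1.0 - a) * tile_img[ov].astype(float)
                    out[ov] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
        covered |= placed_mask[fid]
    return canvas, covered, origin.astype(float)


def write_pyramid(
    image: np.ndarray,
    path: str | os.PathLike,
    spacing_um: float,
    levels: int = 4,
    tile: int = 256,
    preview_max: int = 2048,
) -> str:
    """Write a tiled, multi-level TIFF plus a small PNG preview.

    Levels halve in size; pixel spacing is recorded as TIFF resolution
    metadata.  Returns the preview path.
    """
    path = os.fspath(path)
    px_per_cm = 10_000.0 / spacing_um
    try:
        with tifffile.TiffWriter(path, bigtiff=image.nbytes > 2**31) as tif:
            opts = dict(
                tile=(tile, tile),
                compression="deflate",
                resolution=(px_per_cm, px_per_cm),
                resolutionunit="CENTIMETER",
            )
            tif.write(image, subifds=levels - 1, **opts)
            lvl = image
            for _ in range(levels - 1):
                shape = (max(1, -(-lvl.shape[0] // 2)), max(1, -(-lvl.shape[1] // 2)))
                lvl = np.clip(
                    np.rint(
                        sktransform.resize(
                            lvl, shape, anti_aliasing=True, preserve_range=True
                        )
                    ),
                    0,
                    255,
                ).astype(np.uint8)
                tif.write(lvl, subfiletype=1, **opts)
    except Exception:
        if os.path.exists(path):
            os.remove(path)  # do not leave a truncated file behind
        raise
    preview_path = os.path.splitext(path)[0] + "_preview.png"
    h, w = image.shape[:2]
    s = min(1.0, preview_max / max(h, w))
    if s < 1.0:
        pshape = (max(1, int(round(h * s))), max(1, int(round(w * s))))
        preview = np.clip(
            np.rint(sktransform.resize(image, pshape, anti_aliasing=True, preserve_range=True)),
            0,
            255,
        ).astype(np.uint8)
    else:
        preview = image
    Image.fromarray(preview).save(preview_path)
    return preview_path
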