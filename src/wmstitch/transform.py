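"""Rigid 2-D transforms and raster warping in pixel coordinates.

Conventions used throughout the package: 0-based pixel centers, ``x`` is the
column index (increasing rightward), ``y`` the row index (increasing
downward); points are ``(x, y)`` pairs.  Rotation angles are
counter-clockwise in this frame (which reads as clockwise on screen because
``y`` points down).  Bounding boxes are half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 counter-clockwise rotation matrix for ``(x, y)`` column vectors."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a fixed center followed by a translation.

    Maps a point ``p`` to ``R(p - c) + c + t`` where ``R`` rotates by
    ``rotation_deg``, ``c`` is ``center`` and ``t`` is ``translation``, all
    in pixel units of the resolution level identified by ``level_factor``
    (the downsampling factor relative to the finest working level).
    """

    rotation_deg: float
    translation: tuple[float, float]
    center: tuple[float, float]
    level_factor: float = 1.0

    @classmethod
    def identity(cls, center=(0.0, 0.0), level_factor: float = 1.0) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0), tuple(center), level_factor)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center, level_factor: float = 1.0) -> "RigidTransform":
        """Express a homogeneous rigid matrix as rotation about ``center``."""
        angle = np.rad2deg(np.arctan2(matrix[1, 0], matrix[0, 0]))
        c = np.asarray(center, dtype=float)
        t = matrix[:2, :2] @ c + matrix[:2, 2] - c
        return cls(float(angle), (float(t[0]), float(t[1])), (float(c[0]), float(c[1])), level_factor)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on ``(x, y, 1)`` columns."""
        rot = rotation_matrix(self.rotation_deg)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = c + t - rot @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 2)`` array of ``(x, y)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rot = rotation_matrix(self.rotation_deg)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ rot.T + c + t

    def invert(self) -> "RigidTransform":
        rot_inv = rotation_matrix(-self.rotation_deg)
        t = np.asarray(self.translation)
        return RigidTransform(
            -self.rotation_deg,
            tuple(-(rot_inv @ t)),
            self.center,
            self.level_factor,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform.from_matrix(
            self.matrix @ other.matrix, self.center, self.level_factor
        )

    def rescaled(self, new_factor: float) -> "RigidTransform":
        """Re-express the transform at another pyramid level.

        Level coordinates relate by the pixel-center similarity
        ``s(p) = (p + 0.5) * (old/new) - 0.5``; rotation is unchanged and
        translation scales with the factor ratio.
        """
        a = self.level_factor / new_factor
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return RigidTransform(
            self.rotation_deg,
            tuple(a * t),
            tuple((c + 0.5) * a - 0.5),
            new_factor,
        )

    def translated(self, offset) -> "RigidTransform":
        """Add an extra translation (same level units) after the transform."""
        t = np.asarray(self.translation) + np.asarray(offset, dtype=float)
        return replace(self, translation=(float(t[0]), float(t[1])))


def scale_points(points: np.ndarray, old_factor: float, new_factor: float) -> np.ndarray:
    """Map pixel-center coordinates between pyramid levels."""
    a = old_factor / new_factor
    return (np.asarray(points, dtype=float) + 0.5) * a - 0.5


def _is_integer_translation(matrix: np.ndarray, tol: float = 1e-9) -> bool:
    return (
        abs(matrix[0, 0] - 1) < tol
        and abs(matrix[1, 1] - 1) < tol
        and abs(matrix[0, 1]) < tol
        and abs(matrix[1, 0]) < tol
        and abs(matrix[0, 2] - round(matrix[0, 2])) < tol
        and abs(matrix[1, 2] - round(matrix[1, 2])) < tol
    )


def warp_raster(
    src: np.ndarray,
    matrix: np.ndarray,
    out_shape: tuple[int, int],
    *,
    order: int = 1,
    cval: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Resample ``src`` under a forward homogeneous map ``src -> dst``.

    Output pixel ``(x, y)`` (offset by ``origin``, given as ``(x0, y0)``)
    is filled from ``src`` at ``matrix^-1 (x + x0, y + y0)``.  Grayscale or
    RGB; bilinear for ``order=1``, nearest for ``order=0``.  Pure integer
    translations take an exact slicing path so identity placements are
    bit-exact.
    """
    h, w = out_shape
    x0, y0 = origin
    if _is_integer_translation(matrix) and float(x0).is_integer() and float(y0).is_integer():
        tx = int(round(matrix[0, 2] - x0))
        ty = int(round(matrix[1, 2] - y0))
        out = np.full((h, w) + src.shape[2:], cval, dtype=src.dtype)
        sy0, sy1 = max(0, -ty), min(src.shape[0], h - ty)
        sx0, sx1 = max(0, -tx), min(src.shape[1], w - tx)
        if sy1 > sy0 and sx1 > sx0:
            out[sy0 + ty : sy1 + ty, sx0 + tx : sx1 + tx] = src[sy0:sy1, sx0:sx1]
        return out

    inv = np.linalg.inv(matrix)
    xs, ys = np.meshgrid(np.arange(w) + x0, np.arange(h) + y0)
    sx = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2]
    sy = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2]
    coords = np.stack([sy.ravel(), sx.ravel()])

    def _sample(plane):
        return ndi.map_coordinates(
            plane.astype(float), coords, order=order, mode="constant", cval=cval
        ).reshape(h, w)

    if src.ndim == 2:
        out = _sample(src)
    else:
        out = np.stack([_sample(src[..., ch]) for ch in range(src.shape[2])], axis=-1)
    if np.issubdtype(src.dtype, np.integer):
        info = np.iinfo(src.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(src.dtype)
    elif src.dtype == bool:
        out = out > 0.5
    return out


def warp_mask(mask: np.ndarray, matrix: np.ndarray, out_shape, *, origin=(0.0, 0.0)) -> np.ndarray:
    """Nearest-neighbour warp of a binary mask; background False."""
    return warp_raster(mask.astype(np.uint8), matrix, out_shape, order=0, cval=0, origin=origin).astype(bool)
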