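"""Optical-to-thermal registration from fiducial point correspondences.

The cameras capture an optical and a thermal frame of the same scene at
different resolutions and slightly different viewpoints. Corner points of an
identification card/sticker visible in both frames give point
correspondences, from which a 2-D affine map (optical pixel coordinates ->
thermal pixel coordinates) is estimated by least squares. Three non-collinear
correspondences determine the map exactly; more are combined in the
least-squares sense.

Coordinates are 0-based with x = column index, y = row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AffineMap", "estimate_affine"]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class AffineMap:
    """2x3 affine transform ``dst = A @ src + t``.

    ``matrix`` is the 2x3 array ``[A | t]`` acting on column vectors (x, y).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points) -> np.ndarray:
        """Apply the map to an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        t = -inv @ self.translation
        return AffineMap(np.column_stack([inv, t]))

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(np.column_stack([np.eye(2), np.zeros(2)]))


def _collinear(points: np.ndarray) -> bool:
    """True when all points lie (numerically) on one line."""
    p = points - points.mean(axis=0)
    # second singular value ~ 0 <=> rank-1 spread <=> collinear
    s = np.linalg.svd(p, compute_uv=False)
    scale = max(s[0], 1.0)
    return s[-1] / scale < _COLLINEAR_TOL


def estimate_affine(src_points, dst_points) -> AffineMap:
    """Least-squares affine map sending ``src_points`` onto ``dst_points``.

    Parameters
    ----------
    src_points, dst_points : array-like, shape (n, 2), n >= 3
        Matching (x, y) coordinates, e.g. sticker corners marked in the
        optical and thermal frames.

    Returns
    -------
    AffineMap
        Minimizer of the summed squared residuals; exact (zero residual)
        when exactly three non-collinear pairs are supplied.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) point arrays")
    if src.shape[0] < 3:
        raise ValueError("at least 3 point correspondences are required")
    if not np.all(np.isfinite(src)) or not np.all(np.isfinite(dst)):
        raise ValueError("points must be finite")
    if _collinear(src):
        raise ValueError("source points are collinear; affine map is degenerate")

    # dst = [src | 1] @ M.T  -> solve for M (2x3) column-block wise
    design = np.column_stack([src, np.ones(len(src))])
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineMap(coeffs.T)
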