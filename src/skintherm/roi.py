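"""Elliptical regions of interest on thermal frames.

The cooled site is outlined by >= 5 points clicked along the border of the
circle drawn on the skin; a best-fit ellipse through those points defines the
cooling ROI. A control region — the same ellipse scaled to 1/4 of each
semi-axis — is placed superior of the site along the image x-axis, displaced
by 1.5 x the cooling semi-major axis (the control ellipse's full long-axis
width, 2·a/4, plus the cooling semi-major axis a). When that default spot
hits an invalid region (sticker, clothing, off-body), the control ellipse is
relocated to the nearest valid center by an exhaustive radial sweep.

Pixel membership is exact at pixel centers: a pixel (x, y) belongs to an
ellipse iff the rotated-ellipse inequality evaluates to <= 1. Region
temperature is summarized by the median over member pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import cos, pi, sin

import numpy as np
from skimage.measure import EllipseModel

__all__ = [
    "EllipseROI",
    "fit_ellipse",
    "make_control_roi",
    "extract_median",
    "ellipse_mask",
]

#: Control-ellipse shrink factor applied to each semi-axis.
CONTROL_AXIS_RATIO = 0.25

#: Displacement of the control center from the cooling center along the image
#: x-axis, in units of the cooling semi-major axis a: full control long-axis
#: width (2 * a/4) plus the cooling semi-major axis (a).
CONTROL_OFFSET_FACTOR = 1.5

#: Sign of the "superior" direction along image x (toward the head in the
#: side-lying frames). Configurable because image orientation is a protocol
#: convention, not a property of the data.
SUPERIOR_SIGN = -1


@dataclass(frozen=True)
class EllipseROI:
    """Ellipse in pixel coordinates: center, semi-axes (a >= b), rotation.

    ``theta`` is measured counterclockwise from +x in radians, normalized to
    [0, pi) (an ellipse is invariant under a half-turn).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        object.__setattr__(self, "theta", float(self.theta) % pi)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])

    @property
    def area(self) -> float:
        return pi * self.a * self.b

    def contains(self, x, y) -> np.ndarray:
        """Exact membership test at point(s) (x, y)."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        c, s = cos(self.theta), sin(self.theta)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v <= 1.0

    def scaled(self, factor: float) -> "EllipseROI":
        return replace(self, a=self.a * factor, b=self.b * factor)

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseROI":
        return cls(d["cx"], d["cy"], d["a"], d["b"], d.get("theta", 0.0))


def fit_ellipse(points) -> EllipseROI:
    """Best-fit ellipse through >= 5 boundary points.

    Uses the direct algebraic least-squares conic fit with the ellipse
    constraint (Halir–Flusser), which is deterministic, needs no
    initialization, and recovers an exact ellipse from noise-free points.
    The result is canonicalized to a >= b with theta in [0, pi).

    Raises
    ------
    ValueError
        Fewer than 5 points, non-finite input, or a degenerate configuration
        whose best conic is not an ellipse.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 5:
        raise ValueError("at least 5 boundary points are required")
    if not np.all(np.isfinite(pts)):
        raise ValueError("boundary points must be finite")

    if hasattr(EllipseModel, "from_estimate"):  # skimage >= 0.26
        model = EllipseModel.from_estimate(pts)
        if not bool(model):
            raise ValueError(
                "degenerate point configuration: best-fit conic is not an ellipse"
            )
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        model = EllipseModel()
        if not model.estimate(pts) or model.params is None:
            raise ValueError(
                "degenerate point configuration: best-fit conic is not an ellipse"
            )
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError(
            "degenerate point configuration: best-fit conic is not an ellipse"
        )
    if a <= 0 or b <= 0:
        raise ValueError("degenerate point configuration: non-positive ellipse axis")
    if b > a:
        a, b = b, a
        theta += pi / 2.0
    return EllipseROI(float(xc), float(yc), float(a), float(b), float(theta))


def ellipse_mask(roi: EllipseROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centers fall inside ``roi``."""
    h, w = shape
    x0 = max(int(np.floor(roi.cx - roi.a)), 0)
    x1 = min(int(np.ceil(roi.cx + roi.a)), w - 1)
    y0 = max(int(np.floor(roi.cy - roi.a)), 0)
    y1 = min(int(np.ceil(roi.cy + roi.a)), h - 1)
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask[y0 : y1 + 1, x0 : x1 + 1] = roi.contains(xs, ys)
    return mask


def _placement_valid(roi: EllipseROI, shape: tuple[int, int], valid: np.ndarray | None) -> bool:
    h, w = shape
    if roi.cx - roi.a < -0.5 or roi.cx + roi.a > w - 0.5:
        return False
    if roi.cy - roi.a < -0.5 or roi.cy + roi.a > h - 0.5:
        return False
    mask = ellipse_mask(roi, shape)
    if not mask.any():
        return False
    if valid is not None and not valid[mask].all():
        return False
    return True


def make_control_roi(
    cooling: EllipseROI,
    frame_shape: tuple[int, int],
    valid_mask: np.ndarray | None = None,
    *,
    superior_sign: int = SUPERIOR_SIGN,
    offset_factor: float = CONTROL_OFFSET_FACTOR,
    axis_ratio: float = CONTROL_AXIS_RATIO,
    max_search_radius: int | None = None,
) -> EllipseROI:
    """Construct (and if necessary relocate) the control ellipse.

    The default placement scales the cooling semi-axes by ``axis_ratio`` and
    shifts the center by ``superior_sign * offset_factor * cooling.a`` along
    the image x-axis. If any member pixel is outside the frame or falls on an
    invalid ``valid_mask`` entry, the center is moved to the nearest valid
    position found by a deterministic radial sweep at 1-px steps (ties broken
    by smaller polar angle), preserving size and orientation.

    Raises
    ------
    RuntimeError
        No valid placement exists inside the frame.
    """
    control = replace(
        cooling,
        cx=cooling.cx + superior_sign * offset_factor * cooling.a,
        a=cooling.a * axis_ratio,
        b=cooling.b * axis_ratio,
    )
    if _placement_valid(control, frame_shape, valid_mask):
        return control

    h, w = frame_shape
    if max_search_radius is None:
        max_search_radius = int(np.ceil(np.hypot(h, w)))
    for radius in range(1, max_search_radius + 1):
        candidates = []
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                dist = np.hypot(dx, dy)
                if radius - 0.5 <= dist < radius + 0.5:
                    angle = np.arctan2(dy, dx) % (2 * pi)
                    candidates.append((dist, angle, dx, dy))
        candidates.sort(key=lambda t: (t[0], t[1]))
        for _, _, dx, dy in candidates:
            moved = replace(control, cx=control.cx + dx, cy=control.cy + dy)
            if _placement_valid(moved, frame_shape, valid_mask):
                return moved
    raise RuntimeError(
        "no valid control-region placement inside the frame "
        f"(cooling ROI center=({cooling.cx:.1f}, {cooling.cy:.1f}))"
    )


def extract_median(frame: np.ndarray, roi: EllipseROI, min_pixels: int = 5) -> float:
    """Median temperature (°C) over pixel centers inside ``roi``.

    Even pixel counts use the midpoint of the two central order statistics.
    """
    grid = np.asarray(frame, dtype=float)
    if grid.ndim != 2:
        raise ValueError("thermal frame must be a 2-D temperature grid")
    mask = ellipse_mask(roi, grid.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI contains no pixels")
    if n < min_pixels:
        raise ValueError(f"ROI contains only {n} pixels (minimum {min_pixels})")
    return float(np.median(grid[mask]))
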