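"""Melanin colorimetry: device-scale conversion and skin-tone categorization.

Reflected-light colorimeters report melanin on device-specific scales. The
SkinColorCatch melanin index must be converted to the ColorMeter DSM-II scale
before the modified Eumelanin Human Skin Colour Scale categories (whose
cutoffs are defined on the DSM-II scale) can be assigned. The conversion is
log-linear between the two devices:

    y = exp((x + offset) / scale)

with ``offset = 623.18`` and ``scale = 334.81`` fitted across PANTONE
skin-tone swatches. The mapping is strictly increasing and invertible on all
real inputs, so either scale can serve as a continuous covariate.

Category cutoffs (converted scale, half-open, left-closed):

    Low                [-inf, 25)
    IntermediateLow    [25, 37.5)
    Intermediate       [37.5, 50)
    IntermediateMid    [50, 75)
    IntermediateHigh   [75, 100)
    High               [100, inf)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConversionModel",
    "DEFAULT_CONVERSION",
    "EUMELANIN_CATEGORIES",
    "EUMELANIN_CUTOFFS",
    "convert_melanin",
    "invert_melanin",
    "categorize_melanin",
    "per_category_effect",
    "read_colorimetry_csv",
    "write_colorimetry_csv",
]


@dataclass(frozen=True)
class ConversionModel:
    """Log-linear device conversion ``y = exp((x + offset) / scale)``.

    Parameters
    ----------
    offset : float
        Additive constant on the source (SkinColorCatch) scale.
    scale : float
        Divisor; must be positive so the conversion is strictly increasing.
    """

    offset: float = 623.18
    scale: float = 334.81

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")

    def convert(self, x):
        """Map source-scale melanin index to the converted (DSM-II) scale."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("melanin index must be finite")
        out = np.exp((x + self.offset) / self.scale)
        return float(out) if out.ndim == 0 else out

    def invert(self, y):
        """Map a converted melanin value back to the source scale."""
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("converted melanin value must be finite and > 0")
        out = self.scale * np.log(y) - self.offset
        return float(out) if out.ndim == 0 else out


DEFAULT_CONVERSION = ConversionModel()

#: Ordered (name, lower-bound) pairs on the converted scale; intervals are
#: half-open [lo, next_lo) so the set is disjoint and exhaustive.
EUMELANIN_CUTOFFS: tuple[tuple[str, float], ...] = (
    ("Low", -math.inf),
    ("IntermediateLow", 25.0),
    ("Intermediate", 37.5),
    ("IntermediateMid", 50.0),
    ("IntermediateHigh", 75.0),
    ("High", 100.0),
)

EUMELANIN_CATEGORIES: tuple[str, ...] = tuple(name for name, _ in EUMELANIN_CUTOFFS)

#: Nominal width in converted units separating adjacent skin-tone categories,
#: used when translating a per-unit temperature effect to a per-category one.
CATEGORY_WIDTH_UNITS = 25.0


def convert_melanin(x, model: ConversionModel = DEFAULT_CONVERSION):
    """Convert SkinColorCatch melanin index ``x`` to the DSM-II scale."""
    return model.convert(x)


def invert_melanin(y, model: ConversionModel = DEFAULT_CONVERSION):
    """Inverse of :func:`convert_melanin`."""
    return model.invert(y)


def categorize_melanin(y: float) -> str:
    """Assign the Eumelanin-Scale-Modified category for converted value ``y``.

    Boundaries are left-closed: 25 -> IntermediateLow, 100 -> High.
    """
    if not np.isfinite(y) or y <= 0:
        raise ValueError(f"converted melanin value must be finite and > 0, got {y}")
    category = EUMELANIN_CUTOFFS[0][0]
    for name, lo in EUMELANIN_CUTOFFS:
        if y >= lo:
            category = name
        else:
            break
    return category


def per_category_effect(beta_per_unit: float, category_width: float = CATEGORY_WIDTH_UNITS) -> float:
    """Translate a per-converted-unit temperature effect to per-category °C.

    ``category_width`` defaults to the 25 converted units separating adjacent
    skin-tone categories; pass 75 for the Intermediate-Low to
    Intermediate-High span (three categories).
    """
    if not (category_width > 0):
        raise ValueError("category_width must be > 0")
    return beta_per_unit * category_width


def build_colorimetry_table(
    subject_ids: Sequence,
    melanin_raw: Sequence[float],
    model: ConversionModel = DEFAULT_CONVERSION,
) -> pd.DataFrame:
    """Per-subject colorimetry table with converted values and categories."""
    raw = np.asarray(melanin_raw, dtype=float)
    conv = model.convert(raw)
    conv = np.atleast_1d(conv)
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "melanin_raw": raw,
            "melanin_converted": conv,
            "eumelanin_category": [categorize_melanin(v) for v in conv],
        }
    )


_COLORIMETRY_COLUMNS = ["subject_id", "melanin_raw", "melanin_converted", "eumelanin_category"]


def write_colorimetry_csv(table: pd.DataFrame, path) -> None:
    missing = set(_COLORIMETRY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"colorimetry table missing columns: {sorted(missing)}")
    table.loc[:, _COLORIMETRY_COLUMNS].to_csv(path, index=False)


def read_colorimetry_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(_COLORIMETRY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"colorimetry file {path} missing columns: {sorted(missing)}")
    return table
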