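"""Suitability classification, area summaries and trend typology.

HSI maps are reclassified into four habitat classes on lower-closed bins
(the top class also closed above); area percentages are cell counts over
the region mask, optionally cos-latitude weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import SuitabilityMap
from .raster import Grid

__all__ = [
    "CLASS_EDGES",
    "CLASS_NAMES",
    "AreaSummary",
    "TrendTypology",
    "classify",
    "area_summary",
    "suitable_percent",
    "trend_typology",
    "change",
]

#: Lower edges of the four suitability classes; top class closed at 1.
CLASS_EDGES = (0.0, 0.25, 0.50, 0.75)
CLASS_NAMES = ("not", "low", "moderate", "high")


@dataclass
class AreaSummary:
    scenario: str
    pct_not: float
    pct_low: float
    pct_moderate: float
    pct_high: float

    @property
    def pct_suitable(self) -> float:
        return self.pct_moderate + self.pct_high

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "pct_not": self.pct_not,
            "pct_low": self.pct_low,
            "pct_moderate": self.pct_moderate,
            "pct_high": self.pct_high,
            "pct_suitable": self.pct_suitable,
        }


@dataclass
class TrendTypology:
    label: str                      # growing | declining | fluctuating
    deltas: list[float]             # future minus current suitable percent


def classify(hsi: SuitabilityMap | Grid) -> Grid:
    """Reclassify HSI into classes 1-4 on bins [0,.25) [.25,.5) [.5,.75) [.75,1].

    Nodata is preserved; out-of-range HSI raises.
    """
    grid = hsi.grid if isinstance(hsi, SuitabilityMap) else hsi
    v = grid.values
    valid = np.isfinite(v)
    if np.any((v[valid] < 0) | (v[valid] > 1)):
        raise ValueError("HSI values must lie in [0, 1]")
    cls = np.full(v.shape, np.nan)
    edges = np.asarray(CLASS_EDGES)
    # searchsorted(side='right') gives lower-closed bins; clip keeps 1.0 in class 4
    cls[valid] = np.clip(np.searchsorted(edges, v[valid], side="right"), 1, 4)
    return grid.copy(values=cls)


def area_summary(
    class_grid: Grid,
    region_mask: np.ndarray,
    scenario: str = "",
    latitude_weighted: bool = False,
) -> AreaSummary:
    """Percent of region cells in each class.

    With ``latitude_weighted`` each cell counts proportionally to the cosine
    of its center latitude (approximate geodesic area at fixed resolution).
    """
    mask = np.asarray(region_mask, bool)
    if mask.shape != class_grid.values.shape:
        raise ValueError("region mask shape does not match class grid")
    if latitude_weighted:
        lat_centers = (
            class_grid.yll
            + (class_grid.nrows - 1 - np.arange(class_grid.nrows) + 0.5)
            * class_grid.cellsize
        )
        w_row = np.cos(np.radians(lat_centers))
        weights = np.broadcast_to(w_row[:, None], class_grid.values.shape)
    else:
        weights = np.ones_like(class_grid.values)
    total = weights[mask].sum()
    if total <= 0:
        raise ValueError("region mask selects no cells")
    pct = []
    for c in (1, 2, 3, 4):
        in_class = mask & (class_grid.values == c)
        pct.append(100.0 * weights[in_class].sum() / total)
    return AreaSummary(scenario, *pct)


def suitable_percent(summary: AreaSummary) -> float:
    """Suitable habitat percent: moderately plus highly suitable."""
    return summary.pct_moderate + summary.pct_high


def trend_typology(current: float, futures: list[float] | tuple[float, ...]) -> TrendTypology:
    """Growing if every future exceeds current, declining if every future is
    below it, otherwise fluctuating (strict inequalities, unrounded values)."""
    futures = list(futures)
    if len(futures) != 4:
        raise ValueError("trend typology expects exactly four future values")
    deltas = [f - current for f in futures]
    if all(f > current for f in futures):
        label = "growing"
    elif all(f < current for f in futures):
        label = "declining"
    else:
        label = "fluctuating"
    return TrendTypology(label=label, deltas=deltas)


def change(current: float, future: float) -> float:
    """Future-minus-current difference, reported at two decimals."""
    return round(future - current, 2)


def area_table(summaries: list[AreaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
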