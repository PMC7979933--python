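"""Soil profiles, fixed-depth SOC stocks, and per-region outlier screening.

A profile is an ordered set of depth layers, each with a SOC concentration
(% by mass) and a bulk density (g/cm^3).  The 0-100 cm stock uses the fixed
depth approach: each layer contributes

    (soc_pct / 100) * bulk_density [g/cm^3] * thickness [cm] * 100

megagrams of carbon per hectare for the part of the layer inside the depth
window (layers straddling the limit contribute pro-rata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyWindowError, InvalidArgumentError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoilLayer:
    top_depth: float  # cm below surface
    bottom_depth: float
    soc_concentration: float  # % by mass
    bulk_density: float  # g/cm^3

    def __post_init__(self):
        if not 0 <= self.top_depth < self.bottom_depth:
            raise InvalidArgumentError("need 0 <= top_depth < bottom_depth")
        if self.soc_concentration < 0:
            raise InvalidArgumentError("soc_concentration must be >= 0")
        if self.bulk_density <= 0:
            raise InvalidArgumentError("bulk_density must be > 0")


@dataclass
class SoilProfile:
    """Georeferenced pedon: ordered, non-overlapping depth layers."""

    id: int
    x: float
    y: float
    region_label: int
    layers: list[SoilLayer] = field(default_factory=list)

    def __post_init__(self):
        self.layers = sorted(self.layers, key=lambda l: l.top_depth)
        for a, b in zip(self.layers, self.layers[1:]):
            if b.top_depth < a.bottom_depth - 1e-9:
                raise InvalidArgumentError(
                    f"profile {self.id}: layers {a} and {b} overlap"
                )


def compute_profile_stock(profile: SoilProfile, depth_limit: float = 100.0) -> float:
    """Fixed-depth SOC stock (Mg/ha) over [0, depth_limit) cm.

    Additive over depth partitions: splitting a layer at any interior depth
    leaves the stock unchanged.
    """
    if depth_limit <= 0:
        raise InvalidArgumentError("depth_limit must be positive")
    stock = 0.0
    any_overlap = False
    for lay in profile.layers:
        eff = min(lay.bottom_depth, depth_limit) - max(lay.top_depth, 0.0)
        if eff > 0:
            any_overlap = True
            # (pct/100) * g/cm^3 * cm * 100 -> Mg/ha simplifies to pct*bd*cm
            stock += lay.soc_concentration * lay.bulk_density * eff
    if not any_overlap:
        raise EmptyWindowError(
            f"profile {profile.id}: no layer intersects [0, {depth_limit}) cm"
        )
    return stock


def stocks_from_profiles(profiles, depth_limit: float = 100.0) -> pd.DataFrame:
    """Table of per-profile stocks: id, x, y, region, stock_mg_ha."""
    rows = [
        (p.id, p.x, p.y, p.region_label, compute_profile_stock(p, depth_limit))
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["id", "x", "y", "region", "stock_mg_ha"])


def filter_outliers_iqr(
    table: pd.DataFrame,
    k: float = 1.5,
    stock_col: str = "stock_mg_ha",
    region_col: str = "region",
    min_region_size: int = 4,
):
    """Single-pass 1.5*IQR outlier removal within each ecoregion.

    Rows with stock < Q1 - k*IQR or > Q3 + k*IQR in their own region are
    removed; quartiles use linear interpolation between order statistics.
    Regions with fewer than ``min_region_size`` rows pass through unfiltered
    (logged).  Returns ``(kept, removed)``; their union is the input.
    """
    if len(table) == 0:
        raise InvalidArgumentError("empty observation table")
    if table[region_col].isna().any():
        raise InvalidArgumentError("every row needs a region label")
    keep_mask = np.ones(len(table), dtype=bool)
    pos = {idx: i for i, idx in enumerate(table.index)}
    for region, sub in table.groupby(region_col):
        if len(sub) < min_region_size:
            log.warning(
                "region %s has %d rows (< %d): passed through unfiltered",
                region, len(sub), min_region_size,
            )
            continue
        s = sub[stock_col].to_numpy(dtype=float)
        q1, q3 = np.percentile(s, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        bad = (s < lo) | (s > hi)
        for idx in sub.index[bad]:
            keep_mask[pos[idx]] = False
    return table[keep_mask], table[~keep_mask]
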