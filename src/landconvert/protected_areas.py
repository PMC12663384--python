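"""Conversion within protected areas: category shares and inside/outside rates.

Conversion of each natural class (grassland & shrubland, non-forested
wetland, forestland) to cultivated land is attributed to the IUCN category
(I strictest .. VI) of the PA containing the cell center; where PAs of
different categories overlap, the strictest wins. Rates are class-conditional
shares: converted area of a class inside a category's PAs divided by that
class's time-zero area inside the same PAs, with an OUTSIDE row using the
complement of all PAs. These are descriptive overlay statistics, not causal
estimates of PA effectiveness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import EpochRaster
from .harmonization import HarmonizedClass
from .layers import IUCN_CATEGORIES, PACollection, ZoneLayer
from .transitions import CONVERSION_BY_SOURCE, TransitionRaster

LAND_CLASSES = (
    HarmonizedClass.GRASS_SHRUB,
    HarmonizedClass.NONFOREST_WETLAND,
    HarmonizedClass.FOREST,
)
OUTSIDE = "OUTSIDE"

RATE_TABLE_COLUMNS = [
    "zone_id", "dataset_id", "period", "land_class", "category",
    "converted_area_ha", "baseline_area_ha", "rate",
]


def filter_by_year(pas: PACollection, cutoff_year: int) -> tuple[PACollection, dict]:
    """PAs established strictly before ``cutoff_year``; unknown years are
    excluded and counted in the report (see PACollection.filter_by_year)."""
    return pas.filter_by_year(cutoff_year)


def pa_conversion(
    tr: TransitionRaster, t0: EpochRaster, pas: PACollection
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Converted area per (IUCN category, land class) and category shares.

    Returns ``(areas, proportions)``. ``areas`` has one row per category and
    land class with the converted hectares inside that category's PAs.
    ``proportions`` normalizes each land class's areas over categories so
    they sum to 1 wherever any protected conversion of that class exists.
    """
    pas = pas.terrestrial()
    cat_raster = pas.category_raster(tr.geom)
    areas_ha = tr.geom.cell_areas_ha()
    rows = []
    for land_class in LAND_CLASSES:
        code = int(CONVERSION_BY_SOURCE[land_class])
        conv = tr.values == code
        for idx, cat in enumerate(IUCN_CATEGORIES, start=1):
            area = float(areas_ha[conv & (cat_raster == idx)].sum())
            rows.append((tr.dataset_id, tr.period_label, land_class.name, cat, area))
    areas = pd.DataFrame(
        rows, columns=["dataset_id", "period", "land_class", "category", "converted_area_ha"]
    )
    totals = areas.groupby("land_class")["converted_area_ha"].transform("sum")
    proportions = areas.copy()
    proportions["proportion"] = np.where(
        totals > 0, areas.converted_area_ha / totals, np.nan
    )
    return areas, proportions


def conversion_rates(
    tr: TransitionRaster,
    t0: EpochRaster,
    pas: PACollection,
    zones: ZoneLayer,
) -> pd.DataFrame:
    """Class-conditional conversion rates inside each IUCN category vs
    outside all PAs, per zone.

    rate = converted area of the class within the mask / time-zero area of
    the class within the mask. Zero-baseline combinations carry rate NaN and
    ``rate_defined`` False.
    """
    pas = pas.terrestrial()
    cat_raster = pas.category_raster(tr.geom)
    labels = zones.labels(tr.geom)
    areas_ha = tr.geom.cell_areas_ha()
    valid = tr.valid_mask
    rows = []
    categories = list(IUCN_CATEGORIES) + [OUTSIDE]
    for zi, zone_id in enumerate(zones.zone_ids):
        in_zone = (labels == zi) & valid
        for land_class in LAND_CLASSES:
            code = int(CONVERSION_BY_SOURCE[land_class])
            base_cls = in_zone & (t0.values == int(land_class))
            conv_cls = in_zone & (tr.values == code)
            for cat in categories:
                if cat == OUTSIDE:
                    mask = cat_raster == 0
                else:
                    mask = cat_raster == (IUCN_CATEGORIES.index(cat) + 1)
                baseline = float(areas_ha[base_cls & mask].sum())
                converted = float(areas_ha[conv_cls & mask].sum())
                rate = converted / baseline if baseline > 0 else np.nan
                rows.append(
                    (zone_id, tr.dataset_id, tr.period_label, land_class.name,
                     cat, converted, baseline, rate)
                )
    out = pd.DataFrame(rows, columns=RATE_TABLE_COLUMNS)
    out["rate_defined"] = out.baseline_area_ha > 0
    return out


def inside_outside_decomposition(rates: pd.DataFrame) -> pd.DataFrame:
    """Check table: per (zone, land_class), summed inside + outside converted
    area, for reconciliation against total converted area."""
    g = rates.groupby(["zone_id", "land_class"])
    return g["converted_area_ha"].sum().rename("total_converted_ha").reset_index()


__all__ = [
    "LAND_CLASSES",
    "OUTSIDE",
    "RATE_TABLE_COLUMNS",
    "conversion_rates",
    "filter_by_year",
    "inside_outside_decomposition",
    "pa_conversion",
]
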