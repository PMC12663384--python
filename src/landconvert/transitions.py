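"""Per-pixel transition detection and equal-area conversion accounting.

Two harmonized epochs are overlaid cell-by-cell and every valid cell is
assigned one transition class:

========================  =====================================================
code                      meaning
========================  =====================================================
``CONV_GRASS``            grassland & shrubland -> cultivated
``CONV_WETLAND``          non-forested wetland -> cultivated
``CONV_FOREST``           forestland -> cultivated
``REVERSION``             cultivated -> any natural class
``STABLE``                same class in both epochs
``OTHER_CHANGE``          any remaining change (e.g. natural -> other)
========================  =====================================================

Cells that are nodata in *either* epoch are nodata in the transition raster
and excluded from every numerator and denominator downstream. Areas are in
hectares; on equal-area grids every cell contributes (cell size)^2 / 10^4 ha,
on geographic grids the spherical per-row area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .grid import EpochRaster, GridGeometry, require_same_geometry
from .harmonization import HarmonizedClass, NATURAL_CLASSES
from .layers import ZoneLayer


class TransitionCode(IntEnum):
    NODATA = 0
    STABLE = 1
    CONV_GRASS = 2
    CONV_WETLAND = 3
    CONV_FOREST = 4
    REVERSION = 5
    OTHER_CHANGE = 6


#: natural -> cultivated codes, keyed by the source natural class
CONVERSION_BY_SOURCE = {
    HarmonizedClass.GRASS_SHRUB: TransitionCode.CONV_GRASS,
    HarmonizedClass.NONFOREST_WETLAND: TransitionCode.CONV_WETLAND,
    HarmonizedClass.FOREST: TransitionCode.CONV_FOREST,
}
SOURCE_BY_CONVERSION = {v: k for k, v in CONVERSION_BY_SOURCE.items()}

CONVERSION_CODES = frozenset(CONVERSION_BY_SOURCE.values())
NONFOREST_CONVERSION_CODES = frozenset(
    {TransitionCode.CONV_GRASS, TransitionCode.CONV_WETLAND}
)

AREA_TABLE_COLUMNS = ["zone_id", "dataset_id", "period", "transition_code", "area_ha"]


@dataclass
class TransitionRaster:
    """Per-pixel transition classes between two epochs of one dataset."""

    values: np.ndarray
    period: tuple[int, int]
    dataset_id: str
    geom: GridGeometry

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != TransitionCode.NODATA

    @property
    def period_label(self) -> str:
        return f"{self.period[0]}-{self.period[1]}"


def _check_harmonized(raster: EpochRaster) -> None:
    valid_codes = {int(c) for c in HarmonizedClass}
    present = set(np.unique(raster.values).tolist())
    unknown = present - valid_codes
    if unknown:
        raise ValueError(
            f"raster {raster.dataset_id}/{raster.year} is not harmonized: "
            f"unexpected codes {sorted(unknown)}"
        )


def detect_transitions(t0: EpochRaster, t1: EpochRaster) -> TransitionRaster:
    """Overlay two harmonized epochs and classify every cell's transition."""
    require_same_geometry(t0, t1)
    if t0.dataset_id != t1.dataset_id:
        raise ValueError(
            f"epochs come from different datasets: {t0.dataset_id!r} vs {t1.dataset_id!r}"
        )
    if t0.year >= t1.year:
        raise ValueError(f"epoch years must increase: {t0.year} >= {t1.year}")
    _check_harmonized(t0)
    _check_harmonized(t1)

    a, b = t0.values, t1.values
    valid = (a != t0.nodata) & (b != t1.nodata)
    out = np.full(a.shape, int(TransitionCode.NODATA), dtype=np.int8)
    out[valid & (a == b)] = TransitionCode.STABLE
    changed = valid & (a != b)
    cultivated = int(HarmonizedClass.CULTIVATED)
    for src, code in CONVERSION_BY_SOURCE.items():
        out[changed & (a == int(src)) & (b == cultivated)] = code
    reversion = changed & (a == cultivated) & np.isin(b, [int(c) for c in NATURAL_CLASSES])
    out[reversion] = TransitionCode.REVERSION
    out[changed & (out == int(TransitionCode.NODATA))] = TransitionCode.OTHER_CHANGE
    return TransitionRaster(
        values=out, period=(t0.year, t1.year), dataset_id=t0.dataset_id, geom=t0.geom
    )


def cell_areas(raster: EpochRaster | TransitionRaster) -> np.ndarray:
    """Per-cell area in hectares for any raster carrying a GridGeometry."""
    return raster.geom.cell_areas_ha()


def aggregate_by_zone(tr: TransitionRaster, zones: ZoneLayer) -> pd.DataFrame:
    """Sum transition areas per (zone, transition class), in hectares.

    Valid cells whose center falls outside every zone are reported under the
    reserved zone id ``"unassigned"``. Returns an AreaTable with columns
    (zone_id, dataset_id, period, transition_code, area_ha).
    """
    labels = zones.labels(tr.geom)
    areas = tr.geom.cell_areas_ha()
    valid = tr.valid_mask
    if not valid.any() or (labels[valid] >= 0).sum() == 0 and len(zones) > 0:
        if not (labels[valid] >= 0).any():
            warnings.warn("zones do not intersect any valid raster cell")
    zone_idx = labels[valid] + 1  # 0 = unassigned
    codes = tr.values[valid].astype(np.int64)
    w = areas[valid]
    n_zones = len(zones) + 1
    n_codes = max(int(c) for c in TransitionCode) + 1
    flat = zone_idx * n_codes + codes
    sums = np.bincount(flat, weights=w, minlength=n_zones * n_codes).reshape(
        n_zones, n_codes
    )
    rows = []
    zone_names = [ZoneLayer.UNASSIGNED] + list(zones.zone_ids)
    for zi, zone_id in enumerate(zone_names):
        for code in TransitionCode:
            if code == TransitionCode.NODATA:
                continue
            area = sums[zi, int(code)]
            if area > 0 or zi > 0:  # always emit real-zone rows, even zero
                rows.append(
                    (zone_id, tr.dataset_id, tr.period_label, code.name, float(area))
                )
    return pd.DataFrame(rows, columns=AREA_TABLE_COLUMNS)


def global_totals(tr: TransitionRaster) -> pd.DataFrame:
    """AreaTable with a single implicit global zone."""
    one_zone = ZoneLayer(
        zone_ids=["global"],
        geometries=[_extent_box(tr.geom)],
        names=["global"],
    )
    df = aggregate_by_zone(tr, one_zone)
    return df[df.zone_id == "global"].reset_index(drop=True)


def _extent_box(geom: GridGeometry):
    from shapely.geometry import box

    xmin, ymin, xmax, ymax = geom.extent()
    # pad so every cell center is strictly interior
    pad = geom.cell_size
    return box(xmin - pad, ymin - pad, xmax + pad, ymax + pad)


def block_index(geom: GridGeometry, cell_size_m: float) -> tuple[np.ndarray, int, int]:
    """Block ids for aggregating the raster into coarse square cells.

    Blocks are anchored at the raster origin; ``cell_size_m`` must be a
    positive integer multiple of the raster cell size. Returns (block id per
    cell, n block rows, n block cols); ids are ``brow * ncols_blocks + bcol``.
    """
    factor = cell_size_m / geom.cell_size
    if factor <= 0 or abs(factor - round(factor)) > 1e-9:
        nearest = max(1, round(factor)) * geom.cell_size
        raise ValueError(
            f"coarse cell size {cell_size_m} is not a positive multiple of the "
            f"raster cell size {geom.cell_size}; nearest valid value: {nearest}"
        )
    f = int(round(factor))
    br = np.arange(geom.nrows) // f
    bc = np.arange(geom.ncols) // f
    nbr, nbc = br[-1] + 1, bc[-1] + 1
    ids = br[:, None] * nbc + bc[None, :]
    return ids, int(nbr), int(nbc)


def grid_fraction(
    tr: TransitionRaster,
    cell_size_m: float,
    which: frozenset | set = NONFOREST_CONVERSION_CODES,
) -> pd.DataFrame:
    """Per coarse grid cell, the fraction of valid pixels with code in ``which``.

    Returns a GridSummary with columns (grid_cell_id, dataset_id, period,
    fraction_converted, area_converted_ha). Blocks with zero valid pixels are
    omitted.
    """
    ids, nbr, nbc = block_index(tr.geom, cell_size_m)
    n_blocks = nbr * nbc
    valid = tr.valid_mask
    hit = valid & np.isin(tr.values, [int(c) for c in which])
    areas = tr.geom.cell_areas_ha()
    n_valid = np.bincount(ids[valid], minlength=n_blocks)
    n_hit = np.bincount(ids[hit], minlength=n_blocks)
    a_hit = np.bincount(ids[hit], weights=areas[hit], minlength=n_blocks)
    keep = n_valid > 0
    block_ids = np.arange(n_blocks)[keep]
    return pd.DataFrame(
        {
            "grid_cell_id": block_ids,
            "dataset_id": tr.dataset_id,
            "period": tr.period_label,
            "fraction_converted": n_hit[keep] / n_valid[keep],
            "area_converted_ha": a_hit[keep],
        }
    )


def combine_periods(first: TransitionRaster, second: TransitionRaster) -> TransitionRaster:
    """Merge two consecutive per-period transition rasters into one.

    A cell counts as converted over the full span if it converted in either
    period; the earlier period's conversion code wins where both apply.
    Everything else falls back to STABLE / OTHER_CHANGE / REVERSION from the
    later period. Nodata in either period is nodata.
    """
    if first.geom != second.geom or first.dataset_id != second.dataset_id:
        raise ValueError("periods must share geometry and dataset")
    if first.period[1] != second.period[0]:
        raise ValueError(
            f"periods are not consecutive: {first.period} then {second.period}"
        )
    a, b = first.values, second.values
    valid = (a != TransitionCode.NODATA) & (b != TransitionCode.NODATA)
    out = np.where(valid, b, int(TransitionCode.NODATA)).astype(np.int8)
    conv_codes = [int(c) for c in CONVERSION_CODES]
    a_conv = valid & np.isin(a, conv_codes)
    out[a_conv] = a[a_conv]
    return TransitionRaster(
        values=out,
        period=(first.period[0], second.period[1]),
        dataset_id=first.dataset_id,
        geom=first.geom,
    )


__all__ = [
    "AREA_TABLE_COLUMNS",
    "CONVERSION_BY_SOURCE",
    "CONVERSION_CODES",
    "NONFOREST_CONVERSION_CODES",
    "SOURCE_BY_CONVERSION",
    "TransitionCode",
    "TransitionRaster",
    "aggregate_by_zone",
    "block_index",
    "cell_areas",
    "combine_periods",
    "detect_transitions",
    "global_totals",
    "grid_fraction",
]
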