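"""Biodiversity impact metrics over converted land.

Three complementary views:

* **Richness** of threatened (VU/EN/CR) species on a coarse equal-area grid
  (~30 km target on real data), optionally restricted to *consensus* cells —
  coarse cells where every land-cover dataset detects natural-to-cultivated
  conversion (forest and non-forest alike).
* **Affected species**: a threatened species is affected when its range
  polygon overlaps (positive area) at least one converted pixel; affected
  species are broken down by taxon and, per focal natural class in their
  habitat-affinity set, by how many of the three natural classes they use
  (endemic / two / three).
* **KBA conversion**: converted area inside Key Biodiversity Areas compared
  with converted area inside PAs, and the protection gap — conversion inside
  KBAs but outside every PA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .grid import GridGeometry
from .harmonization import HarmonizedClass
from .layers import KBACollection, PACollection, SpeciesCollection, ZoneLayer
from .transitions import (
    CONVERSION_BY_SOURCE,
    CONVERSION_CODES,
    TransitionRaster,
    block_index,
)

AFFINITY_BUCKETS = {1: "endemic", 2: "two", 3: "three"}


def consensus_cells(grids: dict[str, pd.DataFrame]) -> set:
    """Coarse cells where *every* dataset shows conversion fraction > 0.

    ``grids`` maps dataset_id -> GridSummary computed with ``which`` covering
    all natural-to-cultivated codes. Cells must share one block indexing
    (same raster geometry and coarse cell size).
    """
    if not grids:
        raise ValueError("no grid summaries provided")
    sets = []
    for df in grids.values():
        sets.append(set(df.loc[df.fraction_converted > 0, "grid_cell_id"]))
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def coarse_cell_polygons(
    geom: GridGeometry, coarse_size_m: float, cell_ids=None
) -> dict:
    """Shapely boxes of the coarse grid blocks, keyed by block id."""
    _, nbr, nbc = block_index(geom, coarse_size_m)
    f = coarse_size_m
    out = {}
    ids = range(nbr * nbc) if cell_ids is None else cell_ids
    for cid in ids:
        brow, bcol = divmod(int(cid), nbc)
        x0 = geom.origin_x + bcol * f
        y1 = geom.origin_y - brow * f
        x1 = min(x0 + f, geom.origin_x + geom.ncols * geom.cell_size)
        y0 = max(y1 - f, geom.origin_y - geom.nrows * geom.cell_size)
        out[int(cid)] = box(x0, y0, x1, y1)
    return out


def richness(
    ranges: SpeciesCollection,
    geom: GridGeometry,
    coarse_size_m: float,
    restrict: set | None = None,
) -> pd.DataFrame:
    """Distinct threatened species whose range overlaps each coarse cell.

    Non-threatened species are dropped before counting. When ``restrict`` is
    given only those consensus cells are evaluated. Overlap means positive
    intersection area. Invalid geometries are skipped and counted in the
    ``skipped_species`` DataFrame attribute.
    """
    threatened = ranges.threatened()
    cells = coarse_cell_polygons(geom, coarse_size_m, cell_ids=restrict)
    skipped = []
    counts = {cid: 0 for cid in cells}
    cell_ids = list(cells)
    tree = shapely.STRtree([cells[c] for c in cell_ids]) if cells else None
    for sp in threatened:
        if not sp.geometry.is_valid or sp.geometry.is_empty:
            skipped.append(sp.species_id)
            continue
        if tree is None:
            continue
        for j in tree.query(sp.geometry, predicate="intersects"):
            if sp.geometry.intersection(cells[cell_ids[j]]).area > 0:
                counts[cell_ids[j]] += 1
    out = pd.DataFrame(
        {"grid_cell_id": list(counts), "species_count": list(counts.values())}
    ).sort_values("grid_cell_id").reset_index(drop=True)
    out.attrs["skipped_species"] = skipped
    out.attrs["restricted_to_consensus"] = restrict is not None
    return out


@dataclass
class AffectedSpeciesSummary:
    by_taxon: dict[str, int] = field(default_factory=dict)
    by_class_bucket: dict[tuple[str, str], int] = field(default_factory=dict)
    affected_ids: list[str] = field(default_factory=list)
    n_threatened_input: int = 0

    @property
    def n_affected(self) -> int:
        return len(self.affected_ids)


def _converted_cell_boxes(tr: TransitionRaster) -> list:
    mask = np.isin(tr.values, [int(c) for c in CONVERSION_CODES])
    g = tr.geom
    rows, cols = np.nonzero(mask)
    return [
        box(
            g.origin_x + c * g.cell_size,
            g.origin_y - (r + 1) * g.cell_size,
            g.origin_x + (c + 1) * g.cell_size,
            g.origin_y - r * g.cell_size,
        )
        for r, c in zip(rows, cols)
    ]


def affected_species(
    tr: TransitionRaster, ranges: SpeciesCollection
) -> AffectedSpeciesSummary:
    """Count threatened species whose range overlaps converted pixels.

    A species is affected iff its range has a positive-area intersection
    with at least one natural-to-cultivated cell (of any source class). Each
    affected species contributes once to its taxon count, and once per focal
    class in its habitat set to the (focal class, bucket) matrix, where the
    bucket is the size of its habitat set within the three natural classes:
    1 = endemic, 2 = two habitats, 3 = three habitats.
    """
    threatened = ranges.threatened()
    boxes = _converted_cell_boxes(tr)
    tree = shapely.STRtree(boxes) if boxes else None
    summary = AffectedSpeciesSummary(n_threatened_input=len(threatened))
    for sp in threatened:
        hit = False
        if tree is not None:
            for j in tree.query(sp.geometry, predicate="intersects"):
                if sp.geometry.intersection(boxes[j]).area > 0:
                    hit = True
                    break
        if not hit:
            continue
        summary.affected_ids.append(sp.species_id)
        summary.by_taxon[sp.taxon] = summary.by_taxon.get(sp.taxon, 0) + 1
        bucket = AFFINITY_BUCKETS[len(sp.habitats)]
        for focal in sp.habitats:
            key = (focal.name, bucket)
            summary.by_class_bucket[key] = summary.by_class_bucket.get(key, 0) + 1
    return summary


def kba_conversion(
    tr: TransitionRaster,
    kbas: KBACollection,
    pas: PACollection,
    zones: ZoneLayer,
) -> pd.DataFrame:
    """Per zone and land class: converted area inside KBAs, inside PAs, and
    inside KBAs but outside every PA (the protection gap)."""
    geom = tr.geom
    kba_mask = kbas.union_mask(geom)
    pa_mask = pas.terrestrial().union_mask(geom)
    labels = zones.labels(geom)
    areas = geom.cell_areas_ha()
    rows = []
    for zi, zone_id in enumerate(zones.zone_ids):
        in_zone = labels == zi
        for land_class, code in CONVERSION_BY_SOURCE.items():
            conv = in_zone & (tr.values == int(code))
            rows.append(
                (
                    zone_id,
                    tr.dataset_id,
                    tr.period_label,
                    land_class.name,
                    float(areas[conv & kba_mask].sum()),
                    float(areas[conv & pa_mask].sum()),
                    float(areas[conv & kba_mask & ~pa_mask].sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "zone_id", "dataset_id", "period", "land_class",
            "kba_converted_ha", "pa_converted_ha", "kba_not_pa_converted_ha",
        ],
    )


__all__ = [
    "AFFINITY_BUCKETS",
    "AffectedSpeciesSummary",
    "affected_species",
    "coarse_cell_polygons",
    "consensus_cells",
    "kba_conversion",
    "richness",
]
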