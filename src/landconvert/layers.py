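"""Vector conservation layers: protected areas, KBAs, zones, species ranges.

All layers hold shapely geometries in the raster's coordinate system and
serialize to GeoJSON FeatureCollections. Polygon-on-raster decisions follow
one rule everywhere: a raster cell belongs to a polygon iff its *center*
falls inside the polygon interior (``shapely.contains_xy``). Species-range
overlap is the exception — there, any positive-area intersection counts —
because a range map is a coarse statement of potential presence, not a
cell-resolved one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid import GridGeometry
from .harmonization import HarmonizedClass

IUCN_CATEGORIES = ("I", "II", "III", "IV", "V", "VI")
#: Ia/Ib subcategories collapse to I (one strict-protection class)
_CATEGORY_ALIASES = {"Ia": "I", "Ib": "I"}

TAXA = ("amphibian", "mammal", "reptile", "bird")
THREATENED = ("VU", "EN", "CR")
HABITAT_CLASSES = (
    HarmonizedClass.GRASS_SHRUB,
    HarmonizedClass.NONFOREST_WETLAND,
    HarmonizedClass.FOREST,
)


def cells_inside(geometry, geom: GridGeometry) -> np.ndarray:
    """Boolean mask of cells whose center lies inside the geometry."""
    xx, yy = geom.cell_centers()
    return shapely.contains_xy(geometry, xx, yy)


@dataclass
class PARecord:
    pa_id: str
    geometry: shapely.Geometry
    iucn_category: str
    establishment_year: int | None
    designation: str = ""
    marine_flag: bool = False

    def __post_init__(self) -> None:
        self.iucn_category = _CATEGORY_ALIASES.get(self.iucn_category, self.iucn_category)
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(
                f"PA {self.pa_id}: IUCN category {self.iucn_category!r} is not one of "
                f"{IUCN_CATEGORIES}"
            )
        if self.establishment_year is not None and self.establishment_year <= 0:
            raise ValueError(f"PA {self.pa_id}: establishment_year must be positive or None")


@dataclass
class PACollection:
    """Protected-area polygons with IUCN categories and establishment years."""

    records: list[PARecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PARecord]:
        return iter(self.records)

    def terrestrial(self) -> "PACollection":
        return PACollection([r for r in self.records if not r.marine_flag])

    def filter_by_year(self, cutoff_year: int) -> tuple["PACollection", dict]:
        """Keep PAs established strictly before ``cutoff_year``.

        PAs with unknown establishment year are excluded (the filter asks for
        "established before", which cannot be asserted) and counted in the
        returned report.
        """
        kept, unknown, too_late = [], 0, 0
        for r in self.records:
            if r.establishment_year is None:
                unknown += 1
            elif r.establishment_year < cutoff_year:
                kept.append(r)
            else:
                too_late += 1
        report = {
            "cutoff_year": cutoff_year,
            "n_input": len(self.records),
            "n_kept": len(kept),
            "n_excluded_unknown_year": unknown,
            "n_excluded_established_later": too_late,
        }
        return PACollection(kept), report

    def category_raster(self, geom: GridGeometry) -> np.ndarray:
        """Rasterize to per-cell category index 1..6 (0 = outside all PAs).

        Where PAs of different categories overlap, the strictest (lowest
        numbered) category wins: painting proceeds from VI down to I so that
        stricter categories overwrite.
        """
        out = np.zeros(geom.shape, dtype=np.int8)
        for cat_idx in range(len(IUCN_CATEGORIES), 0, -1):
            cat = IUCN_CATEGORIES[cat_idx - 1]
            for r in self.records:
                if r.iucn_category == cat:
                    out[cells_inside(r.geometry, geom)] = cat_idx
        return out

    def union_mask(self, geom: GridGeometry) -> np.ndarray:
        return self.category_raster(geom) > 0

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for r in self.records:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r.geometry),
                    "properties": {
                        "pa_id": r.pa_id,
                        "iucn_cat": r.iucn_category,
                        "status_yr": r.establishment_year,
                        "designation": r.designation,
                        "marine": r.marine_flag,
                    },
                }
            )
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PACollection":
        doc = json.loads(Path(path).read_text())
        records = []
        for feat in doc["features"]:
            p = feat["properties"]
            records.append(
                PARecord(
                    pa_id=str(p["pa_id"]),
                    geometry=shape(feat["geometry"]),
                    iucn_category=p["iucn_cat"],
                    establishment_year=p.get("status_yr"),
                    designation=p.get("designation", ""),
                    marine_flag=bool(p.get("marine", False)),
                )
            )
        return cls(records)


@dataclass
class KBARecord:
    kba_id: str
    geometry: shapely.Geometry
    name: str = ""


@dataclass
class KBACollection:
    records: list[KBARecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[KBARecord]:
        return iter(self.records)

    def union_mask(self, geom: GridGeometry) -> np.ndarray:
        out = np.zeros(geom.shape, dtype=bool)
        for r in self.records:
            out |= cells_inside(r.geometry, geom)
        return out

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {"kba_id": r.kba_id, "name": r.name},
            }
            for r in self.records
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "KBACollection":
        doc = json.loads(Path(path).read_text())
        return cls(
            [
                KBARecord(
                    kba_id=str(f["properties"]["kba_id"]),
                    geometry=shape(f["geometry"]),
                    name=f["properties"].get("name", ""),
                )
                for f in doc["features"]
            ]
        )


@dataclass
class ZoneLayer:
    """Mutually exclusive zones ("countries") as polygons over the extent.

    ``labels(geom)`` rasterizes by cell-center containment to an integer
    label array indexing into ``zone_ids`` (-1 = outside every zone).
    """

    zone_ids: list[str]
    geometries: list[shapely.Geometry]
    names: list[str] = field(default_factory=list)

    UNASSIGNED = "unassigned"

    def __post_init__(self) -> None:
        if len(self.zone_ids) != len(self.geometries):
            raise ValueError("zone_ids and geometries must have equal length")
        if not self.names:
            self.names = list(self.zone_ids)

    def __len__(self) -> int:
        return len(self.zone_ids)

    def labels(self, geom: GridGeometry) -> np.ndarray:
        out = np.full(geom.shape, -1, dtype=np.int64)
        xx, yy = geom.cell_centers()
        for i, g in enumerate(self.geometries):
            inside = shapely.contains_xy(g, xx, yy)
            multi = inside & (out >= 0)
            if multi.any():
                warnings.warn(
                    f"zone {self.zone_ids[i]} overlaps a previous zone on "
                    f"{int(multi.sum())} cells; first assignment kept"
                )
                inside &= out < 0
            out[inside] = i
        return out

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(g),
                "properties": {"zone_id": z, "name": n},
            }
            for z, g, n in zip(self.zone_ids, self.geometries, self.names)
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZoneLayer":
        doc = json.loads(Path(path).read_text())
        zone_ids, geoms, names = [], [], []
        for f in doc["features"]:
            zone_ids.append(str(f["properties"]["zone_id"]))
            geoms.append(shape(f["geometry"]))
            names.append(f["properties"].get("name", ""))
        return cls(zone_ids, geoms, names)


@dataclass
class SpeciesRange:
    """One species' range polygon with Red List and habitat attributes."""

    species_id: str
    taxon: str
    red_list: str
    habitats: frozenset[HarmonizedClass]
    geometry: shapely.Geometry

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"species {self.species_id}: unknown taxon {self.taxon!r}")
        if self.red_list not in THREATENED and self.red_list != "other":
            raise ValueError(
                f"species {self.species_id}: red_list must be VU/EN/CR/other, "
                f"got {self.red_list!r}"
            )
        self.habitats = frozenset(self.habitats) & set(HABITAT_CLASSES)
        if not self.habitats:
            raise ValueError(
                f"species {self.species_id}: habitat-affinity set is empty after "
                "restriction to the three natural analysis classes"
            )

    @property
    def threatened(self) -> bool:
        return self.red_list in THREATENED


class SpeciesCollection:
    def __init__(self, records: Iterable[SpeciesRange] = ()):
        self.records: list[SpeciesRange] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRange]:
        return iter(self.records)

    def threatened(self) -> "SpeciesCollection":
        return SpeciesCollection(r for r in self.records if r.threatened)

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for r in self.records:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r.geometry),
                    "properties": {
                        "species_id": r.species_id,
                        "taxon": r.taxon,
                        "red_list": r.red_list,
                        "habitats": "|".join(sorted(h.name for h in r.habitats)),
                    },
                }
            )
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "SpeciesCollection":
        doc = json.loads(Path(path).read_text())
        records = []
        for f in doc["features"]:
            p = f["properties"]
            habitats = frozenset(
                HarmonizedClass[h] for h in p["habitats"].split("|") if h
            )
            records.append(
                SpeciesRange(
                    species_id=str(p["species_id"]),
                    taxon=p["taxon"],
                    red_list=p["red_list"],
                    habitats=habitats,
                    geometry=shape(f["geometry"]),
                )
            )
        return cls(records)


__all__ = [
    "HABITAT_CLASSES",
    "IUCN_CATEGORIES",
    "KBACollection",
    "KBARecord",
    "PACollection",
    "PARecord",
    "SpeciesCollection",
    "SpeciesRange",
    "TAXA",
    "THREATENED",
    "ZoneLayer",
    "cells_inside",
]
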