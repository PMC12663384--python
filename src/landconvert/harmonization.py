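"""Harmonization of native land-cover legends into the common class scheme.

Each source product (GlobeLand30, GLCLUC, GLC_FCS30D) uses its own legend.
Cross-product change accounting requires mapping every native class into one
common scheme of four analysis classes — cultivated land/cropland, grassland
& shrubland, non-forested wetland, forestland — plus OTHER for everything
else (water, ice, bare, tundra, built-up) and NODATA.

The mappings are shipped as editable YAML tables under ``landconvert/data``
because native integer legends differ between product versions; each table
names the legend it was built against. Notable legend-specific rules:

* GLCLUC distinguishes vegetation by height: tree cover >= 5 m (including
  forested wetlands) counts as forestland, shorter vegetation as grassland &
  shrubland (terra firma) or non-forested wetland (wetland stratum).
* GLC_FCS30D swamp and mangrove are woody and count as forestland; marsh,
  salt marsh, flooded/tidal flats and saline classes are non-forested
  wetland. Its cropland includes tree crops.
* GlobeLand30 cannot split forested from non-forested wetland, so its entire
  wetland class is non-forested wetland and never forestland. Its cultivated
  class includes cultivated grassland (pasture) and excludes tree crops.
* Tundra (where a product has it) maps to OTHER, not grassland & shrubland.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path

import numpy as np
import yaml


class HarmonizedClass(IntEnum):
    """The study's common land-cover scheme (integer raster codes)."""

    NODATA = 0
    CULTIVATED = 1
    GRASS_SHRUB = 2
    NONFOREST_WETLAND = 3
    FOREST = 4
    OTHER = 5


#: the four classes the analysis is about (everything else is OTHER/NODATA)
ANALYSIS_CLASSES = (
    HarmonizedClass.CULTIVATED,
    HarmonizedClass.GRASS_SHRUB,
    HarmonizedClass.NONFOREST_WETLAND,
    HarmonizedClass.FOREST,
)

#: natural classes whose conversion to cultivated land is tracked
NATURAL_CLASSES = (
    HarmonizedClass.GRASS_SHRUB,
    HarmonizedClass.NONFOREST_WETLAND,
    HarmonizedClass.FOREST,
)

SUPPORTED_DATASETS = ("globeland30", "glcluc", "glc_fcs30d", "synthetic")


@dataclass
class HarmonizationTable:
    """Total mapping from one product's native codes to harmonized codes."""

    dataset_id: str
    mapping: dict[int, HarmonizedClass]
    notes: dict[int, str] = field(default_factory=dict)
    legend: str = ""

    def __post_init__(self) -> None:
        for code, target in self.mapping.items():
            if not isinstance(target, HarmonizedClass):
                self.mapping[code] = HarmonizedClass[str(target)]

    def lookup_array(self, max_code: int) -> np.ndarray:
        """Dense LUT of length max_code+1; -1 marks unmapped codes."""
        lut = np.full(max_code + 1, -1, dtype=np.int64)
        for code, target in self.mapping.items():
            lut[code] = int(target)
        return lut


def _data_path(name: str) -> Path:
    return Path(str(resources.files("landconvert").joinpath("data", name)))


def load_table(path: str | Path) -> HarmonizationTable:
    """Load a harmonization table from its YAML serialization."""
    doc = yaml.safe_load(Path(path).read_text())
    mapping: dict[int, HarmonizedClass] = {}
    notes: dict[int, str] = {}
    for entry in doc["classes"]:
        code = int(entry["native_code"])
        mapping[code] = HarmonizedClass[entry["harmonized_code"]]
        if entry.get("note"):
            notes[code] = entry["note"]
    return HarmonizationTable(
        dataset_id=doc["dataset_id"],
        mapping=mapping,
        notes=notes,
        legend=doc.get("legend", ""),
    )


def builtin_table(dataset_id: str) -> HarmonizationTable:
    """Return the shipped harmonization table for a supported product."""
    if dataset_id not in SUPPORTED_DATASETS:
        raise KeyError(
            f"unknown dataset_id {dataset_id!r}; supported: {', '.join(SUPPORTED_DATASETS)}"
        )
    return load_table(_data_path(f"{dataset_id}.yml"))


def harmonize(raster, table: HarmonizationTable):
    """Remap a native-legend raster into harmonized codes.

    Geometry, nodata placement and the total number of valid cells are
    preserved; only the class coding changes. Raises if the raster contains
    a non-nodata code the table does not cover, naming the code and how many
    cells carry it.
    """
    from .grid import EpochRaster  # local import to avoid cycle at module load

    if raster.dataset_id != table.dataset_id:
        raise ValueError(
            f"raster dataset_id {raster.dataset_id!r} does not match "
            f"table dataset_id {table.dataset_id!r}"
        )
    values = raster.values
    valid = raster.valid_mask
    native = values[valid]
    if native.size:
        max_code = max(int(native.max()), max(table.mapping, default=0))
        lut = table.lookup_array(max_code)
        mapped = lut[native]
        if (mapped < 0).any():
            bad = np.unique(native[mapped < 0])
            counts = {int(c): int((native == c).sum()) for c in bad}
            detail = ", ".join(f"code {c} ({n} cells)" for c, n in counts.items())
            raise ValueError(f"unmapped native codes in {raster.dataset_id}: {detail}")
    out = np.full_like(values, HarmonizedClass.NODATA)
    if native.size:
        out[valid] = mapped
    return EpochRaster(
        values=out,
        year=raster.year,
        dataset_id=raster.dataset_id,
        geom=raster.geom,
        nodata=int(HarmonizedClass.NODATA),
    )


def identity_table(dataset_id: str = "synthetic") -> HarmonizationTable:
    """Identity mapping over the harmonized codes themselves."""
    mapping = {int(c): c for c in HarmonizedClass if c != HarmonizedClass.NODATA}
    return HarmonizationTable(dataset_id=dataset_id, mapping=mapping, legend="identity")


__all__ = [
    "ANALYSIS_CLASSES",
    "HarmonizationTable",
    "HarmonizedClass",
    "NATURAL_CLASSES",
    "SUPPORTED_DATASETS",
    "builtin_table",
    "harmonize",
    "identity_table",
    "load_table",
]
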