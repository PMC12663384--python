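"""Raster grid geometry, epoch rasters and plain-text raster I/O.

Rasters are square-celled single-band integer grids. Geometry follows the
usual north-up convention: ``origin_x/origin_y`` is the *top-left* corner,
rows increase southwards. Two CRS families are supported through ``crs_tag``:

* equal-area tags (``local-equal-area``, ``mollweide``): ``cell_size`` is in
  metres and every cell has the same area;
* ``geographic``: ``cell_size`` is in decimal degrees and cell areas follow
  the spherical closed form (cosine-latitude weighting).

Serialization uses the ESRI ASCII grid format (plain text, readable by GIS
tools) plus a small JSON sidecar for the attributes the .asc header cannot
carry (year, dataset id, CRS tag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

#: mean (authalic) Earth radius in metres, used for geographic cell areas
EARTH_RADIUS_M = 6_371_007.181

EQUAL_AREA_TAGS = frozenset({"local-equal-area", "mollweide"})
GEOGRAPHIC_TAG = "geographic"


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a north-up raster: top-left corner, cell size, shape."""

    origin_x: float
    origin_y: float
    cell_size: float
    nrows: int
    ncols: int
    crs_tag: str = "local-equal-area"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid shape must be positive, got {(self.nrows, self.ncols)}")
        if self.crs_tag not in EQUAL_AREA_TAGS and self.crs_tag != GEOGRAPHIC_TAG:
            raise ValueError(
                f"unknown crs_tag {self.crs_tag!r}; expected one of "
                f"{sorted(EQUAL_AREA_TAGS) + [GEOGRAPHIC_TAG]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def is_equal_area(self) -> bool:
        return self.crs_tag in EQUAL_AREA_TAGS

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center as 2-D arrays."""
        cols = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size
        rows = self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell_size,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
        )

    def cell_areas_ha(self) -> np.ndarray:
        """Per-cell area in hectares, shaped like the raster.

        Equal-area grids return a constant field of (cell_size m)^2 / 10^4.
        Geographic grids use the exact spherical formula for a
        latitude-longitude quadrangle: A = R^2 * dlambda * (sin(phi_n) -
        sin(phi_s)), broadcast over columns.
        """
        if self.is_equal_area:
            area = self.cell_size * self.cell_size / 1e4
            return np.full(self.shape, area, dtype=float)
        lat_top = np.deg2rad(self.origin_y - np.arange(self.nrows) * self.cell_size)
        lat_bot = np.deg2rad(self.origin_y - (np.arange(self.nrows) + 1) * self.cell_size)
        dlon = np.deg2rad(self.cell_size)
        band = EARTH_RADIUS_M**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot)) / 1e4
        return np.broadcast_to(band[:, None], self.shape).copy()


@dataclass
class EpochRaster:
    """A categorical land-cover raster for one dataset and one year."""

    values: np.ndarray
    year: int
    dataset_id: str
    geom: GridGeometry
    nodata: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geom.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"shape {self.geom.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("raster values must be integer class codes")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def with_values(self, values: np.ndarray, **changes) -> "EpochRaster":
        out = EpochRaster(
            values=values,
            year=changes.pop("year", self.year),
            dataset_id=changes.pop("dataset_id", self.dataset_id),
            geom=changes.pop("geom", self.geom),
            nodata=changes.pop("nodata", self.nodata),
        )
        if changes:
            raise TypeError(f"unknown fields: {sorted(changes)}")
        return out


def write_ascii_grid(raster: EpochRaster, path: str | Path) -> None:
    """Write as ESRI ASCII grid with a JSON metadata sidecar (<path>.json)."""
    path = Path(path)
    g = raster.geom
    yll = g.origin_y - g.nrows * g.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.origin_x:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {g.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values, fmt="%d")
    sidecar = {
        "year": raster.year,
        "dataset_id": raster.dataset_id,
        "crs_tag": g.crs_tag,
        "nodata": raster.nodata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_ascii_grid(path: str | Path) -> EpochRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    geom = GridGeometry(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nrows=nrows,
        ncols=int(header["ncols"]),
        crs_tag=meta.get("crs_tag", "local-equal-area"),
    )
    return EpochRaster(
        values=values,
        year=int(meta.get("year", 0)),
        dataset_id=meta.get("dataset_id", "unknown"),
        geom=geom,
        nodata=int(header.get("nodata_value", meta.get("nodata", 0))),
    )


def require_same_geometry(a: EpochRaster, b: EpochRaster) -> None:
    if a.geom != b.geom:
        raise ValueError(
            f"raster geometries differ: {a.geom} vs {b.geom}; "
            "co-register inputs (nearest-neighbour for categorical data) first"
        )


__all__ = [
    "EARTH_RADIUS_M",
    "EpochRaster",
    "GridGeometry",
    "read_ascii_grid",
    "require_same_geometry",
    "write_ascii_grid",
]
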