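"""Synthetic landscapes with known ground truth.

Emulates the statistical structure the downstream analysis assumes — patchy
categorical land cover on an equal-area grid, decadal class transitions,
protected-area / KBA / country layers and species ranges — without any real
data download. The generator is fully deterministic given the scenario seed:
every random draw flows from one ``numpy`` SeedSequence through named
substreams, so the same scenario yields bit-identical rasters and attribute
tables on every run and platform.

Construction choices:

* the time-zero map is a Gaussian random field smoothed at the scenario's
  autocorrelation range and sliced at the class-proportion quantiles, which
  gives contiguous patches with (near-)exact class proportions;
* epoch transitions are applied independently per cell from the scenario's
  row-stochastic transition matrix, so class-conditional conversion rates
  are exactly binomial and recovery tests have closed-form error bars;
* PA/KBA polygons are rectangles snapped *off* cell boundaries so that
  partial-cell overlay decisions are actually exercised;
* zones are vertical strips that exactly partition the extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .grid import EpochRaster, GridGeometry
from .harmonization import HarmonizedClass
from .layers import (
    HABITAT_CLASSES,
    IUCN_CATEGORIES,
    KBACollection,
    KBARecord,
    PACollection,
    PARecord,
    SpeciesCollection,
    SpeciesRange,
    TAXA,
    ZoneLayer,
)

_STREAMS = {
    "field": 1,
    "nodata": 2,
    "transitions": 3,
    "pas": 4,
    "kbas": 5,
    "zones": 6,
    "species": 7,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], int(extra)])


#: default land-class mix at time zero: a cultivated/grass-shrub dominated
#: mosaic with a small wetland share, mirroring the relative extent ordering
#: of the real land covers (grass/shrub and forest large, wetland small)
DEFAULT_PROPORTIONS = {
    HarmonizedClass.CULTIVATED: 0.25,
    HarmonizedClass.GRASS_SHRUB: 0.30,
    HarmonizedClass.NONFOREST_WETLAND: 0.05,
    HarmonizedClass.FOREST: 0.30,
    HarmonizedClass.OTHER: 0.10,
}

#: default decadal transition probabilities: ~10% of grass/shrub, 5% of
#: wetland and 3% of forest convert to cultivated per decade; 2% of
#: cultivated reverts to grass/shrub; everything else stays put
DEFAULT_TRANSITIONS = {
    (HarmonizedClass.GRASS_SHRUB, HarmonizedClass.CULTIVATED): 0.10,
    (HarmonizedClass.NONFOREST_WETLAND, HarmonizedClass.CULTIVATED): 0.05,
    (HarmonizedClass.FOREST, HarmonizedClass.CULTIVATED): 0.03,
    (HarmonizedClass.CULTIVATED, HarmonizedClass.GRASS_SHRUB): 0.02,
}


def _full_matrix(
    sparse: dict[tuple[HarmonizedClass, HarmonizedClass], float],
) -> dict[HarmonizedClass, dict[HarmonizedClass, float]]:
    """Expand off-diagonal entries into complete row-stochastic rows."""
    classes = [c for c in HarmonizedClass if c != HarmonizedClass.NODATA]
    rows: dict[HarmonizedClass, dict[HarmonizedClass, float]] = {}
    for src in classes:
        row = {dst: 0.0 for dst in classes}
        off = 0.0
        for (s, d), p in sparse.items():
            if s == src:
                row[d] = float(p)
                off += float(p)
        row[src] = 1.0 - off
        rows[src] = row
    return rows


@dataclass
class SyntheticScenario:
    """Declarative description of one synthetic study landscape."""

    grid_shape: tuple[int, int] = (200, 200)
    cell_size: float = 100.0  # metres; local equal-area grid
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    transition_matrix: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )  # sparse (from, to) -> prob, or full nested rows
    autocorrelation_range: float = 8.0  # cells
    nodata_fraction: float = 0.0
    n_pas: int = 8
    pa_category_probs: dict = field(
        default_factory=lambda: {c: 1 / 6 for c in IUCN_CATEGORIES}
    )
    pa_year_range: tuple[int, int] = (1970, 2015)
    pa_years: list | None = None  # explicit per-PA years override
    n_kbas: int = 4
    n_zones: int = 3
    n_species: int = 40
    threatened_fraction: float = 0.6
    dataset_styles: tuple[str, ...] = ("synthetic",)
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        self.class_proportions = {
            HarmonizedClass(k) if not isinstance(k, HarmonizedClass) else k: float(v)
            for k, v in self.class_proportions.items()
        }
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")
        first = next(iter(self.transition_matrix.values()), None)
        if isinstance(first, dict):
            self.rows = {
                HarmonizedClass(k): {HarmonizedClass(d): float(p) for d, p in row.items()}
                for k, row in self.transition_matrix.items()
            }
        else:
            sparse = {
                (HarmonizedClass(s), HarmonizedClass(d)): float(p)
                for (s, d), p in self.transition_matrix.items()
            }
            self.rows = _full_matrix(sparse)
        for src, row in self.rows.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"transition_matrix row for {src.name} sums to {s}, expected 1"
                )
            bad = {d.name: p for d, p in row.items() if p < 0 or p > 1}
            if bad:
                raise ValueError(
                    f"transition_matrix row for {src.name} has probabilities "
                    f"outside [0,1]: {bad}"
                )
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must be in [0, 1)")

    @property
    def geometry(self) -> GridGeometry:
        rows, cols = self.grid_shape
        return GridGeometry(
            origin_x=0.0,
            origin_y=rows * self.cell_size,
            cell_size=self.cell_size,
            nrows=rows,
            ncols=cols,
            crs_tag="local-equal-area",
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery testing downstream."""

    realized_transition_counts: dict[tuple[HarmonizedClass, HarmonizedClass], int]
    n_valid_cells: int
    pa_truth: dict[str, int] = field(default_factory=dict)
    species_truth: dict[str, bool] = field(default_factory=dict)

    def conversion_rate(self, src: HarmonizedClass) -> float:
        """Realized P(src -> CULTIVATED) among valid src cells at t0."""
        n_src = sum(
            n for (s, _), n in self.realized_transition_counts.items() if s == src
        )
        n_conv = self.realized_transition_counts.get(
            (src, HarmonizedClass.CULTIVATED), 0
        )
        return n_conv / n_src if n_src else float("nan")


def _t0_values(scenario: SyntheticScenario) -> np.ndarray:
    """Smoothed-field construction: threshold a Gaussian random field at the
    class-proportion quantiles so patches are contiguous and proportions
    near-exact (exact up to integer rounding of cell counts)."""
    rng = _rng(scenario.seed, "field")
    field_ = rng.standard_normal(scenario.grid_shape)
    if scenario.autocorrelation_range > 0:
        field_ = gaussian_filter(field_, sigma=scenario.autocorrelation_range)
    order = np.argsort(field_, axis=None, kind="stable")
    n = field_.size
    out = np.empty(n, dtype=np.int8)
    start = 0
    items = list(scenario.class_proportions.items())
    for i, (cls, p) in enumerate(items):
        stop = n if i == len(items) - 1 else start + int(round(p * n))
        out[order[start:stop]] = int(cls)
        start = stop
    values = out.reshape(scenario.grid_shape)
    if scenario.nodata_fraction > 0:
        nd = _rng(scenario.seed, "nodata").random(scenario.grid_shape)
        values = np.where(
            nd < scenario.nodata_fraction, int(HarmonizedClass.NODATA), values
        )
    return values


def _advance(
    values: np.ndarray, scenario: SyntheticScenario, epoch_index: int
) -> np.ndarray:
    """Apply the transition matrix i.i.d. per cell for one epoch step."""
    rng = _rng(scenario.seed, "transitions", epoch_index)
    u = rng.random(values.shape)
    out = values.copy()
    for src, row in scenario.rows.items():
        mask = values == int(src)
        if not mask.any():
            continue
        dsts = list(row)
        cum = np.cumsum([row[d] for d in dsts])
        idx = np.searchsorted(cum, u[mask], side="right")
        idx = np.clip(idx, 0, len(dsts) - 1)  # guard float roundoff at u~1
        out[mask] = np.array([int(d) for d in dsts], dtype=values.dtype)[idx]
    return out


def _count_transitions(
    a: np.ndarray, b: np.ndarray
) -> dict[tuple[HarmonizedClass, HarmonizedClass], int]:
    valid = (a != int(HarmonizedClass.NODATA)) & (b != int(HarmonizedClass.NODATA))
    pairs, counts = np.unique(
        np.stack([a[valid], b[valid]]).reshape(2, -1), axis=1, return_counts=True
    )
    return {
        (HarmonizedClass(int(s)), HarmonizedClass(int(d))): int(n)
        for (s, d), n in zip(pairs.T, counts)
    }


def generate_landscape(
    scenario: SyntheticScenario, dataset_id: str = "synthetic"
) -> tuple[EpochRaster, EpochRaster, GroundTruth]:
    """Generate the two-epoch landscape and its realized-transition truth."""
    geom = scenario.geometry
    v0 = _t0_values(scenario)
    v1 = _advance(v0, scenario, epoch_index=0)
    v1 = np.where(v0 == int(HarmonizedClass.NODATA), int(HarmonizedClass.NODATA), v1)
    counts = _count_transitions(v0, v1)
    truth = GroundTruth(
        realized_transition_counts=counts,
        n_valid_cells=int((v0 != int(HarmonizedClass.NODATA)).sum()),
    )
    t0 = EpochRaster(values=v0, year=2000, dataset_id=dataset_id, geom=geom,
                     nodata=int(HarmonizedClass.NODATA))
    t1 = EpochRaster(values=v1, year=2010, dataset_id=dataset_id, geom=geom,
                     nodata=int(HarmonizedClass.NODATA))
    return t0, t1, truth


def generate_epoch_chain(
    scenario: SyntheticScenario,
    years: list[int],
    dataset_id: str = "synthetic",
) -> list[EpochRaster]:
    """Chain the per-epoch transition matrix over several epochs."""
    geom = scenario.geometry
    values = _t0_values(scenario)
    nodata = values == int(HarmonizedClass.NODATA)
    rasters = [
        EpochRaster(values=values, year=years[0], dataset_id=dataset_id, geom=geom,
                    nodata=int(HarmonizedClass.NODATA))
    ]
    for i, year in enumerate(years[1:]):
        values = _advance(values, scenario, epoch_index=i)
        values = np.where(nodata, int(HarmonizedClass.NODATA), values)
        rasters.append(
            EpochRaster(values=values, year=year, dataset_id=dataset_id, geom=geom,
                        nodata=int(HarmonizedClass.NODATA))
        )
    return rasters


def _random_rect(rng, geom: GridGeometry, min_frac=0.05, max_frac=0.3):
    """Axis-aligned rectangle inside the extent, corners off cell boundaries."""
    xmin, ymin, xmax, ymax = geom.extent()
    w_ext, h_ext = xmax - xmin, ymax - ymin
    w = rng.uniform(min_frac, max_frac) * w_ext
    h = rng.uniform(min_frac, max_frac) * h_ext
    x0 = xmin + rng.uniform(0, w_ext - w)
    y0 = ymin + rng.uniform(0, h_ext - h)
    # snap corners off cell-boundary multiples to exercise partial cells
    snap = geom.cell_size

    def off(v):
        frac = (v / snap) % 1.0
        return v + (0.31 - frac) * snap if abs(frac) < 1e-9 or abs(frac - 1) < 1e-9 else v

    return box(off(x0), off(y0), off(x0 + w), off(y0 + h))


def generate_conservation_layers(
    scenario: SyntheticScenario, t0: EpochRaster
) -> tuple[PACollection, KBACollection, ZoneLayer]:
    """Protected areas, KBAs and country zones over the landscape extent."""
    geom = t0.geom
    rng = _rng(scenario.seed, "pas")
    cats = list(scenario.pa_category_probs)
    cat_p = np.array([scenario.pa_category_probs[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    pas: list[PARecord] = []
    attempts = 0
    while len(pas) < scenario.n_pas and attempts < scenario.n_pas * 40:
        attempts += 1
        rect = _random_rect(rng, geom)
        too_much_overlap = any(
            rect.intersection(p.geometry).area > 0.5 * rect.area for p in pas
        )
        if too_much_overlap:
            continue
        i = len(pas)
        if scenario.pa_years is not None:
            year = int(scenario.pa_years[i % len(scenario.pa_years)])
        else:
            year = int(rng.integers(scenario.pa_year_range[0], scenario.pa_year_range[1] + 1))
        pas.append(
            PARecord(
                pa_id=f"PA{i:03d}",
                geometry=rect,
                iucn_category=str(rng.choice(cats, p=cat_p)),
                establishment_year=year,
                designation="synthetic reserve",
            )
        )
    if len(pas) < scenario.n_pas:
        warnings.warn(
            f"could only place {len(pas)} of {scenario.n_pas} PAs without "
            ">50% mutual overlap; emitting fewer polygons"
        )

    rng_k = _rng(scenario.seed, "kbas")
    kbas = KBACollection(
        [
            KBARecord(kba_id=f"KBA{i:03d}", geometry=_random_rect(rng_k, geom),
                      name=f"synthetic KBA {i}")
            for i in range(scenario.n_kbas)
        ]
    )

    # vertical strips with random integer-column boundaries: exact partition,
    # and cell centers (at half-cells) never sit on a strip edge
    rng_z = _rng(scenario.seed, "zones")
    n_zones = max(2, scenario.n_zones)
    cuts = np.sort(rng_z.choice(np.arange(1, geom.ncols), size=n_zones - 1, replace=False))
    edges = np.concatenate([[0], cuts, [geom.ncols]])
    xmin, ymin, xmax, ymax = geom.extent()
    pad = geom.cell_size  # pad outer edges so border cell centers are interior
    geoms, ids = [], []
    for i in range(n_zones):
        x0 = xmin + edges[i] * geom.cell_size
        x1 = xmin + edges[i + 1] * geom.cell_size
        if i == 0:
            x0 -= pad
        if i == n_zones - 1:
            x1 += pad
        geoms.append(box(x0, ymin - pad, x1, ymax + pad))
        ids.append(f"Z{i:02d}")
    zones = ZoneLayer(zone_ids=ids, geometries=geoms,
                      names=[f"country {i}" for i in range(n_zones)])
    return PACollection(pas), kbas, zones


def generate_species_ranges(
    scenario: SyntheticScenario, t0: EpochRaster
) -> SpeciesCollection:
    """Species ranges (buffered random points) with taxon/status/habitats."""
    geom = t0.geom
    rng = _rng(scenario.seed, "species")
    xmin, ymin, xmax, ymax = geom.extent()
    w, h = xmax - xmin, ymax - ymin
    records = []
    size_probs = [0.5, 0.3, 0.2]  # P(|habitats| = 1, 2, 3)
    for i in range(scenario.n_species):
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        radius = rng.uniform(0.03, 0.20) * min(w, h)
        poly = shapely_point(cx, cy).buffer(radius, quad_segs=8)
        poly = poly.intersection(box(xmin, ymin, xmax, ymax))
        if rng.random() < scenario.threatened_fraction:
            red_list = str(rng.choice(["VU", "EN", "CR"]))
        else:
            red_list = "other"
        k = int(rng.choice([1, 2, 3], p=size_probs))
        habitats = frozenset(
            rng.choice(len(HABITAT_CLASSES), size=k, replace=False).tolist()
        )
        records.append(
            SpeciesRange(
                species_id=f"SP{i:04d}",
                taxon=str(rng.choice(TAXA)),
                red_list=red_list,
                habitats=frozenset(HABITAT_CLASSES[j] for j in habitats),
                geometry=poly,
            )
        )
    return SpeciesCollection(records)


def shapely_point(x: float, y: float):
    from shapely.geometry import Point

    return Point(x, y)


def attach_overlay_truth(
    truth: GroundTruth,
    t0: EpochRaster,
    t1: EpochRaster,
    pas: PACollection | None = None,
    species: SpeciesCollection | None = None,
) -> GroundTruth:
    """Fill per-PA converted-cell counts and per-species overlap flags.

    Uses direct cell-center containment per polygon (PAs) and positive-area
    cell-box intersection (species), the same geometric rules the analysis
    modules use; tests compare both against exhaustive loops.
    """
    from .layers import cells_inside

    geom = t0.geom
    conv = _conversion_mask(t0, t1)
    if pas is not None:
        for r in pas:
            inside = cells_inside(r.geometry, geom)
            truth.pa_truth[r.pa_id] = int((inside & conv).sum())
    if species is not None:
        boxes = _cell_boxes(geom, conv)
        import shapely as _sh

        tree = _sh.STRtree(boxes) if boxes else None
        for sp in species:
            flag = False
            if tree is not None:
                for j in tree.query(sp.geometry, predicate="intersects"):
                    if sp.geometry.intersection(boxes[j]).area > 0:
                        flag = True
                        break
            truth.species_truth[sp.species_id] = flag
    return truth


def _conversion_mask(t0: EpochRaster, t1: EpochRaster) -> np.ndarray:
    a, b = t0.values, t1.values
    valid = (a != t0.nodata) & (b != t1.nodata)
    natural = np.isin(a, [int(c) for c in HABITAT_CLASSES])
    return valid & natural & (b == int(HarmonizedClass.CULTIVATED))


def _cell_boxes(geom: GridGeometry, mask: np.ndarray) -> list:
    rows, cols = np.nonzero(mask)
    out = []
    for r, c in zip(rows, cols):
        x0 = geom.origin_x + c * geom.cell_size
        y1 = geom.origin_y - r * geom.cell_size
        out.append(box(x0, y1 - geom.cell_size, x0 + geom.cell_size, y1))
    return out


__all__ = [
    "DEFAULT_PROPORTIONS",
    "DEFAULT_TRANSITIONS",
    "GroundTruth",
    "SyntheticScenario",
    "attach_overlay_truth",
    "generate_conservation_layers",
    "generate_epoch_chain",
    "generate_landscape",
    "generate_species_ranges",
]
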