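"""End-to-end orchestration from a declarative YAML config.

A run loads (files mode) or generates (synthetic mode) co-registered epoch
rasters for one or more datasets, detects per-period transitions, and writes
a stable output layout:

    <out>/
      resolved_config.yml
      run_report.json
      transitions_<dataset>_<period>.asc(+.json)
      area_by_zone_<dataset>_<period>.csv
      grid_summary_<dataset>_<period>.csv
      hotspot_cells.csv, hotspot_countries.csv          (hotspots toggle)
      pa_category_areas_*.csv, pa_rates.csv             (pa toggle)
      richness.csv, affected_species.csv, kba_table.csv (biodiversity/kba)

All floating-point CSV values are serialized with 6 significant digits so a
re-run with the same config and seed reproduces every CSV byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biodiversity as bio
from . import hotspots as hs
from . import protected_areas as pa_mod
from . import synthetic as syn
from . import transitions as trans
from .grid import read_ascii_grid, write_ascii_grid
from .harmonization import builtin_table, harmonize
from .layers import KBACollection, PACollection, SpeciesCollection, ZoneLayer

FLOAT_FORMAT = "%.6g"

ALL_CONVERSION = frozenset(trans.CONVERSION_CODES)
NONFOREST = frozenset(trans.NONFOREST_CONVERSION_CODES)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    periods: list[tuple[int, int]] = field(
        default_factory=lambda: [(2000, 2010), (2010, 2020)]
    )
    seed: int = 0
    output_dir: str = "landconvert_run"
    # analysis toggles
    hotspots: bool = True
    pa: bool = True
    biodiversity: bool = True
    kba: bool = True
    # parameters
    hotspot_threshold: float = 0.90
    hotspot_k: int = 10
    hotspot_min_datasets: int = 2
    coarse_cell_size_m: float | None = None  # default: 10 raster cells
    richness_cell_size_m: float | None = None  # default: 3x coarse
    pa_cutoff_year: int | None = None  # default: first period start
    biodiversity_dataset: str | None = None  # default: first dataset
    # synthetic mode
    scenario: dict = field(default_factory=dict)
    dataset_styles: list[str] = field(default_factory=lambda: ["synthetic"])
    # files mode: {dataset_id: {year: raster_path}}, plus layer paths
    rasters: dict = field(default_factory=dict)
    harmonize_inputs: bool = False
    pa_path: str | None = None
    kba_path: str | None = None
    zones_path: str | None = None
    species_path: str | None = None

    def __post_init__(self) -> None:
        self.periods = [tuple(p) for p in self.periods]
        last_end = None
        for start, end in self.periods:
            if start >= end:
                raise ValueError(f"period {start}-{end} is not ordered")
            if last_end is not None and start < last_end:
                raise ValueError("periods must be non-overlapping and ordered")
            last_end = end
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            for ds, by_year in self.rasters.items():
                for year, path in by_year.items():
                    if not Path(path).exists():
                        raise FileNotFoundError(f"{ds}/{year}: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["periods"] = [list(p) for p in self.periods]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _load_inputs(config: RunConfig):
    """Return (epochs: {dataset: {year: EpochRaster}}, pas, kbas, zones, species)."""
    years = sorted({y for p in config.periods for y in p})
    epochs: dict[str, dict[int, object]] = {}
    if config.mode == "synthetic":
        base = dict(config.scenario)
        pas = kbas = zones = species = None
        for i, ds in enumerate(config.dataset_styles):
            params = dict(base)
            params["seed"] = (config.seed * 131 + i) % (2**31 - 1)
            params["dataset_styles"] = (ds,)
            scenario = syn.SyntheticScenario(**params)
            chain = syn.generate_epoch_chain(scenario, years, dataset_id=ds)
            epochs[ds] = {r.year: r for r in chain}
            if i == 0:
                # shared conservation/species layers from the first realization
                pas, kbas, zones = syn.generate_conservation_layers(scenario, chain[0])
                species = syn.generate_species_ranges(scenario, chain[0])
        return epochs, pas, kbas, zones, species

    for ds, by_year in config.rasters.items():
        epochs[ds] = {}
        for year, path in by_year.items():
            raster = read_ascii_grid(path)
            raster.year = int(year)
            raster.dataset_id = ds
            if config.harmonize_inputs:
                raster = harmonize(raster, builtin_table(ds))
            epochs[ds][int(year)] = raster
    pas = PACollection.from_geojson(config.pa_path) if config.pa_path else PACollection()
    kbas = KBACollection.from_geojson(config.kba_path) if config.kba_path else KBACollection()
    if config.zones_path:
        zones = ZoneLayer.from_geojson(config.zones_path)
    else:
        raise ValueError("files mode requires zones_path")
    species = (
        SpeciesCollection.from_geojson(config.species_path)
        if config.species_path
        else SpeciesCollection()
    )
    return epochs, pas, kbas, zones, species


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle and writes files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs, pas, kbas, zones, species = _load_inputs(config)
    datasets = list(epochs)
    geom = epochs[datasets[0]][min(epochs[datasets[0]])].geom
    coarse = config.coarse_cell_size_m or 10 * geom.cell_size
    rich_size = config.richness_cell_size_m or 3 * coarse

    report: dict = {"datasets": {}, "pa_filters": [], "skipped_species": []}
    bundle: dict = {"config": config}

    per_ds_transitions: dict[str, list] = {}
    area_tables: dict[str, pd.DataFrame] = {}
    nonforest_grids_combined: dict[str, pd.DataFrame] = {}
    allconv_grids_combined: dict[str, pd.DataFrame] = {}

    for ds in datasets:
        per_period = []
        report["datasets"][ds] = {}
        for start, end in config.periods:
            tr = trans.detect_transitions(epochs[ds][start], epochs[ds][end])
            per_period.append(tr)
            label = tr.period_label
            n_total = tr.values.size
            n_valid = int(tr.valid_mask.sum())
            report["datasets"][ds][label] = {
                "total_cells": n_total,
                "valid_cells": n_valid,
                "nodata_cells": n_total - n_valid,
            }
            write_ascii_grid(
                _as_epoch(tr), out / f"transitions_{ds}_{label}.asc"
            )
            at = trans.aggregate_by_zone(tr, zones)
            _write_csv(at, out / f"area_by_zone_{ds}_{label}.csv")
            gs = trans.grid_fraction(tr, coarse, which=NONFOREST)
            _write_csv(gs, out / f"grid_summary_{ds}_{label}.csv")
        per_ds_transitions[ds] = per_period
        combined = per_period[0]
        for nxt in per_period[1:]:
            combined = trans.combine_periods(combined, nxt)
        per_ds_transitions[ds].append(combined)
        at_combined = trans.aggregate_by_zone(combined, zones)
        label = combined.period_label
        _write_csv(at_combined, out / f"area_by_zone_{ds}_{label}.csv")
        area_tables[ds] = at_combined
        nonforest_grids_combined[ds] = trans.grid_fraction(combined, coarse, which=NONFOREST)
        allconv_grids_combined[ds] = trans.grid_fraction(
            combined, coarse, which=ALL_CONVERSION
        )
    bundle["area_tables"] = area_tables

    if config.hotspots:
        cells = hs.hotspot_cells(nonforest_grids_combined, config.hotspot_threshold)
        cells_df = pd.DataFrame({"grid_cell_id": cells.cell_ids})
        cells_df["coverage_achieved"] = cells.coverage_achieved
        cells_df["threshold"] = cells.threshold
        _write_csv(cells_df, out / "hotspot_cells.csv")
        countries = hs.hotspot_countries(
            area_tables, k=config.hotspot_k, min_datasets=config.hotspot_min_datasets
        )
        _write_csv(countries, out / "hotspot_countries.csv")
        bundle["hotspot_cells"] = cells
        bundle["hotspot_countries"] = countries

    if config.pa and pas is not None:
        # per-period category shares with period-specific establishment cutoffs
        for ds in datasets:
            for tr in per_ds_transitions[ds][:-1]:
                cutoff = tr.period[0]
                pas_f, rep = pa_mod.filter_by_year(pas, cutoff)
                rep["dataset_id"], rep["period"] = ds, tr.period_label
                report["pa_filters"].append(rep)
                _, props = pa_mod.pa_conversion(tr, epochs[ds][tr.period[0]], pas_f)
                _write_csv(
                    props, out / f"pa_category_areas_{ds}_{tr.period_label}.csv"
                )
        # full-span rates with the overall cutoff
        cutoff = config.pa_cutoff_year or config.periods[0][0]
        pas_f, rep = pa_mod.filter_by_year(pas, cutoff)
        rep["dataset_id"], rep["period"] = "all", "full-span"
        report["pa_filters"].append(rep)
        rate_frames = []
        for ds in datasets:
            combined = per_ds_transitions[ds][-1]
            t0 = epochs[ds][combined.period[0]]
            rate_frames.append(pa_mod.conversion_rates(combined, t0, pas_f, zones))
        rates = pd.concat(rate_frames, ignore_index=True)
        _write_csv(rates, out / "pa_rates.csv")
        bundle["pa_rates"] = rates

    if config.biodiversity and species is not None:
        consensus = bio.consensus_cells(
            {
                ds: trans.grid_fraction(per_ds_transitions[ds][-1], rich_size,
                                        which=ALL_CONVERSION)
                for ds in datasets
            }
        )
        rich = bio.richness(species, geom, rich_size, restrict=consensus)
        report["skipped_species"] = rich.attrs["skipped_species"]
        _write_csv(rich, out / "richness.csv")
        focal_ds = config.biodiversity_dataset or datasets[0]
        summary = bio.affected_species(per_ds_transitions[focal_ds][-1], species)
        aff_rows = [
            {"kind": "taxon", "key": taxon, "bucket": "", "count": n}
            for taxon, n in sorted(summary.by_taxon.items())
        ] + [
            {"kind": "class_bucket", "key": cls, "bucket": bucket, "count": n}
            for (cls, bucket), n in sorted(summary.by_class_bucket.items())
        ]
        aff = pd.DataFrame(aff_rows, columns=["kind", "key", "bucket", "count"])
        _write_csv(aff, out / "affected_species.csv")
        bundle["richness"] = rich
        bundle["affected_species"] = summary

    if config.kba and kbas is not None and pas is not None:
        kba_frames = []
        for ds in datasets:
            kba_frames.append(
                bio.kba_conversion(per_ds_transitions[ds][-1], kbas, pas, zones)
            )
        kba_table = pd.concat(kba_frames, ignore_index=True)
        _write_csv(kba_table, out / "kba_table.csv")
        bundle["kba_table"] = kba_table

    config.to_yaml(out / "resolved_config.yml")
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    bundle["report"] = report
    bundle["transitions"] = per_ds_transitions
    return bundle


def _as_epoch(tr: trans.TransitionRaster):
    """View a transition raster as an EpochRaster for ASCII serialization."""
    from .grid import EpochRaster

    return EpochRaster(
        values=tr.values.astype(int),
        year=tr.period[1],
        dataset_id=tr.dataset_id,
        geom=tr.geom,
        nodata=int(trans.TransitionCode.NODATA),
    )


__all__ = ["RunConfig", "run"]
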