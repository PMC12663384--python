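"""Hotspot identification: 90%-coverage grid cells and top-k countries.

Hotspot *cells* are the minimal prefix of grid cells, ranked by mean
converted area across datasets (descending, ties broken by ascending cell
id), whose cumulative converted area reaches the coverage threshold
(default 90% of the global total).

Hotspot *countries* are zones that rank within the top k (default 10) by
conversion area in at least ``min_datasets`` (default 2) of the datasets;
the output table is ordered by cross-dataset mean area descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class HotspotCellSet:
    cell_ids: list = field(default_factory=list)
    coverage_achieved: float = 0.0
    threshold: float = 0.90
    mean_areas: pd.DataFrame | None = None


def hotspot_cells(
    grids: dict[str, pd.DataFrame], threshold: float = 0.90
) -> HotspotCellSet:
    """Minimal descending-order prefix of cells covering ``threshold`` of
    total converted area, using the cross-dataset mean per cell.

    ``grids`` maps dataset_id -> GridSummary (needs columns grid_cell_id and
    area_converted_ha); cells absent from a dataset count as zero there.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not grids:
        raise ValueError("no grid summaries provided")
    per_dataset = []
    for ds, df in grids.items():
        s = df.groupby("grid_cell_id")["area_converted_ha"].sum().rename(ds)
        per_dataset.append(s)
    wide = pd.concat(per_dataset, axis=1).fillna(0.0)
    mean = wide.mean(axis=1).rename("mean_area_ha")
    total = float(mean.sum())
    if total <= 0:
        warnings.warn("zero total conversion: hotspot cell set is empty")
        return HotspotCellSet(threshold=threshold, mean_areas=mean.reset_index())
    ordered = mean.sort_index().sort_values(ascending=False, kind="stable")
    cum = ordered.cumsum() / total
    n_sel = int((cum < threshold).sum()) + 1  # first index reaching threshold
    n_sel = min(n_sel, int((ordered > 0).sum()))  # zero cells never add coverage
    selected = ordered.iloc[:n_sel]
    return HotspotCellSet(
        cell_ids=selected.index.tolist(),
        coverage_achieved=float(selected.sum() / total),
        threshold=threshold,
        mean_areas=mean.reset_index(),
    )


def hotspot_countries(
    tables: dict[str, pd.DataFrame],
    k: int = 10,
    min_datasets: int = 2,
    which: set[str] = frozenset({"CONV_GRASS", "CONV_WETLAND"}),
    exclude_zones: set[str] = frozenset({"unassigned"}),
) -> pd.DataFrame:
    """Rank zones by conversion area per dataset and flag cross-dataset
    hotspots.

    ``tables`` maps dataset_id -> AreaTable. A zone is a hotspot when it is
    in the top ``k`` by summed area over the transition codes in ``which``
    for at least ``min_datasets`` datasets. Zones missing from a dataset
    count as zero area there (no detected conversion). Returns a table with
    per-dataset areas, the cross-dataset mean, the top-k membership count
    and the hotspot flag, sorted by mean area descending (zone id ties
    ascending).
    """
    if k < 1 or min_datasets < 1:
        raise ValueError("k and min_datasets must be >= 1")
    per_dataset = {}
    for ds, df in tables.items():
        sel = df[df.transition_code.isin(which) & ~df.zone_id.isin(exclude_zones)]
        per_dataset[ds] = sel.groupby("zone_id")["area_ha"].sum().rename(ds)
    wide = pd.concat(per_dataset.values(), axis=1).fillna(0.0)
    n_top = pd.Series(0, index=wide.index, dtype=int)
    for ds in per_dataset:
        ranked = wide[ds].sort_index().sort_values(ascending=False, kind="stable")
        top = set(ranked.iloc[:k].index)
        n_top.loc[n_top.index.isin(top)] += 1
    out = wide.copy()
    out["mean_area_ha"] = wide.mean(axis=1)
    out["n_datasets_top_k"] = n_top
    out["is_hotspot"] = n_top >= min_datasets
    out = (
        out.reset_index()
        .rename(columns={"index": "zone_id"})
        .sort_values(["mean_area_ha", "zone_id"], ascending=[False, True],
                     kind="stable")
        .reset_index(drop=True)
    )
    return out


__all__ = ["HotspotCellSet", "hotspot_cells", "hotspot_countries"]
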