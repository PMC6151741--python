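"""Zonal area accounting: suitable area per region on a spherical Earth.

A suitability mask is turned into ranked per-region areas in km².  Cell
area uses the exact spherical-zone formula on the authalic Earth radius
(6371.0088 km): a cell spanning longitude width Δλ between latitudes
φ_bottom and φ_top has area ``R² · Δλ_rad · (sin φ_top − sin φ_bottom)``,
constant within a grid row and shrinking toward the poles.  A true cell is
assigned to the region containing its centre (no partial-cell weighting);
true cells whose centre falls in no region are reported under a reserved
``(unassigned)`` row, so that per-region areas always sum to the total
mask area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .grids import GridLayer, RegionSet

__all__ = [
    "EARTH_RADIUS_KM",
    "UNASSIGNED",
    "RegionSummary",
    "cell_area",
    "row_areas",
    "summarize_by_region",
    "clip_mask",
    "plot_rank",
]

#: Authalic (equal-area-sphere) Earth radius.
EARTH_RADIUS_KM = 6371.0088

UNASSIGNED = "(unassigned)"


@dataclass
class RegionSummary:
    """Ranked suitable areas per region.

    ``table`` columns: region, area_km2, cells — sorted by area descending,
    ties broken alphabetically by region name.
    """

    table: pd.DataFrame
    total_area_km2: float
    total_cells: int

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def area_of(self, region: str) -> float:
        hit = self.table.loc[self.table["region"] == region, "area_km2"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def cell_area(row: int, layer: GridLayer) -> float:
    """Spherical-Earth area (km²) of one cell in the given grid row."""
    n_rows = layer.shape[0]
    if not 0 <= row < n_rows:
        raise IndexError(f"row {row} outside grid of {n_rows} rows")
    t = layer.transform
    lat_top = np.radians(t.north - row * t.dy)
    lat_bottom = np.radians(t.north - (row + 1) * t.dy)
    dlam = np.radians(t.dx)
    return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bottom)))


def row_areas(layer: GridLayer) -> np.ndarray:
    """Vector of per-cell areas (km²) for every grid row."""
    t = layer.transform
    rows = np.arange(layer.shape[0])
    lat_top = np.radians(t.north - rows * t.dy)
    lat_bottom = np.radians(t.north - (rows + 1) * t.dy)
    return EARTH_RADIUS_KM**2 * np.radians(t.dx) * (np.sin(lat_top) - np.sin(lat_bottom))


def _assign_regions(mask: GridLayer, regions: RegionSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, region_index) of true cells; index -1 = unassigned."""
    truth = (mask.values == 1) & mask.valid
    rows, cols = np.nonzero(truth)
    lon, lat = mask.transform.cell_center(rows, cols)
    assignment = np.full(rows.shape, -1, dtype=np.int64)
    for i, (_, geom) in enumerate(regions.regions):
        free = assignment == -1
        if not free.any():
            break
        hit = shapely.contains_xy(geom, lon[free], lat[free])
        idx = np.nonzero(free)[0][hit]
        assignment[idx] = i
    return rows, cols, assignment


def summarize_by_region(mask: GridLayer, regions: RegionSet) -> RegionSummary:
    """Suitable area and cell count per region, ranked by area.

    Each true cell contributes its spherical cell area to the first region
    (in set order) containing its centre; centres in no region land in the
    ``(unassigned)`` row.  The per-region areas (including unassigned) sum
    exactly to the total mask area.
    """
    rows, _, assignment = _assign_regions(mask, regions)
    areas = row_areas(mask)[rows]
    records = []
    for i, (name, _) in enumerate(regions.regions):
        sel = assignment == i
        records.append((name, float(areas[sel].sum()), int(sel.sum())))
    sel = assignment == -1
    records.append((UNASSIGNED, float(areas[sel].sum()), int(sel.sum())))

    table = pd.DataFrame(records, columns=["region", "area_km2", "cells"])
    table = table.sort_values(["area_km2", "region"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return RegionSummary(table=table,
                         total_area_km2=float(areas.sum()),
                         total_cells=int(rows.size))


def clip_mask(mask: GridLayer, regions: RegionSet, name: str) -> GridLayer:
    """Restrict a mask to one named region (cells outside become false)."""
    geom = regions[name]  # KeyError for unknown names
    truth = (mask.values == 1) & mask.valid
    rows, cols = np.nonzero(truth)
    lon, lat = mask.transform.cell_center(rows, cols)
    inside = shapely.contains_xy(geom, lon, lat)
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[rows[inside], cols[inside]] = 1
    nodata = 255
    out = np.where(mask.valid, out, np.uint8(nodata))
    return GridLayer(name=f"{mask.name}:{name}", units="bool", values=out,
                     transform=mask.transform, nodata=nodata)


def plot_rank(summary: RegionSummary, path: str | Path, top: int = 15,
              title: str = "Suitable area by region") -> Path:
    """Horizontal bar chart of the top regions by suitable area."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary.table[summary.table["region"] != UNASSIGNED].head(top)
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(table), 4) + 1.2))
    ax.barh(table["region"][::-1], table["area_km2"][::-1] / 1e3, color="#3a7d44")
    ax.set_xlabel("suitable area (10³ km²)")
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
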