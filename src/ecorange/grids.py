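"""Raster layers, occurrence tables and region polygons, with file I/O.

Everything downstream operates on a small set of in-memory containers:

* :class:`GridLayer` — one named ecological factor on a regular
  longitude/latitude grid (row 0 is the northernmost row).
* :class:`LayerStack` — the continuous factors plus one categorical soil
  layer, all on an identical grid.
* :class:`OccurrenceSet` — species presence coordinates.
* :class:`RegionSet` — named polygons used for zonal area accounting.

Rasters travel as GeoTIFF (written through tifffile with explicit
georeferencing tags) or ESRI ASCII grid; occurrences as CSV with columns
``species, longitude, latitude``; regions as a GeoJSON FeatureCollection
whose features carry a ``name`` property.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "DEFAULT_NODATA",
    "GEOGRAPHIC_CRS",
    "GridTransform",
    "GridLayer",
    "LayerStack",
    "OccurrenceSet",
    "RegionSet",
    "CRSError",
    "GridMismatchError",
    "OccurrenceValidationError",
    "RegionValidationError",
    "read_layer",
    "write_layer",
    "read_occurrences",
    "write_occurrences",
    "read_regions",
    "write_regions",
]

#: Sentinel used when a raster file carries no nodata metadata.  Far outside
#: any ecological value range, and representable in float32.
DEFAULT_NODATA = -3.4e38

GEOGRAPHIC_CRS = "EPSG:4326"


class CRSError(ValueError):
    """Raster is not in a geographic (longitude/latitude) CRS."""


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


class OccurrenceValidationError(ValueError):
    """An occurrence record violates the coordinate contract."""


class RegionValidationError(ValueError):
    """A region feature is malformed or its geometry cannot be repaired."""


@dataclass(frozen=True)
class GridTransform:
    """Corner-registered geographic grid geometry.

    ``west`` / ``north`` are the outer edges of the top-left cell; ``dx`` /
    ``dy`` are cell width/height in decimal degrees (both strictly
    positive).  Cell ``(row, col)`` covers the half-open box
    ``[west + col*dx, west + (col+1)*dx)`` in longitude and
    ``(north - (row+1)*dy, north - row*dy]`` in latitude, so any point maps
    to at most one cell.
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("cell width and height must be strictly positive")

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized point -> (row, col) under the half-open convention.

        Indices may fall outside the grid; callers bounds-check against the
        layer shape.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # a point exactly on a cell's top edge has (north - lat)/dy equal to
        # the row index itself, so floor realises the closed-top convention
        col = np.floor((lon - self.west) / self.dx).astype(np.int64)
        row = np.floor((self.north - lat) / self.dy).astype(np.int64)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.west + (np.asarray(col) + 0.5) * self.dx
        lat = self.north - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def extent(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(west, south, east, north) of the full grid."""
        n_rows, n_cols = shape
        return (
            self.west,
            self.north - n_rows * self.dy,
            self.west + n_cols * self.dx,
            self.north,
        )


@dataclass
class GridLayer:
    """One ecological factor on a geographic raster grid.

    ``values`` is a 2-D array with row 0 the northernmost row.  Cells equal
    to ``nodata`` carry no measurement and are excluded from every
    statistic.  Continuous factors are floats; the soil layer holds integer
    category codes (stored as floats or ints — comparisons are exact).
    """

    name: str
    units: str
    values: np.ndarray
    transform: GridTransform
    nodata: float = DEFAULT_NODATA
    crs: str = GEOGRAPHIC_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        if self.values.size == 0:
            raise ValueError(f"layer {self.name!r}: empty grid")
        finite = np.isfinite(self.values) | (self.values == self.nodata)
        if not finite.all():
            raise ValueError(f"layer {self.name!r}: non-finite cells that are not the nodata sentinel")
        west, south, east, north = self.transform.extent(self.values.shape)
        if not (-180.0 - 1e-9 <= west and east <= 180.0 + 1e-9 and -90.0 - 1e-9 <= south and north <= 90.0 + 1e-9):
            raise ValueError(f"layer {self.name!r}: grid extent outside geographic bounds")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "GridLayer") -> bool:
        return self.shape == other.shape and self.transform == other.transform and self.crs == other.crs

    # -- nodata handling ------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of measured cells."""
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def min_max(self) -> tuple[float, float]:
        """(min, max) over valid cells; raises on an all-nodata layer."""
        v = self.valid_values()
        if v.size == 0:
            raise ValueError(f"layer {self.name!r}: all cells are nodata; min/max undefined")
        return float(v.min()), float(v.max())

    def with_values(self, values: np.ndarray, name: str | None = None, units: str | None = None,
                    nodata: float | None = None) -> "GridLayer":
        """New layer on the same grid with different cell values."""
        return GridLayer(
            name=name if name is not None else self.name,
            units=units if units is not None else self.units,
            values=values,
            transform=self.transform,
            nodata=self.nodata if nodata is None else nodata,
            crs=self.crs,
        )


@dataclass
class LayerStack:
    """Continuous factor layers plus one categorical soil layer on a shared grid.

    ``factor_order`` fixes the factor ordering used by every vector
    operation downstream (normalization, scoring, CSV export).
    """

    layers: dict[str, GridLayer]
    soil: GridLayer
    factor_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.factor_order:
            self.factor_order = tuple(self.layers)
        if set(self.factor_order) != set(self.layers):
            raise ValueError("factor_order must list exactly the continuous factor names")
        if len(set(self.factor_order)) != len(self.factor_order):
            raise ValueError("factor names must be unique")
        ref = self.soil
        for name, layer in self.layers.items():
            if not layer.same_grid(ref):
                raise GridMismatchError(f"layer {name!r} does not share the soil layer's grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.soil.shape

    @property
    def transform(self) -> GridTransform:
        return self.soil.transform

    def __iter__(self) -> Iterable[GridLayer]:
        return (self.layers[name] for name in self.factor_order)

    def __getitem__(self, name: str) -> GridLayer:
        if name == "soil":
            return self.soil
        return self.layers[name]


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one species."""

    species: str
    points: list[tuple[float, float]]
    source: str = ""

    def __post_init__(self) -> None:
        for i, (lon, lat) in enumerate(self.points):
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise OccurrenceValidationError(
                    f"point {i}: coordinate ({lon}, {lat}) outside longitude [-180, 180] / latitude [-90, 90]"
                )

    def __len__(self) -> int:
        return len(self.points)

    def lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.points, dtype=float).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]

    def deduplicated(self) -> "OccurrenceSet":
        seen: dict[tuple[float, float], None] = {}
        for p in self.points:
            seen.setdefault((float(p[0]), float(p[1])))
        return OccurrenceSet(self.species, list(seen), self.source)


@dataclass
class RegionSet:
    """Named polygons (countries/provinces) in geographic coordinates."""

    regions: list[tuple[str, BaseGeometry]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            raise RegionValidationError("region names must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def names(self) -> list[str]:
        return [n for n, _ in self.regions]

    def __getitem__(self, name: str) -> BaseGeometry:
        for n, g in self.regions:
            if n == name:
                return g
        raise KeyError(f"unknown region {name!r}")


# ---------------------------------------------------------------------------
# GeoTIFF read/write (tifffile + explicit GeoTIFF tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024       # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025      # 1 = PixelIsArea
_KEY_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS84
_KEY_PROJECTED_CS = 3072


def _write_geotiff(layer: GridLayer, path: Path) -> None:
    import tifffile

    t = layer.transform
    geo_keys = (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, 2,
        _KEY_RASTER_TYPE, 0, 1, 1,
        _KEY_GEOGRAPHIC_TYPE, 0, 1, 4326,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.west, t.north, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geo_keys), geo_keys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(layer.nodata))),
    ]
    tifffile.imwrite(
        path,
        layer.values,
        extratags=extratags,
        description=json.dumps({"name": layer.name, "units": layer.units}),
        metadata=None,
    )


def _read_geotiff(path: Path, name: str) -> GridLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags

        geo = tags.get(_TAG_GEO_KEYS)
        if geo is not None:
            keys = np.asarray(geo.value).ravel()
            kv = {int(keys[i]): int(keys[i + 3]) for i in range(4, len(keys) - 3, 4)}
            model = kv.get(_KEY_MODEL_TYPE)
            if model == 1:
                epsg = kv.get(_KEY_PROJECTED_CS, "unknown")
                raise CRSError(
                    f"{path}: raster is in a projected CRS (EPSG:{epsg}); only geographic longitude/latitude is supported"
                )
            gcs = kv.get(_KEY_GEOGRAPHIC_TYPE, 4326)
            crs = f"EPSG:{gcs}"
        else:
            crs = GEOGRAPHIC_CRS

        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise CRSError(f"{path}: TIFF lacks georeferencing tags (not a GeoTIFF)")
        dx, dy = float(scale.value[0]), float(scale.value[1])
        west, north = float(tie.value[3]), float(tie.value[4])

        nd_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nd_tag.value) if nd_tag is not None else DEFAULT_NODATA

        units = ""
        lname = name
        desc = tags.get(270)
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                units = meta.get("units", "")
            except (json.JSONDecodeError, TypeError, AttributeError):
                pass

    return GridLayer(
        name=lname,
        units=units,
        values=values,
        transform=GridTransform(west, north, dx, dy),
        nodata=nodata,
        crs=crs,
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _write_ascii(layer: GridLayer, path: Path) -> None:
    if not math.isclose(layer.transform.dx, layer.transform.dy):
        raise ValueError("ESRI ASCII grids require square cells; use GeoTIFF")
    n_rows, n_cols = layer.shape
    west, south, _, _ = layer.transform.extent(layer.shape)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {west!r}\n")
        fh.write(f"yllcorner {south!r}\n")
        fh.write(f"cellsize {layer.transform.dx!r}\n")
        fh.write(f"NODATA_value {float(layer.nodata)!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: Path, name: str) -> GridLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="ascii") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise ValueError(f"{path}: ESRI ASCII header missing {required}")
    cell = header["cellsize"]
    # center-registered headers are converted to the corner convention
    if "xllcorner" in header:
        west = header["xllcorner"]
    elif "xllcenter" in header:
        west = header["xllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        south = header["yllcorner"]
    elif "yllcenter" in header:
        south = header["yllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: header missing yllcorner/yllcenter")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        values = values.reshape(n_rows, n_cols)
    north = south + n_rows * cell
    return GridLayer(
        name=name,
        units="",
        values=values,
        transform=GridTransform(west, north, cell, cell),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def read_layer(path: str | Path, name: str) -> GridLayer:
    """Read one raster layer from GeoTIFF or ESRI ASCII grid.

    The nodata sentinel comes from file metadata, defaulting to
    :data:`DEFAULT_NODATA` when absent.  A raster in a projected CRS raises
    :class:`CRSError`; no silent reprojection ever happens.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    if path.suffix.lower() in {".asc", ".agr", ".grd", ".txt"}:
        return _read_ascii(path, name)
    return _read_geotiff(path, name)


def write_layer(layer: GridLayer, path: str | Path) -> Path:
    """Write a layer to disk; GeoTIFF by default, ESRI ASCII for ``.asc``.

    ``read_layer(write_layer(x))`` reproduces values, transform and nodata
    exactly (ASCII floats are written with full round-trip precision).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in {".asc", ".agr", ".txt"}:
        _write_ascii(layer, path)
    else:
        _write_geotiff(layer, path)
    return path


# ---------------------------------------------------------------------------
# Occurrence CSV
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path, deduplicate: bool = False) -> OccurrenceSet:
    """Read species occurrences from a CSV with columns species, longitude, latitude.

    Extra columns are ignored.  Duplicate coordinates are retained unless
    ``deduplicate`` is set.  Out-of-range coordinates raise
    :class:`OccurrenceValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence CSV not found: {path}")
    points: list[tuple[float, float]] = []
    species = ""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"species", "longitude", "latitude"} <= set(reader.fieldnames):
            raise OccurrenceValidationError(
                f"{path}: header must contain species, longitude, latitude (found {reader.fieldnames})"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                lon = float(row["longitude"])
                lat = float(row["latitude"])
            except (TypeError, ValueError) as exc:
                raise OccurrenceValidationError(f"{path}: row {i}: non-numeric coordinate") from exc
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise OccurrenceValidationError(
                    f"{path}: row {i}: coordinate ({lon}, {lat}) out of geographic range"
                )
            species = species or row["species"]
            points.append((lon, lat))
    if not points:
        raise OccurrenceValidationError(f"{path}: no occurrence records")
    occ = OccurrenceSet(species=species, points=points, source=str(path))
    return occ.deduplicated() if deduplicate else occ


def write_occurrences(occurrences: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "longitude", "latitude"])
        for lon, lat in occurrences.points:
            writer.writerow([occurrences.species, repr(float(lon)), repr(float(lat))])
    return path


# ---------------------------------------------------------------------------
# Region GeoJSON
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> RegionSet:
    """Read named regions from a GeoJSON FeatureCollection.

    Each feature must carry a ``name`` property.  Invalid geometries are
    repaired with ``shapely.make_valid``; irreparable ones raise
    :class:`RegionValidationError` naming the feature.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"region GeoJSON not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise RegionValidationError(f"{path}: not a GeoJSON FeatureCollection")
    regions: list[tuple[str, BaseGeometry]] = []
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        name = props.get("name")
        if not name:
            raise RegionValidationError(f"{path}: feature {i} has no 'name' property")
        geom = shapely_shape(feature["geometry"])
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if geom.is_empty or not geom.is_valid:
            raise RegionValidationError(f"{path}: feature {name!r}: geometry invalid and not repairable")
        regions.append((str(name), geom))
    return RegionSet(regions=regions)


def write_regions(regions: RegionSet, path: str | Path) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": json.loads(shapely.to_geojson(geom)),
        }
        for name, geom in regions.regions
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
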