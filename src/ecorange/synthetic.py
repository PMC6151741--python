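"""Synthetic ecological landscapes with a known true suitability envelope.

The generator emulates the statistical structure a range-based suitability
analysis assumes: spatially coherent continuous factor fields (temperature
falls away from the equator; precipitation, humidity and radiation carry
their own smooth trends), a categorical soil mosaic of contiguous patches,
a partition of the map into named regions, and — crucially — a *truth
mask*: the set of cells genuinely inside a configured factor envelope and
soil-class set.  Occurrence points are then drawn from the truth mask, so
envelope recovery is a well-posed estimation problem with a known answer.

Each continuous field is::

    value(lon, lat) = base + lat_slope * |lat| + trend(lon, lat) + noise

with ``trend`` a sum of three seeded low-frequency sinusoids scaled to the
configured amplitude, and ``noise`` i.i.d. Gaussian per cell.  The soil
layer is a nearest-seed (Voronoi) mosaic over seeded random centres.  All
randomness flows from one seed through ``numpy.random.SeedSequence``, so a
fixed config reproduces the landscape bit-for-bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import GridLayer, GridTransform, LayerStack, OccurrenceSet, RegionSet

__all__ = [
    "FactorFieldSpec",
    "LandscapeConfig",
    "SyntheticLandscape",
    "generate_landscape",
    "sample_occurrences",
    "default_config",
    "FACTOR_UNITS",
]

#: The seven ecological factors of the analysis and their native units.
FACTOR_UNITS: dict[str, str] = {
    "annual_mean_temperature": "°C",
    "mean_temperature_coldest_quarter": "°C",
    "mean_temperature_warmest_quarter": "°C",
    "annual_precipitation": "mm",
    "annual_humidity": "%",
    "annual_radiation": "W·m⁻²",
    "soil": "category",
}


@dataclass(frozen=True)
class FactorFieldSpec:
    """Shape of one synthetic continuous factor field.

    base
        value at the equator before trend and noise (native units)
    lat_slope
        change per degree of absolute latitude (units/degree); negative for
        temperature-like factors
    trend_amplitude
        scale of the smooth low-frequency spatial trend (native units)
    noise_sd
        standard deviation of the per-cell independent noise (native units)
    """

    base: float
    lat_slope: float = 0.0
    trend_amplitude: float = 0.0
    noise_sd: float = 0.0


@dataclass
class LandscapeConfig:
    """Full specification of a synthetic landscape."""

    n_rows: int
    n_cols: int
    extent: tuple[float, float, float, float]  # (west, south, east, north)
    factor_specs: dict[str, FactorFieldSpec]
    n_soil_classes: int
    true_envelope: dict[str, tuple[float, float]]
    suitable_soils: frozenset[int]
    seed: int = 0
    n_soil_patches: int = 40
    region_grid: tuple[int, int] = (2, 3)  # (rows, cols) of rectangular regions

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        west, south, east, north = self.extent
        if not (west < east and south < north):
            raise ValueError("extent must satisfy west < east and south < north")
        if self.n_soil_classes < 2:
            raise ValueError("need at least two soil classes")
        self.suitable_soils = frozenset(int(s) for s in self.suitable_soils)
        if not self.suitable_soils:
            raise ValueError("suitable_soils must be non-empty")
        if set(self.true_envelope) - set(self.factor_specs):
            raise ValueError("true_envelope names a factor without a field spec")
        for name, (lo, hi) in self.true_envelope.items():
            if not lo < hi:
                raise ValueError(f"true envelope for {name!r} is empty ({lo} >= {hi})")

    @property
    def transform(self) -> GridTransform:
        west, south, east, north = self.extent
        return GridTransform(
            west=west,
            north=north,
            dx=(east - west) / self.n_cols,
            dy=(north - south) / self.n_rows,
        )

    # -- plain-dict (YAML/JSON) serialization ---------------------------
    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "extent": list(self.extent),
            "factor_specs": {
                k: {"base": s.base, "lat_slope": s.lat_slope,
                    "trend_amplitude": s.trend_amplitude, "noise_sd": s.noise_sd}
                for k, s in self.factor_specs.items()
            },
            "n_soil_classes": self.n_soil_classes,
            "true_envelope": {k: list(v) for k, v in self.true_envelope.items()},
            "suitable_soils": sorted(self.suitable_soils),
            "seed": self.seed,
            "n_soil_patches": self.n_soil_patches,
            "region_grid": list(self.region_grid),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandscapeConfig":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            extent=tuple(float(x) for x in d["extent"]),
            factor_specs={k: FactorFieldSpec(**v) for k, v in d["factor_specs"].items()},
            n_soil_classes=int(d["n_soil_classes"]),
            true_envelope={k: (float(v[0]), float(v[1])) for k, v in d["true_envelope"].items()},
            suitable_soils=frozenset(int(s) for s in d["suitable_soils"]),
            seed=int(d.get("seed", 0)),
            n_soil_patches=int(d.get("n_soil_patches", 40)),
            region_grid=tuple(int(x) for x in d.get("region_grid", (2, 3))),
        )


@dataclass
class SyntheticLandscape:
    """A generated landscape together with its ground truth."""

    stack: LayerStack
    regions: RegionSet
    truth_mask: GridLayer  # boolean values on the stack's grid
    config: LandscapeConfig

    def __post_init__(self) -> None:
        if not self.truth_mask.same_grid(self.stack.soil):
            raise ValueError("truth mask must share the stack's grid")


def default_config(seed: int = 0) -> LandscapeConfig:
    """Desk-scale analog of a global 1° analysis grid.

    360×180 cells at 1° resolution with the six continuous factors plus
    soil.  The true envelope is the observed factor range of *Panax
    japonicus* (annual mean temperature 2.6–22.3 °C, coldest quarter
    −7.0–14.3 °C, warmest quarter 10.7–28.8 °C, precipitation 539–2273 mm,
    humidity 49.4–75.5 %, radiation 118.7–157.6 W·m⁻²), which under the
    default fields becomes a noisy mid-latitude band — the kind of target a
    real envelope analysis estimates.
    """
    factor_specs = {
        "annual_mean_temperature": FactorFieldSpec(base=28.0, lat_slope=-0.65, trend_amplitude=3.0, noise_sd=1.5),
        "mean_temperature_coldest_quarter": FactorFieldSpec(base=22.0, lat_slope=-0.85, trend_amplitude=3.0, noise_sd=1.5),
        "mean_temperature_warmest_quarter": FactorFieldSpec(base=33.0, lat_slope=-0.45, trend_amplitude=3.0, noise_sd=1.5),
        "annual_precipitation": FactorFieldSpec(base=1600.0, lat_slope=-11.0, trend_amplitude=300.0, noise_sd=100.0),
        "annual_humidity": FactorFieldSpec(base=76.0, lat_slope=-0.30, trend_amplitude=5.0, noise_sd=2.0),
        "annual_radiation": FactorFieldSpec(base=160.0, lat_slope=-0.45, trend_amplitude=6.0, noise_sd=2.0),
    }
    true_envelope = {
        "annual_mean_temperature": (2.6, 22.3),
        "mean_temperature_coldest_quarter": (-7.0, 14.3),
        "mean_temperature_warmest_quarter": (10.7, 28.8),
        "annual_precipitation": (539.0, 2273.0),
        "annual_humidity": (49.4, 75.5),
        "annual_radiation": (118.7, 157.6),
    }
    return LandscapeConfig(
        n_rows=180,
        n_cols=360,
        extent=(-180.0, -90.0, 180.0, 90.0),
        factor_specs=factor_specs,
        n_soil_classes=8,
        true_envelope=true_envelope,
        suitable_soils=frozenset({1, 2, 3}),
        seed=seed,
    )


def _smooth_trend(rng: np.random.Generator, lon: np.ndarray, lat: np.ndarray,
                  amplitude: float) -> np.ndarray:
    """Sum of three seeded low-frequency sinusoids, scaled to ``amplitude``."""
    if amplitude == 0.0:
        return np.zeros_like(lon)
    out = np.zeros_like(lon)
    for _ in range(3):
        wavelength_lon = rng.uniform(90.0, 360.0)
        wavelength_lat = rng.uniform(60.0, 180.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += np.sin(2.0 * np.pi * (lon / wavelength_lon + lat / wavelength_lat) + phase)
    return amplitude * out / 3.0


def _soil_mosaic(rng: np.random.Generator, lon: np.ndarray, lat: np.ndarray,
                 n_classes: int, n_patches: int,
                 extent: tuple[float, float, float, float]) -> np.ndarray:
    """Nearest-seed-point (Voronoi) categorical mosaic; all classes present."""
    west, south, east, north = extent
    n_patches = max(n_patches, n_classes)
    centres_lon = rng.uniform(west, east, size=n_patches)
    centres_lat = rng.uniform(south, north, size=n_patches)
    # patch i -> class i mod n_classes guarantees every class appears
    patch_class = np.arange(n_patches) % n_classes
    d2 = (lon[..., None] - centres_lon) ** 2 + (lat[..., None] - centres_lat) ** 2
    nearest = np.argmin(d2, axis=-1)
    return patch_class[nearest].astype(np.int64)


def _rectangular_regions(config: LandscapeConfig) -> RegionSet:
    from shapely.geometry import box

    west, south, east, north = config.extent
    n_r, n_c = config.region_grid
    regions = []
    dlat = (north - south) / n_r
    dlon = (east - west) / n_c
    k = 0
    for i in range(n_r):
        for j in range(n_c):
            k += 1
            regions.append((
                f"R{k}",
                box(west + j * dlon, north - (i + 1) * dlat, west + (j + 1) * dlon, north - i * dlat),
            ))
    return RegionSet(regions=regions)


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate the full landscape: factor stack, soil, regions, truth mask.

    Deterministic: identical config (including seed) gives bit-identical
    output.  Raises ``ValueError`` if the configured envelope excludes the
    entire landscape (an empty truth mask would make every downstream test
    vacuous).
    """
    transform = config.transform
    rows = np.arange(config.n_rows)
    cols = np.arange(config.n_cols)
    lon_c, lat_c = transform.cell_center(*np.meshgrid(rows, cols, indexing="ij"))

    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(len(config.factor_specs) + 1)
    layers: dict[str, GridLayer] = {}
    for (name, spec), child in zip(config.factor_specs.items(), children):
        rng = np.random.default_rng(child)
        values = (
            spec.base
            + spec.lat_slope * np.abs(lat_c)
            + _smooth_trend(rng, lon_c, lat_c, spec.trend_amplitude)
            + (rng.normal(0.0, spec.noise_sd, size=lon_c.shape) if spec.noise_sd > 0 else 0.0)
        )
        layers[name] = GridLayer(
            name=name,
            units=FACTOR_UNITS.get(name, ""),
            values=values,
            transform=transform,
            nodata=-3.4e38,
        )

    soil_rng = np.random.default_rng(children[-1])
    soil_codes = _soil_mosaic(soil_rng, lon_c, lat_c, config.n_soil_classes,
                              config.n_soil_patches, config.extent)
    soil = GridLayer(name="soil", units="category", values=soil_codes,
                     transform=transform, nodata=-1)

    stack = LayerStack(layers=layers, soil=soil, factor_order=tuple(config.factor_specs))

    truth = np.ones(soil_codes.shape, dtype=bool)
    for name, (lo, hi) in config.true_envelope.items():
        v = layers[name].values
        truth &= (v >= lo) & (v <= hi)
    truth &= np.isin(soil_codes, sorted(config.suitable_soils))
    if not truth.any():
        raise ValueError("envelope excludes entire landscape: truth mask has no true cell")

    truth_layer = GridLayer(name="truth_mask", units="bool", values=truth.astype(np.uint8),
                            transform=transform, nodata=255)
    return SyntheticLandscape(stack=stack, regions=_rectangular_regions(config),
                              truth_mask=truth_layer, config=config)


def sample_occurrences(landscape: SyntheticLandscape, n: int, seed: int,
                       species: str = "Simulatus exemplaris") -> OccurrenceSet:
    """Draw ``n`` occurrence points uniformly over the true-suitability cells.

    A cell is chosen uniformly at random (with replacement) among cells
    where the truth mask is true, then the point is placed uniformly within
    that cell's half-open box, so every sampled point lies in truth-mask
    territory by construction.
    """
    if n < 1:
        raise ValueError("need n >= 1 occurrence points")
    truth = landscape.truth_mask.values.astype(bool)
    true_rows, true_cols = np.nonzero(truth)
    if true_rows.size == 0:
        raise ValueError("truth mask has no true cell")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, true_rows.size, size=n)
    t = landscape.stack.transform
    u = rng.random(n)
    w = rng.random(n)
    lon = t.west + (true_cols[idx] + u) * t.dx
    lat = t.north - (true_rows[idx] + w) * t.dy
    points = list(zip(lon.tolist(), lat.tolist()))
    return OccurrenceSet(species=species, points=points, source="synthetic")
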