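"""Shared fixtures: small synthetic landscapes and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ecorange import (FactorFieldSpec, GridLayer, GridTransform,
                      LandscapeConfig, LayerStack, generate_landscape)


def small_config(seed: int = 11, n_rows: int = 30, n_cols: int = 40,
                 noise: float = 1.0) -> LandscapeConfig:
    """Two-factor landscape on a ±30° window; envelope is a latitude band."""
    return LandscapeConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        extent=(-20.0, -30.0, 20.0, 30.0),
        factor_specs={
            "temp": FactorFieldSpec(base=25.0, lat_slope=-0.5, trend_amplitude=2.0, noise_sd=noise),
            "precip": FactorFieldSpec(base=1200.0, lat_slope=-8.0, trend_amplitude=100.0, noise_sd=40.0 * noise),
        },
        n_soil_classes=4,
        true_envelope={"temp": (5.0, 20.0), "precip": (800.0, 1250.0)},
        suitable_soils=frozenset({0, 1, 2}),
        seed=seed,
    )


@pytest.fixture
def landscape():
    return generate_landscape(small_config())


@pytest.fixture
def tiny_layer():
    """4x4 layer with one nodata cell, 1° cells anchored at (0°E, 4°N)."""
    values = np.arange(16, dtype=float).reshape(4, 4)
    values[1, 2] = -9999.0
    return GridLayer(name="temp", units="°C", values=values,
                     transform=GridTransform(west=0.0, north=4.0, dx=1.0, dy=1.0),
                     nodata=-9999.0)


# ---------------------------------------------------------------------------
# independent brute-force oracles (scalar python, no shared code paths)
# ---------------------------------------------------------------------------

def brute_force_distance_surface(stack: LayerStack, envelope) -> np.ndarray:
    """Cell-by-cell scalar re-evaluation of the full scoring chain."""
    n_rows, n_cols = stack.shape
    names = list(envelope.ranges)
    bounds = {}
    for name in names:
        layer = stack.layers[name]
        vals = [float(v) for v in layer.values.ravel() if v != layer.nodata]
        bounds[name] = (min(vals), max(vals))

    def norm(v, name):
        lo, hi = bounds[name]
        return (v - lo) / (hi - lo) * (100.0 - 0.0) + 0.0

    out = np.empty((n_rows, n_cols), dtype=float)
    for r in range(n_rows):
        for c in range(n_cols):
            total = 0.0
            nodata_hit = False
            for name in names:
                layer = stack.layers[name]
                v = float(layer.values[r, c])
                if v == layer.nodata:
                    nodata_hit = True
                    continue
                vp = norm(v, name)
                lo_p = norm(envelope.ranges[name][0], name)
                hi_p = norm(envelope.ranges[name][1], name)
                if lo_p <= vp <= hi_p:
                    d = 0.0
                else:
                    d = min(abs(vp - lo_p), abs(vp - hi_p))
                total += d * d
            out[r, c] = -1.0 if nodata_hit else math.sqrt(total)
    return out


def brute_force_truth(stack: LayerStack, true_envelope, suitable_soils) -> np.ndarray:
    """Direct cell-by-cell evaluation of the envelope definition."""
    n_rows, n_cols = stack.shape
    out = np.zeros((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            ok = int(stack.soil.values[r, c]) in suitable_soils
            for name, (lo, hi) in true_envelope.items():
                v = stack.layers[name].values[r, c]
                ok = ok and (lo <= v <= hi)
            out[r, c] = ok
    return out
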