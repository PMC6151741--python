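"""Range-based suitability scoring.

The scoring pipeline, per grid cell:

1. **Normalization.**  Each continuous layer A is linearly rescaled by its
   own valid-cell minimum and maximum,
   ``v' = (v - min_A) / (max_A - min_A) * 100``, so all factors share one
   dimensionless 0–100 scale and no factor dominates the distance by its
   units.
2. **Per-factor range distance.**  Against the (normalized) envelope
   ``[lo', hi']`` of a factor: 0 when the cell value lies inside the
   closed interval, otherwise the distance to the nearest bound,
   ``min(|v' - lo'|, |v' - hi'|)``.  Continuous in v', zero exactly on the
   envelope.
3. **Aggregation.**  The per-cell score is the Euclidean norm of the
   per-factor distances; it is 0 iff every factor is inside its range.
4. **Classification.**  The distance surface over [Min_d, Max_d] is cut
   into suitability classes; class 0 is reserved for distance exactly 0
   ("most similar ecological area").
5. **Soil intersection.**  The final suitable mask is class-0 AND
   soil class in the envelope's observed soil set.

Normalization statistics always come from the analysis stack's valid
cells, not from the occurrence sample; envelope bounds are pushed through
the same affine map, so the zero set of the score is exactly the native
envelope box.  Nothing is clamped: an envelope reused on a stack whose
values exceed the fitting stack's range still maps consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .envelope import FactorEnvelope
from .grids import GridLayer, GridMismatchError, LayerStack

__all__ = [
    "NormalizationParams",
    "NormalizedEnvelope",
    "ClassificationScheme",
    "SuitabilityResult",
    "DegenerateLayerError",
    "fit_normalization",
    "normalize_value",
    "range_distance",
    "score_cell",
    "score_surface",
    "classify_surface",
    "soil_suitability",
    "final_mask",
    "run_scoring",
]

NEW_MIN = 0.0
NEW_MAX = 100.0


class DegenerateLayerError(ValueError):
    """A layer with < 2 distinct valid values cannot be normalized."""


@dataclass(frozen=True)
class NormalizationParams:
    """Per-factor (min_A, max_A) on the native scale; targets are fixed 0–100."""

    bounds: dict[str, tuple[float, float]]
    new_min: float = NEW_MIN
    new_max: float = NEW_MAX

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise DegenerateLayerError(f"factor {name!r}: max_A ({hi}) must exceed min_A ({lo})")

    def to_dict(self) -> dict:
        return {"bounds": {k: list(v) for k, v in self.bounds.items()},
                "new_min": self.new_min, "new_max": self.new_max}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(bounds={k: (float(v[0]), float(v[1])) for k, v in d["bounds"].items()},
                   new_min=float(d.get("new_min", NEW_MIN)),
                   new_max=float(d.get("new_max", NEW_MAX)))


@dataclass(frozen=True)
class NormalizedEnvelope:
    """Envelope bounds pushed through the normalization map.

    ``ranges[name] = (lo', hi')`` on the 0–100 scale; the soil-class set is
    carried over unchanged (soil is categorical, never normalized).
    """

    species: str
    ranges: dict[str, tuple[float, float]]
    soil_classes: frozenset[int]


@dataclass(frozen=True)
class ClassificationScheme:
    """Left-open, right-closed distance bins over (0, Max_d], plus class 0 = {0}.

    ``thresholds`` are the strictly increasing upper edges of classes
    1..k; a distance exactly on a threshold goes to the lower (more
    suitable) class.  Class 0 is always reserved for distance exactly 0.
    """

    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("class thresholds must be strictly increasing")
        if t and t[0] <= 0:
            raise ValueError("the first threshold must be positive (class 0 is {0})")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need one label per class: len(labels) == len(thresholds) + 1")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1

    @classmethod
    def equal_width(cls, max_d: float, n_bins: int = 4,
                    labels: Sequence[str] | None = None) -> "ClassificationScheme":
        """Default scheme: class 0 = {0}; (0, max_d] in ``n_bins`` equal bins."""
        if max_d <= 0:
            # degenerate surface: everything is class 0
            return cls(thresholds=(), labels=("most similar",))
        edges = tuple(max_d * (i + 1) / n_bins for i in range(n_bins))
        if labels is None:
            base = ["most similar", "marginal", "moderately dissimilar", "dissimilar", "unsuitable"]
            labels = tuple(base[: n_bins + 1]) if n_bins + 1 <= len(base) else tuple(
                ["most similar"] + [f"class {i}" for i in range(1, n_bins + 1)])
        return cls(thresholds=edges, labels=tuple(labels))

    def to_dict(self) -> dict:
        return {"thresholds": list(self.thresholds), "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationScheme":
        return cls(thresholds=tuple(float(t) for t in d["thresholds"]),
                   labels=tuple(d["labels"]))


@dataclass
class SuitabilityResult:
    """Distance surface, its classification, and the soil/final masks."""

    distance: GridLayer
    classes: GridLayer
    soil_mask: GridLayer
    final: GridLayer
    envelope: FactorEnvelope
    normalization: NormalizationParams
    scheme: ClassificationScheme

    def final_bool(self) -> np.ndarray:
        return self.final.values.astype(bool) & (self.final.values != self.final.nodata)


# ---------------------------------------------------------------------------
# scalar / small-vector primitives
# ---------------------------------------------------------------------------

def fit_normalization(stack: LayerStack) -> NormalizationParams:
    """Per-factor min/max over each layer's valid (non-nodata) cells."""
    bounds: dict[str, tuple[float, float]] = {}
    for name in stack.factor_order:
        lo, hi = stack.layers[name].min_max()
        if not hi > lo:
            raise DegenerateLayerError(f"factor {name!r} is constant over valid cells; cannot normalize")
        bounds[name] = (lo, hi)
    return NormalizationParams(bounds=bounds)


def normalize_value(v, factor: str, params: NormalizationParams):
    """Linear min–max rescale of native value(s) to the 0–100 scale.

    The layer minimum maps to exactly 0 and the maximum to exactly 100;
    values outside [min_A, max_A] map outside [0, 100] without clamping.
    """
    lo, hi = params.bounds[factor]
    return (np.asarray(v, dtype=float) - lo) / (hi - lo) * (params.new_max - params.new_min) + params.new_min


def normalize_envelope(envelope: FactorEnvelope, params: NormalizationParams) -> NormalizedEnvelope:
    missing = [f for f in envelope.ranges if f not in params.bounds]
    if missing:
        raise KeyError(f"normalization lacks factors: {missing}")
    ranges = {
        name: (float(normalize_value(lo, name, params)), float(normalize_value(hi, name, params)))
        for name, (lo, hi) in envelope.ranges.items()
    }
    return NormalizedEnvelope(species=envelope.species, ranges=ranges,
                              soil_classes=envelope.soil_classes)


def range_distance(v, lo: float, hi: float):
    """Distance from value(s) to the closed interval [lo, hi].

    Exactly 0 on the interval; outside, the distance to the nearer bound
    ``min(|v - lo|, |v - hi|)``.  Continuous everywhere.
    """
    if lo > hi:
        raise ValueError(f"empty range: lo {lo} > hi {hi}")
    v = np.asarray(v, dtype=float)
    inside = (v >= lo) & (v <= hi)
    d = np.minimum(np.abs(v - lo), np.abs(v - hi))
    out = np.where(inside, 0.0, d)
    return out if out.ndim else float(out)


def score_cell(values: Sequence[float], ranges: Sequence[tuple[float, float]]) -> float:
    """Euclidean aggregate of per-factor range distances for one cell.

    ``sqrt(sum_i dist(v_i, [lo_i, hi_i])^2)`` — zero iff every factor lies
    inside its range; reduces to the single-factor distance when only one
    factor is outside.
    """
    if len(values) != len(ranges):
        raise ValueError("one value per factor required")
    total = 0.0
    for v, (lo, hi) in zip(values, ranges):
        d = range_distance(v, lo, hi)
        total += d * d
    return float(np.sqrt(total))


# ---------------------------------------------------------------------------
# surface operations
# ---------------------------------------------------------------------------

def score_surface(stack: LayerStack, envelope: FactorEnvelope,
                  params: NormalizationParams | None = None) -> GridLayer:
    """Per-cell aggregate range distance over the whole grid.

    Every cell and both envelope bounds go through the *same* linear
    normalization, then per-factor distances combine as a Euclidean norm.
    A cell that is nodata in any factor is nodata in the output.
    """
    if params is None:
        params = fit_normalization(stack)
    missing = [f for f in envelope.ranges if f not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks envelope factors: {missing}")
    norm_env = normalize_envelope(envelope, params)

    sq_sum = np.zeros(stack.shape, dtype=float)
    any_nodata = np.zeros(stack.shape, dtype=bool)
    for name in envelope.ranges:
        layer = stack.layers[name]
        lo_p, hi_p = norm_env.ranges[name]
        vp = normalize_value(layer.values, name, params)
        d = range_distance(vp, lo_p, hi_p)
        sq_sum += np.where(layer.valid, d * d, 0.0)
        any_nodata |= ~layer.valid

    nodata = -1.0
    dist = np.sqrt(sq_sum)
    dist = np.where(any_nodata, nodata, dist)
    return GridLayer(name="distance", units="normalized", values=dist,
                     transform=stack.transform, nodata=nodata)


def classify_surface(distance: GridLayer, scheme: ClassificationScheme) -> GridLayer:
    """Assign each valid cell its suitability class.

    Class 0 is exactly the zero set of the distance; positive distances go
    to left-open/right-closed bins, ties on a threshold to the lower (more
    suitable) class.
    """
    v = distance.values
    valid = distance.valid
    cls = np.zeros(v.shape, dtype=np.int64)
    if scheme.thresholds:
        # searchsorted 'left': d == threshold stays in the lower class
        pos = np.searchsorted(np.asarray(scheme.thresholds), v, side="left")
        cls = np.where(v > 0, pos + 1, 0)
        cls = np.minimum(cls, scheme.n_classes - 1)
    nodata = -1
    out = np.where(valid, cls, nodata)
    return GridLayer(name="suitability_class", units="class", values=out,
                     transform=distance.transform, nodata=nodata)


def soil_suitability(soil: GridLayer, soil_classes: Iterable[int]) -> GridLayer:
    """Boolean layer: cell soil code is one of the observed suitable classes."""
    codes = sorted(int(c) for c in soil_classes)
    if not codes:
        raise ValueError("soil_classes must be non-empty")
    valid = soil.valid
    mask = np.isin(soil.values, codes) & valid
    nodata = 255
    out = np.where(valid, mask.astype(np.uint8), np.uint8(nodata))
    return GridLayer(name="soil_mask", units="bool", values=out,
                     transform=soil.transform, nodata=nodata)


def final_mask(classes: GridLayer, soil_mask: GridLayer,
               suitable_classes: Iterable[int] = (0,)) -> GridLayer:
    """Intersect climatic suitability classes with the soil mask."""
    if not classes.same_grid(soil_mask):
        raise GridMismatchError("class layer and soil mask are on different grids")
    wanted = sorted(int(c) for c in suitable_classes)
    valid = classes.valid & soil_mask.valid
    climatic = np.isin(classes.values, wanted) if wanted else np.zeros(classes.shape, dtype=bool)
    mask = climatic & (soil_mask.values == 1) & valid
    nodata = 255
    out = np.where(valid, mask.astype(np.uint8), np.uint8(nodata))
    return GridLayer(name="final_mask", units="bool", values=out,
                     transform=classes.transform, nodata=nodata)


def run_scoring(stack: LayerStack, envelope: FactorEnvelope,
                scheme: ClassificationScheme | None = None,
                suitable_classes: Iterable[int] = (0,)) -> SuitabilityResult:
    """Normalize, score, classify and intersect with soil in one call."""
    params = fit_normalization(stack)
    dist = score_surface(stack, envelope, params)
    if scheme is None:
        valid_d = dist.valid_values()
        max_d = float(valid_d.max()) if valid_d.size else 0.0
        scheme = ClassificationScheme.equal_width(max_d)
    classes = classify_surface(dist, scheme)
    soil = soil_suitability(stack.soil, envelope.soil_classes)
    final = final_mask(classes, soil, suitable_classes)
    return SuitabilityResult(distance=dist, classes=classes, soil_mask=soil,
                             final=final, envelope=envelope,
                             normalization=params, scheme=scheme)
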