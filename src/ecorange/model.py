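"""Model/Results front end for the range-based suitability analysis.

:class:`RangeSuitabilityModel` is constructed from a factor stack and a
set of occurrence points (plus, optionally, region polygons); ``fit()``
estimates the environmental envelope and normalization, scores the whole
grid, and returns a :class:`RangeSuitabilityResults` carrying the fitted
envelope, the suitability surfaces, diagnostics, and a ``summary()``
table, in the style of the classic statistical-modelling packages::

    model = RangeSuitabilityModel(stack, occurrences, regions=regions)
    res = model.fit()
    print(res.summary())
    res.region_summary.table          # ranked areas in km²
    res.predict(other_stack)          # reuse the envelope on a new grid
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import (FactorEnvelope, FactorSample, FactorSummary,
                       extract_values, fit_envelope, summarize_factors)
from .grids import LayerStack, OccurrenceSet, RegionSet
from .regions import RegionSummary, row_areas, summarize_by_region
from .suitability import (ClassificationScheme, SuitabilityResult,
                          fit_normalization, run_scoring, score_surface)

__all__ = ["RangeSuitabilityModel", "RangeSuitabilityResults"]


class RangeSuitabilityModel:
    """Environmental-envelope suitability model for one species.

    Parameters
    ----------
    stack
        Continuous ecological factors plus the categorical soil layer,
        all on one geographic grid.
    occurrences
        Presence coordinates of the species whose envelope is estimated.
    regions
        Optional named polygons for the zonal area summary.
    """

    def __init__(self, stack: LayerStack, occurrences: OccurrenceSet,
                 regions: RegionSet | None = None) -> None:
        self.stack = stack
        self.occurrences = occurrences
        self.regions = regions

    @classmethod
    def from_landscape(cls, landscape, occurrences: OccurrenceSet) -> "RangeSuitabilityModel":
        """Build from a synthetic landscape (keeps its regions)."""
        return cls(landscape.stack, occurrences, regions=landscape.regions)

    def fit(self, trim_percentile: float | None = None,
            scheme: ClassificationScheme | None = None,
            suitable_classes: tuple[int, ...] = (0,)) -> "RangeSuitabilityResults":
        """Estimate the envelope and score the training grid.

        ``trim_percentile=p`` replaces the raw min/max envelope with the
        [p, 100−p] percentile envelope per factor (default: off — the
        envelope is the full observed range).
        """
        sample = extract_values(self.stack, self.occurrences)
        envelope = fit_envelope(sample, trim_percentile=trim_percentile)
        scoring = run_scoring(self.stack, envelope, scheme=scheme,
                              suitable_classes=suitable_classes)
        return RangeSuitabilityResults(model=self, sample=sample,
                                       envelope=envelope, scoring=scoring)


@dataclass
class RangeSuitabilityResults:
    """Fitted envelope, suitability surfaces and diagnostics."""

    model: RangeSuitabilityModel
    sample: FactorSample
    envelope: FactorEnvelope
    scoring: SuitabilityResult

    _region_summary: RegionSummary | None = field(default=None, repr=False)

    # -- fitted quantities ----------------------------------------------
    @property
    def normalization(self):
        return self.scoring.normalization

    @property
    def factor_summary(self) -> FactorSummary:
        """Five-number summary of the factors at valid occurrence points."""
        return summarize_factors(self.sample)

    @property
    def region_summary(self) -> RegionSummary:
        if self.model.regions is None:
            raise ValueError("model was built without regions")
        if self._region_summary is None:
            self._region_summary = summarize_by_region(self.scoring.final, self.model.regions)
        return self._region_summary

    def predict(self, stack: LayerStack | None = None) -> SuitabilityResult:
        """Score a (new) stack with the fitted envelope.

        Normalization statistics are refitted on the target stack, mirroring
        the training pipeline; with ``stack=None`` this recomputes the
        training-surface result.
        """
        from .suitability import run_scoring
        target = stack if stack is not None else self.model.stack
        return run_scoring(target, self.envelope, scheme=self.scoring.scheme)

    # -- diagnostics -----------------------------------------------------
    def suitable_cell_count(self) -> int:
        return int(self.scoring.final_bool().sum())

    def suitable_area_km2(self) -> float:
        mask = self.scoring.final_bool()
        areas = row_areas(self.scoring.final)
        return float((mask * areas[:, None]).sum())

    def training_containment(self) -> float:
        """Fraction of valid training cells inside the final mask (expected 1.0)."""
        rows = self.sample.valid_rows()
        t = self.model.stack.transform
        r, c = t.cell_of(rows["longitude"].to_numpy(), rows["latitude"].to_numpy())
        return float(self.scoring.final_bool()[r, c].mean())

    def envelope_frame(self) -> pd.DataFrame:
        """Envelope ranges with their normalized images, one row per factor."""
        from .suitability import normalize_envelope
        norm = normalize_envelope(self.envelope, self.normalization)
        rows = []
        for name, (lo, hi) in self.envelope.ranges.items():
            lo_p, hi_p = norm.ranges[name]
            units = self.model.stack.layers[name].units
            rows.append((name, units, lo, hi, lo_p, hi_p))
        return pd.DataFrame(rows, columns=["factor", "units", "min", "max",
                                           "min_norm", "max_norm"])

    def summary(self) -> str:
        """Plain-text summary table of the fitted model."""
        env = self.envelope_frame()
        lines = [
            "Range-based ecological suitability model",
            "=" * 72,
            f"species:              {self.envelope.species}",
            f"occurrence points:    {self.sample.n_points} ({self.sample.n_valid} valid)",
            f"grid:                 {self.model.stack.shape[0]} x {self.model.stack.shape[1]} cells",
            f"soil classes:         {sorted(self.envelope.soil_classes)}",
            f"suitable cells:       {self.suitable_cell_count()}",
            f"suitable area:        {self.suitable_area_km2():,.2f} km²",
            f"training containment: {self.training_containment():.1%}",
            "-" * 72,
            "fitted factor envelope (native units and 0-100 normalized scale):",
        ]
        with pd.option_context("display.width", 100, "display.max_columns", 20):
            lines.append(env.to_string(index=False,
                                       float_format=lambda x: f"{x:.2f}"))
        if self.model.regions is not None:
            lines.append("-" * 72)
            lines.append("top regions by suitable area (km²):")
            top = self.region_summary.table.head(8)
            lines.append(top.to_string(index=False,
                                       float_format=lambda x: f"{x:,.2f}"))
        lines.append("=" * 72)
        return "\n".join(lines)
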