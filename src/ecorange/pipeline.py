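"""Reproducible end-to-end pipeline with serialized stage artifacts.

A :class:`PipelineConfig` runs in exactly one of two modes:

* **synthetic** — a landscape is generated from a
  :class:`~ecorange.synthetic.LandscapeConfig` and occurrences are sampled
  from its truth mask;
* **files** — rasters, occurrences and regions are read from user paths.

``run_pipeline`` executes generate/ingest → extract → fit envelope →
normalize → score → classify → soil intersect → final mask → regional
summary, writing every intermediate artifact plus a provenance manifest.
All randomness flows from the single top-level seed, split per stage, so
identical config+seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .envelope import extract_values, fit_envelope, summarize_factors
from .grids import (GridLayer, LayerStack, OccurrenceSet, RegionSet,
                    read_layer, read_occurrences, read_regions,
                    write_layer, write_occurrences, write_regions)
from .model import RangeSuitabilityModel
from .regions import plot_rank, summarize_by_region
from .suitability import ClassificationScheme
from .synthetic import (LandscapeConfig, default_config, generate_landscape,
                        sample_occurrences)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "write_stack",
    "read_stack",
    "run_pipeline",
]

log = logging.getLogger("ecorange")


class ConfigError(ValueError):
    """Invalid or contradictory pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    landscape: LandscapeConfig | None = None
    n_occurrences: int = 500
    layer_paths: dict[str, str] | None = None
    soil_path: str | None = None
    occurrence_path: str | None = None
    region_path: str | None = None
    trim_percentile: float | None = None
    scheme: ClassificationScheme | None = None
    suitable_classes: tuple[int, ...] = (0,)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        synthetic = self.landscape is not None
        files = any(p is not None for p in
                    (self.layer_paths, self.soil_path, self.occurrence_path))
        if synthetic and files:
            raise ConfigError("config mixes synthetic mode with real-data paths; choose one")
        if not synthetic and not files:
            raise ConfigError("config specifies neither synthetic mode nor data paths")
        if files and not (self.layer_paths and self.soil_path and self.occurrence_path):
            raise ConfigError("file mode needs layer paths, a soil path and an occurrence CSV")

    @property
    def synthetic(self) -> bool:
        return self.landscape is not None

    def to_dict(self) -> dict:
        d: dict = {
            "n_occurrences": self.n_occurrences,
            "trim_percentile": self.trim_percentile,
            "suitable_classes": list(self.suitable_classes),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        if self.landscape is not None:
            d["mode"] = "synthetic"
            d["landscape"] = self.landscape.to_dict()
        else:
            d["mode"] = "files"
            d["layers"] = self.layer_paths
            d["soil"] = self.soil_path
            d["occurrences"] = self.occurrence_path
            d["regions"] = self.region_path
        if self.scheme is not None:
            d["scheme"] = self.scheme.to_dict()
        return d


def load_config(source: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML; the literal name ``demo`` gives
    the built-in synthetic demo configuration."""
    if str(source) == "demo":
        return PipelineConfig(landscape=default_config())
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}

    mode = doc.get("mode", "synthetic" if "landscape" in doc else "files")
    landscape = None
    if "landscape" in doc:
        landscape = LandscapeConfig.from_dict(doc["landscape"])
    elif mode == "synthetic":
        landscape = default_config(seed=int(doc.get("seed", 0)))
    scheme = ClassificationScheme.from_dict(doc["scheme"]) if "scheme" in doc else None
    return PipelineConfig(
        landscape=landscape,
        n_occurrences=int(doc.get("n_occurrences", 500)),
        layer_paths=doc.get("layers"),
        soil_path=doc.get("soil"),
        occurrence_path=doc.get("occurrences"),
        region_path=doc.get("regions"),
        trim_percentile=doc.get("trim_percentile"),
        scheme=scheme,
        suitable_classes=tuple(doc.get("suitable_classes", (0,))),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )


# ---------------------------------------------------------------------------
# stack serialization (a directory of GeoTIFFs plus a small manifest)
# ---------------------------------------------------------------------------

def write_stack(stack: LayerStack, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in stack.factor_order:
        write_layer(stack.layers[name], outdir / f"{name}.tif")
    write_layer(stack.soil, outdir / "soil.tif")
    with open(outdir / "stack.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"factor_order": list(stack.factor_order)}, fh)
    return outdir


def read_stack(indir: str | Path) -> LayerStack:
    indir = Path(indir)
    manifest = indir / "stack.yaml"
    if not manifest.exists():
        raise FileNotFoundError(f"no stack.yaml in {indir}")
    with open(manifest, encoding="utf-8") as fh:
        order = yaml.safe_load(fh)["factor_order"]
    layers = {name: read_layer(indir / f"{name}.tif", name) for name in order}
    soil = read_layer(indir / "soil.tif", "soil")
    return LayerStack(layers=layers, soil=soil, factor_order=tuple(order))


def _stage(manifest: dict, name: str):
    """Context manager recording stage duration/status into the manifest."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            status = "ok" if exc is None else f"failed: {exc}"
            manifest["stages"].append({
                "stage": name,
                "status": status,
                "seconds": round(time.perf_counter() - self.t0, 3),
            })
            if exc is None:
                log.info("stage %s: done", name)
            else:
                log.error("stage %s: %s", name, exc)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write every artifact to ``outdir``.

    Returns the output directory.  Stage failures propagate (with the
    stage name recorded in the manifest, which is written even on error).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")

    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"ecorange": __version__, "numpy": np.__version__},
        "stages": [],
        "artifacts": [],
    }

    def emit(path: Path) -> Path:
        manifest["artifacts"].append(path.name)
        return path

    try:
        if config.synthetic:
            with _stage(manifest, "generate"):
                landscape = generate_landscape(config.landscape)
                stack = landscape.stack
                regions = landscape.regions
                write_stack(stack, outdir / "stack")
                emit(write_layer(landscape.truth_mask, outdir / "truth_mask.tif"))
                emit(write_regions(regions, outdir / "regions.geojson"))
            with _stage(manifest, "sample_occurrences"):
                # the pipeline seed drives occurrence sampling; the landscape
                # carries its own seed, so 'simulate' + 'run --resume'
                # reproduces the one-shot run exactly
                occurrences = sample_occurrences(landscape, config.n_occurrences, config.seed)
                emit(write_occurrences(occurrences, outdir / "occurrences.csv"))
        else:
            with _stage(manifest, "ingest"):
                layers = {name: read_layer(p, name) for name, p in config.layer_paths.items()}
                soil = read_layer(config.soil_path, "soil")
                stack = LayerStack(layers=layers, soil=soil,
                                   factor_order=tuple(config.layer_paths))
                occurrences = read_occurrences(config.occurrence_path)
                regions = read_regions(config.region_path) if config.region_path else None

        with _stage(manifest, "fit"):
            model = RangeSuitabilityModel(stack, occurrences, regions=regions)
            res = model.fit(trim_percentile=config.trim_percentile,
                            scheme=config.scheme,
                            suitable_classes=config.suitable_classes)
            emit(res.sample.to_csv(outdir / "sample.csv"))
            emit(res.envelope.to_csv(outdir / "envelope.csv"))

        with _stage(manifest, "score"):
            emit(write_layer(res.scoring.distance, outdir / "distance.tif"))
            emit(write_layer(res.scoring.classes, outdir / "classes.tif"))
            emit(write_layer(res.scoring.soil_mask, outdir / "soil_mask.tif"))
            emit(write_layer(res.scoring.final, outdir / "final_mask.tif"))
            provenance = {
                "envelope": res.envelope.to_dict(),
                "normalization": res.normalization.to_dict(),
                "scheme": res.scoring.scheme.to_dict(),
                "suitable_classes": list(config.suitable_classes),
            }
            with open(outdir / "provenance.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(provenance, fh)
            manifest["artifacts"].append("provenance.yaml")

        if regions is not None:
            with _stage(manifest, "summarize"):
                summary = res.region_summary
                emit(summary.to_csv(outdir / "region_summary.csv"))
                emit(plot_rank(summary, outdir / "region_rank.png",
                               title=f"Suitable area by region — {res.envelope.species}"))

        with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(res.summary() + "\n")
        manifest["artifacts"].append("summary.txt")
    finally:
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return outdir
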