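"""Configuration-driven orchestration of the two-step mapping workflow.

Stages run in dependency order:

    simulate -> gi -> mirad -> synergy -> validate -> trend

``simulate`` draws a synthetic scene per year; ``gi`` smooths the GI
stack and composites the annual peak; ``mirad`` downscales per-region
statistics on the peak-GI field (the provisional map); ``synergy`` fuses
the weight-ordered product stack — by default substituting the
provisional map at rank 3, mirroring the operational weight order — on
the agreement-score field; ``validate`` scores both maps against the
scene's reference samples; ``trend`` fits per-coarse-cell fraction
trends across the years.  Every run writes a manifest (config echo,
output checksums, per-region allocation summaries).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy_assessment import confusion, metrics
from .area_allocator import allocate_map
from .gi_preprocess import annual_peak, smooth_stack
from .grid_model import Grid, write_grid
from .synergy_fusion import Product, ProductStack, build_score_table, fuse
from .synthetic import SynthConfig, generate_scene
from .trend_analysis import trend_map

log = logging.getLogger("irrimap")

ALL_STAGES = ("simulate", "gi", "mirad", "synergy", "validate", "trend")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    out_dir: str = "irrimap_run"
    years: list[int] = field(default_factory=lambda: [2010])
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    stats_path: Optional[str] = None  # required for mirad without simulate
    sg_window: int = 7
    sg_polyorder: int = 2
    quantize_decimals: Optional[int] = 3
    score_mode: str = "paper5"
    include_mirad_in_stack: bool = True
    n_samples: int = 1000
    trend_factor: int = 12
    p_threshold: float = 0.05
    min_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if not self.years:
            raise ConfigError("no years configured")
        if "simulate" not in self.stages:
            if {"gi", "mirad", "synergy"} & set(self.stages):
                raise ConfigError("gi/mirad/synergy without simulate require input "
                                  "rasters; provide them or enable simulate")
            if "mirad" in self.stages and not self.stats_path:
                raise ConfigError("mirad stage requires a statistics path")
        if "trend" in self.stages and len(self.years) < 3:
            raise ConfigError("trend stage needs at least 3 years")

    def synth_config(self, year: int) -> SynthConfig:
        return SynthConfig(seed=self.seed, year=year, **self.synth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_traces(traces, path: Path) -> None:
    rows = [
        {"region_id": t.region_id, "threshold": t.threshold,
         "target_ha": t.target_area, "achieved_ha": t.achieved_area,
         "gap_ha": t.achieved_area - t.target_area,
         "n_pixels": t.n_pixels, "n_selected": t.n_selected}
        for t in traces.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages_completed": [],
        "outputs": {},
        "summaries": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    scenes: dict[int, object] = {}
    peak_by_year: dict[int, Grid] = {}
    mirad_by_year: dict[int, Grid] = {}
    synergy_by_year: dict[int, Grid] = {}

    for year in cfg.years:
        if "simulate" in cfg.stages:
            scene = generate_scene(cfg.synth_config(year), year, n_samples=cfg.n_samples)
            scenes[year] = scene
            write_grid(scene.regions, out / f"regions_{year}.tif")
            write_grid(scene.cropland.copy_with(scene.cropland.values.astype(np.uint8)),
                       out / f"cropland_{year}.tif")
            write_grid(scene.truth, out / f"truth_{year}.tif")
            scene.stats.to_frame().to_csv(out / f"stats_{year}.csv", index=False)
            scene.samples.to_csv(out / f"samples_{year}.csv", index=False)
            for name, grid, _rank in scene.products:
                write_grid(grid, out / f"product_{name}_{year}.tif")
            for stem in (f"regions_{year}.tif", f"cropland_{year}.tif",
                         f"truth_{year}.tif"):
                record(stem, out / stem)
            log.info("simulate %s: %d cropland px, %d irrigated px", year,
                     int(scene.cropland.values.sum()), int(scene.truth.values.sum()))

        if "gi" in cfg.stages:
            scene = scenes[year]
            smoothed = smooth_stack(scene.gi_stack, cfg.sg_window, cfg.sg_polyorder)
            peak = annual_peak(smoothed)
            peak_by_year[year] = peak
            write_grid(peak, out / f"peakgi_{year}.tif")
            record(f"peakgi_{year}.tif", out / f"peakgi_{year}.tif")

        if "mirad" in cfg.stages:
            scene = scenes[year]
            targets = scene.stats.targets_for_year(year)
            mirad, traces = allocate_map(peak_by_year[year], scene.cropland,
                                         scene.regions, targets,
                                         scene.config.pixel_area_ha,
                                         quantize_decimals=cfg.quantize_decimals)
            mirad_by_year[year] = mirad
            write_grid(mirad, out / f"mirad_{year}.tif")
            record(f"mirad_{year}.tif", out / f"mirad_{year}.tif")
            _write_traces(traces, out / f"mirad_trace_{year}.csv")
            log.info("mirad %s: %d px allocated over %d regions", year,
                     int(mirad.values.sum()), len(traces))

        if "synergy" in cfg.stages:
            scene = scenes[year]
            prods = [Product(name, grid, rank) for name, grid, rank in scene.products]
            if cfg.include_mirad_in_stack and year in mirad_by_year:
                # provisional map takes the middle weight rank, as in the
                # operational weight order
                mid = len(prods) // 2
                prods[mid] = Product("MIRAD", mirad_by_year[year], prods[mid].rank)
            table = build_score_table(len(prods), cfg.score_mode)
            targets = scene.stats.targets_for_year(year)
            fused, traces = fuse(ProductStack(prods), scene.cropland, scene.regions,
                                 targets, scene.config.pixel_area_ha, table)
            synergy_by_year[year] = fused
            write_grid(fused, out / f"synergy_{year}.tif")
            record(f"synergy_{year}.tif", out / f"synergy_{year}.tif")
            _write_traces(traces, out / f"synergy_trace_{year}.csv")

        if "validate" in cfg.stages:
            scene = scenes[year]
            report = {}
            for name, grid in (("mirad", mirad_by_year.get(year)),
                               ("synergy", synergy_by_year.get(year))):
                if grid is None:
                    continue
                m = metrics(confusion(grid, scene.samples)).rounded()
                report[name] = m.to_dict()
                log.info("validate %s/%s: OA=%.3f kappa=%.3f", year, name,
                         m.overall_accuracy, m.kappa)
            path = out / f"metrics_{year}.json"
            path.write_text(json.dumps(report, indent=2))
            record(f"metrics_{year}.json", path)
            manifest["summaries"][f"metrics_{year}"] = report

    if "trend" in cfg.stages:
        maps = synergy_by_year or mirad_by_year
        tg = trend_map(maps, cfg.trend_factor, cfg.p_threshold, cfg.min_fraction)
        df = pd.DataFrame({
            "slope_per_year": tg.slope.ravel(),
            "p_value": tg.p_value.ravel(),
            "max_fraction": tg.max_fraction.ravel(),
            "masked": tg.masked.ravel(),
        })
        path = out / "trend_summary.csv"
        df.to_csv(path, index=False)
        record("trend_summary.csv", path)
        manifest["summaries"]["trend"] = {
            "n_cells": int(tg.masked.size),
            "n_unmasked": int((~tg.masked).sum()),
        }

    manifest["stages_completed"] = [s for s in ALL_STAGES if s in cfg.stages]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
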