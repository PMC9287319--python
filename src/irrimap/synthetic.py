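"""Seeded synthetic landscapes with the statistical structure the pipeline assumes.

The generator stands in for the study's real inputs (8-day reflectance
composites, a national cropland mask, county statistics, and existing
irrigation products).  It emulates three empirical regularities the
method relies on: (a) irrigated pixels reach a higher annual peak
greenness index than rainfed pixels within the same region; (b) reported
per-region irrigated areas equal the true area up to a multiplicative
bias (reported statistics tend to underestimate); (c) existing products
are the truth corrupted by per-product omission and commission rates.

Defaults describe the standard test landscape: a 200x200 grid of 500-m
pixels (25 ha) split into 10 contiguous regions, half cropland, 40% of
cropland irrigated, GI peaks 6.0 (irrigated) vs 4.0 (rainfed) over a 1.0
baseline with noise sd 0.5 — a 4-sigma class separation — and a Gaussian
season peaking at composite 23 of 46.

Randomness contract: one root seed; every operation draws from its own
child stream (seed, stream-id[, year]) so changing one generator never
perturbs the others, and everything is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .gi_preprocess import PERIODS_PER_YEAR, GITimeStack
from .grid_model import Grid, GridTransform
from .stats_prep import StatRecord, StatTable

__all__ = ["SynthConfig", "SyntheticScene", "generate_landscape",
           "generate_gi_stack", "generate_statistics", "degrade_product",
           "draw_samples", "generate_scene"]

# stream ids for derived RNG streams
_S_REGIONS, _S_CROP, _S_IRR, _S_GI, _S_PRODUCT, _S_SAMPLE = range(6)

DEFAULT_PRODUCT_ERRORS = (
    (0.05, 0.03),  # product A: most trusted
    (0.08, 0.05),
    (0.12, 0.08),
    (0.18, 0.12),
    (0.25, 0.15),  # product E: least trusted
)


@dataclass
class SynthConfig:
    shape: tuple[int, int] = (200, 200)
    n_regions: int = 10
    cropland_fraction: float = 0.5
    irrigated_fraction: float = 0.4  # of cropland
    gi_peak_irrigated: float = 6.0
    gi_peak_rainfed: float = 4.0
    gi_base: float = 1.0
    gi_noise_sd: float = 0.5
    peak_composite: int = 23  # 0-based index into the 46 periods
    season_width: float = 5.0  # composites (Gaussian sigma)
    clump_sigma: float = 3.0  # pixels; spatial coherence of masks
    stats_bias: float = 1.0  # reported = bias * true area
    product_errors: tuple = DEFAULT_PRODUCT_ERRORS
    pixel_area_ha: float = 25.0  # 500-m pixel
    pixel_size: float = 500.0  # projected units
    year: int = 2010
    seed: int = 0

    def __post_init__(self):
        for name in ("cropland_fraction", "irrigated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.gi_peak_irrigated <= self.gi_peak_rainfed:
            raise ValueError("irrigated peak GI must exceed the rainfed peak")
        if not 0 <= self.peak_composite < PERIODS_PER_YEAR:
            raise ValueError("peak_composite outside the composite year")
        if self.season_width <= 0:
            raise ValueError("season_width must be positive")
        for om, com in self.product_errors:
            if not (0 <= om <= 1 and 0 <= com <= 1):
                raise ValueError("product error rates must lie in [0, 1]")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, 0.0, self.pixel_size, -self.pixel_size)


@dataclass
class SyntheticScene:
    """All co-registered layers of one synthetic study year."""

    config: SynthConfig
    regions: Grid
    cropland: Grid
    truth: Grid
    gi_stack: GITimeStack
    stats: StatTable
    products: list = field(default_factory=list)  # (name, Grid, rank)
    samples: Optional[pd.DataFrame] = None


def _rng(seed: int, stream: int, year: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, year)))


def _clumped_field(shape, sigma, rng) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    return gaussian_filter(field_, sigma) if sigma > 0 else field_


def _top_k_mask(values: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting the k largest ``values`` among ``candidates``."""
    out = np.zeros(values.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.flatnonzero(candidates)
    order = np.argsort(values.flat[idx])[::-1]
    out.flat[idx[order[:k]]] = True
    return out


def generate_landscape(cfg: SynthConfig, year: Optional[int] = None):
    """(RegionLabelGrid, CroplandMask, truth BinaryIrrigationMap).

    Regions are a Voronoi partition of seeded points (labels 1..n);
    cropland and irrigated truth are spatially clumped masks hitting the
    configured fractions exactly at pixel resolution.  Region and
    cropland layers depend only on the seed (persistent across years);
    the irrigated truth is re-drawn per year.
    """
    year = cfg.year if year is None else year
    rows, cols = cfg.shape
    n_pix = rows * cols

    rng = _rng(cfg.seed, _S_REGIONS)
    seeds = rng.uniform(0, [rows, cols], size=(cfg.n_regions, 2))
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    labels = (np.argmin(d2, axis=-1) + 1).astype(np.int32)

    crop_field = _clumped_field(cfg.shape, cfg.clump_sigma, _rng(cfg.seed, _S_CROP))
    n_crop = int(round(cfg.cropland_fraction * n_pix))
    cropland = _top_k_mask(crop_field, np.ones(cfg.shape, dtype=bool), n_crop)

    irr_field = _clumped_field(cfg.shape, cfg.clump_sigma, _rng(cfg.seed, _S_IRR, year))
    n_irr = int(round(cfg.irrigated_fraction * n_crop))
    truth = _top_k_mask(irr_field, cropland, n_irr)

    t = cfg.transform
    return (
        Grid(labels, transform=t),
        Grid(cropland, transform=t),
        Grid(truth.astype(np.uint8), transform=t),
    )


def generate_gi_stack(truth: Grid, cropland: Grid, cfg: SynthConfig,
                      year: Optional[int] = None) -> GITimeStack:
    """46-composite GI year per pixel.

    Cropland pixels follow a Gaussian-in-time seasonal curve rising from
    the baseline to the class peak (irrigated vs rainfed) plus i.i.d.
    noise; non-cropland pixels keep a constant low flat profile.  GI is
    clipped at 0 (the index is non-negative).  With zero noise the annual
    maximum equals the class peak exactly.
    """
    year = cfg.year if year is None else year
    tgrid = np.arange(PERIODS_PER_YEAR, dtype=float)
    season = np.exp(-((tgrid - cfg.peak_composite) ** 2) / (2 * cfg.season_width**2))

    crop = cropland.values.astype(bool)
    irr = truth.values.astype(bool)
    peaks = np.where(irr, cfg.gi_peak_irrigated, cfg.gi_peak_rainfed)
    stack = cfg.gi_base + season[:, None, None] * (peaks - cfg.gi_base)[None, :, :]
    stack = np.where(crop[None, :, :], stack, cfg.gi_base)
    if cfg.gi_noise_sd > 0:
        rng = _rng(cfg.seed, _S_GI, year)
        noise = rng.normal(0.0, cfg.gi_noise_sd, size=stack.shape)
        stack = stack + np.where(crop[None, :, :], noise, 0.0)
    np.clip(stack, 0.0, None, out=stack)
    return GITimeStack(stack, transform=truth.transform, crs_tag=truth.crs_tag, year=year)


def generate_statistics(truth: Grid, regions: Grid, pixel_area: float,
                        stats_bias: float = 1.0, year: int = 0) -> StatTable:
    """Reported per-region areas: bias x (true pixel count x pixel area)."""
    if not truth.same_lattice(regions):
        raise ValueError("truth and region labels must share one lattice")
    table = StatTable()
    labels = regions.values
    for rid in np.unique(labels[labels > 0]):
        count = int(((labels == rid) & (truth.values != 0)).sum())
        table.add(StatRecord(int(rid), year, stats_bias * count * pixel_area,
                             "county", source="synthetic"))
    return table


def degrade_product(truth: Grid, omission_rate: float, commission_rate: float,
                    mask: Grid, seed: int) -> Grid:
    """Truth corrupted by independent per-pixel label errors.

    Truly irrigated pixels are dropped with ``omission_rate``; rainfed
    cropland pixels are added with ``commission_rate``.  Non-cropland
    stays 0.  Deterministic for a fixed seed.
    """
    for name, rate in (("omission", omission_rate), ("commission", commission_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    crop = mask.values.astype(bool)
    irr = (truth.values != 0) & crop
    u = rng.random(truth.shape)
    out = np.where(irr, u >= omission_rate, crop & ~irr & (u < commission_rate))
    return Grid(out.astype(np.uint8), transform=truth.transform, crs_tag=truth.crs_tag)


def generate_products(truth: Grid, cropland: Grid, cfg: SynthConfig,
                      year: Optional[int] = None) -> list[tuple[str, Grid, int]]:
    """One degraded product per configured (omission, commission) pair.

    Products are named A, B, C, ... in descending weight order; error
    rates grow down the weight order so the ranking is consistent with
    product quality.
    """
    year = cfg.year if year is None else year
    rng = _rng(cfg.seed, _S_PRODUCT, year)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(cfg.product_errors))
    products = []
    for i, (om, com) in enumerate(cfg.product_errors):
        grid = degrade_product(truth, om, com, cropland, seed=int(child_seeds[i]))
        products.append((chr(ord("A") + i), grid, i + 1))
    return products


def draw_samples(truth: Grid, cropland: Grid, n: int, seed: int,
                 stratified: bool = False, year: int = 0) -> pd.DataFrame:
    """Without-replacement reference sample of cropland pixels.

    Stratified mode draws n/2 from each class (capped by class size).
    Returns a DataFrame with row, col, truth, year.
    """
    rng = np.random.default_rng(seed)
    crop_idx = np.flatnonzero(cropland.values.astype(bool))
    if n > crop_idx.size:
        raise ValueError(f"requested {n} samples but only {crop_idx.size} cropland pixels")
    flat_truth = (truth.values.flat[crop_idx] != 0)
    if stratified:
        pos = crop_idx[flat_truth]
        neg = crop_idx[~flat_truth]
        n_pos = min(n // 2, pos.size)
        n_neg = min(n - n_pos, neg.size)
        chosen = np.concatenate([
            rng.choice(pos, size=n_pos, replace=False),
            rng.choice(neg, size=n_neg, replace=False),
        ])
    else:
        chosen = rng.choice(crop_idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, truth.shape)
    return pd.DataFrame({
        "row": rows, "col": cols,
        "truth": (truth.values[rows, cols] != 0).astype(int),
        "year": year,
    })


def generate_scene(cfg: SynthConfig, year: Optional[int] = None,
                   n_samples: int = 1000, stratified: bool = False) -> SyntheticScene:
    """Full co-registered scene: landscape, GI year, statistics, products, samples."""
    year = cfg.year if year is None else year
    regions, cropland, truth = generate_landscape(cfg, year)
    gi = generate_gi_stack(truth, cropland, cfg, year)
    stats = generate_statistics(truth, regions, cfg.pixel_area_ha, cfg.stats_bias, year)
    products = generate_products(truth, cropland, cfg, year)
    n_crop = int(cropland.values.sum())
    n_samples = min(n_samples, n_crop)
    sample_seed = int(_rng(cfg.seed, _S_SAMPLE, year).integers(0, 2**31 - 1))
    samples = draw_samples(truth, cropland, n_samples, sample_seed, stratified, year)
    return SyntheticScene(cfg, regions, cropland, truth, gi, stats, products, samples)
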