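# irrimap

Annual irrigated-cropland mapping by statistical downscaling and
multi-product agreement fusion.

Reported irrigation statistics say *how much* area is irrigated in each
administrative region but not *where*; satellite greenness time series
and existing irrigation products say *where* water is likely applied but
disagree with the reported totals and with each other. `irrimap`
implements the two-step hybrid strategy that reconciles them:

1. **Greenness-index downscaling.** The greenness index
   GI = ρ_NIR / ρ_green is computed from 8-day reflectance composites
   (46 per year), smoothed per pixel with a Savitzky–Golay filter, and
   composited to the annual peak. Irrigated crops reach higher annual
   peak GI than rainfed crops in the same region, so within each region
   the cropland pixels are ranked by peak GI and a threshold is lowered
   level by level until the cumulative pixel area is closest to the
   region's reported irrigated area Area_c. All pixels at or above the
   threshold form the provisional irrigation map.

2. **Agreement-score fusion.** N co-registered binary irrigation
   products (the provisional map among them) are ranked by an
   expert-assigned weight order A > B > … > E. Each cropland pixel's
   agreement vector — which products call it irrigated — is mapped to an
   integer score in 0..2^N − 1 ordering pixels by agreement level first
   and by the weight of the agreeing products second (score 31 = all
   five agree, …, 0 = none). The same area-constrained thresholding is
   then run on the score field to produce the final map.

The package also provides pixel-wise accuracy assessment (producer's /
user's / overall accuracy, Cohen's kappa, F1 for the irrigated class),
coarse-grid irrigated-fraction trend analysis with significance and
minimum-fraction display masks, and a seeded synthetic-landscape
generator so the whole pipeline is testable without any satellite or
census downloads. Rasters are single-band GeoTIFFs (binary maps 8-bit,
1 = irrigated); statistics and samples are plain CSV.

## Worked example

```python
import irrimap as im

cfg = im.SynthConfig(shape=(120, 120), n_regions=6, seed=42)   # 500-m pixels, 25 ha
scene = im.generate_scene(cfg, n_samples=800)

# step 1: smoothed annual peak GI -> area-constrained allocation
peak = im.annual_peak(im.smooth_stack(scene.gi_stack))
targets = scene.stats.targets_for_year(cfg.year)
mirad, traces = im.allocate_map(peak, scene.cropland, scene.regions,
                                targets, cfg.pixel_area_ha)
t = traces[1]
print(f"region 1: target {t.target_area:.0f} ha, threshold GI {t.threshold:.3f}, "
      f"achieved {t.achieved_area:.0f} ha, {t.n_selected} of {t.n_pixels} px")

# step 2: fuse five weight-ordered products on the agreement-score field
stack = im.ProductStack([im.Product(n, g, r) for n, g, r in scene.products])
table = im.build_score_table(5, "paper5")
fused, _ = im.fuse(stack, scene.cropland, scene.regions, targets,
                   cfg.pixel_area_ha, table)

print(im.metrics(im.confusion(fused, scene.samples)).rounded().to_dict())
```

Output:

```
region 1: target 20075 ha, threshold GI 5.337, achieved 20075 ha, 803 of 1742 px
{'producers_accuracy': 0.987, 'users_accuracy': 0.991, 'overall_accuracy': 0.991,
 'kappa': 0.982, 'f1': 0.989}
```

Region 1 reports 20 075 ha irrigated; lowering the peak-GI threshold to
5.337 selects 803 of the region's 1742 cropland pixels (25 ha each),
hitting the target exactly. The fused map scores 0.991 overall accuracy
against the scene's reference samples — above every degraded input
product on its own (the weakest product alone reaches 0.795) because
the score field concentrates the allocation on high-consensus pixels.

## Command line

Each stage is also a subcommand of the `irrimap` console script:
`simulate`, `gi`, `mirad`, `synergy`, `validate`, `trend`, and `run`
(YAML-configured end-to-end orchestration with a provenance manifest).

```bash
irrimap simulate --out scene/ --seed 1 --year 2010
irrimap run --config pipeline.yaml
```

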