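# lymphmorph

Lymphatic microvessel morphometry and prognosis statistics for stained
histology images.

In many solid tumors — neuroblastoma prominently among them — the density
and shape of lymphatic microvessels carry prognostic information, but
classical assessment (hot-spot counting, Chalkley grids) is subjective and
ignores vessel morphology. `lymphmorph` implements an objective pipeline
for tissue-microarray core images stained with a lymphatic endothelial
marker (e.g. anti-D2-40/podoplanin):

1. **Segmentation** — separate the stain channel, trace vessel walls, and
   *close open-outline vessels*: walls broken by stain discontinuities are
   sealed by a chord between the break endpoints (gap ≤ `max_gap`, default
   10 μm), so the lumen can be measured regardless of wall thickness.
2. **Morphometry** — per-vessel lumen descriptors (area, length = max
   Feret, width = min Feret, perimeter, roundness = P²/4πA, aspect,
   perimeter ratio, deformity, shape factor, skeleton branching), caliber
   classes by longest axis (small capillaries 5–15 μm, intermediate 15–20,
   large 20–50, small collectors 50–200), and per-sample quantity metrics
   (density n/mm², %SA, relative density, relative %SA).
3. **Cohort statistics** — median dichotomization; Mann–Whitney contrasts
   against binary adverse factors; backward-elimination logistic
   regression of the high-risk group, summarised as a multiplicative odds
   equation (odds multiplier = Π Exp(B) over high indicators); Rice-rule
   normalized histograms and excess-kurtosis heterogeneity reports
   (G2 = m₄/m₂² − 3, SEK = √(24/n), leptokurtic when Zg2 = G2/SEK > 2).
4. **Survival** — Kaplan–Meier with Greenwood SE and 5-year survival,
   log-rank tests, and Cox proportional-hazards with backward Wald
   elimination (drop p ≥ 0.05), with unvascularized samples kept as their
   own stratum.

A fully seeded synthetic-data generator produces TMA-core images with
vessel ground truth and complete cohorts (covariates + survival), so the
entire pipeline is testable without any patient data.

## Worked example

```python
from lymphmorph import (sample_core_vessels, render_core_image,
                        separate_stain, extract_vessel_regions,
                        measure_regions, aggregate_sample, vessels_to_frame)

vessels = sample_core_vessels(30, rng_seed=7, open_vessel_fraction=0.2)
image, truth, _ = render_core_image(vessels, pixel_size=0.5, rng_seed=7)
stain = separate_stain(image, pixel_size=0.5)
regions = extract_vessel_regions(stain, max_gap=10.0)
measured = measure_regions(regions)
table = aggregate_sample(vessels_to_frame(measured), tissue_area=stain.tissue_area)
print(table[["caliber_class", "n", "density", "sa_pct", "rel_density"]]
      .round(2).to_string(index=False))
```

prints

```
   caliber_class  n  density  sa_pct  rel_density
       small_cap 23    29.75    0.17        79.31
intermediate_cap  4     5.17    0.08        13.79
       large_cap  1     1.29    0.10         3.45
 small_collector  1     1.29    1.22         3.45
           total 29    37.51    1.57       100.00
```

29 of the 30 ground-truth vessels were recovered (11 of them required
algorithmic closing of a broken wall); densities are vessels per mm² of
tissue, `sa_pct` is the lumen area share of the tissue, and `rel_density`
is each caliber class's share of the total density. The `examples/`
directory has one short script per capability (core rendering,
segmentation, cohort statistics, survival, full pipeline); the same
pipeline is scriptable from the shell:

```sh
lymphmorph simulate --seed 11 --out demo
lymphmorph all --config demo/config.yaml
```

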