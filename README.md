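# mtenm — multi-temporal ecological niche modelling

`mtenm` builds presence-only ecological niche models (ENMs) for
sea-ice-associated species from occurrence records spanning fossil,
historical, and contemporary eras, and projects habitat suitability across
past and future climates. It is written for spatial ecologists and
macroecologists who want a tested, reproducible implementation of the
multi-temporal hypervolume-ENM workflow: heterogeneous occurrence archives
in, tuned suitability maps and decline statistics out.

The motivating system is the bowhead whale (*Balaena mysticetus*), an
Arctic endemic whose summer habitat tracks sea ice concentration; the
pipeline is nonetheless generic over any four-axis marine niche
(sea ice concentration SIC, sea surface temperature SST, sea surface
salinity SSS, bathymetry).

## The model

Occurrence environments **x**ᵢ ∈ ℝ⁴ with weights wᵢ define a Gaussian
kernel-density hypervolume. After standardizing each axis by the weighted
mean and sd, the niche density is

  f(x) = Σᵢ wᵢ Kₕ(x − xᵢ) / Σᵢ wᵢ,

with a diagonal Gaussian kernel Kₕ whose per-axis scale h is the Silverman
rule-of-thumb bandwidth times a tuned multiplier, truncated at `sd_count`
bandwidths (the model never extrapolates beyond its training data). The
niche boundary is the density super-level set enclosing a tuned fraction
(`quantile` ∈ {0.95, 0.975, 0.99}) of total kernel mass, located by
Monte-Carlo sampling from the mixture. Suitability is

  s(x) = min(1, f(x) / max_i f(xᵢ)) · t(x),

where the edge taper t(x) ramps from 1 at the boundary to 0 at a distance
controlled by `edges_zero_distance_factor`, with distances to the boundary
sample aggregated by an inverse-distance weighting of exponent
`weight_exponent`.

Around the core model the pipeline provides:

* **occurrences** — summer (June–October) filtering, snapping of
  land-stranded records to the nearest ocean cell (< 170 km), spatial
  thinning to one record per 90 km cell per 35-year bin, fossil
  pseudo-replication weighted by calibrated-age mass (weights sum to 1 per
  fossil), 3×3-neighbourhood environmental annotation, and ten
  cross-validation folds stratified by stock × era;
* **climate** — summer 35-year bin averaging, inverse-distance regridding,
  bathymetry time interpolation, additive (SST) and multiplicative (SSS)
  delta corrections, and a beta-regression GAM (logit link, penalized
  smooths of source SIC, bathymetry, distance-to-coast, month, and a
  spatial tensor surface) for bounded SIC bias correction;
* **model selection** — ROC-AUC against hypervolume pseudo-background,
  the Continuous Boyce Index, and Sensitivity at the 10th-percentile
  training threshold, cross-validated over the hyperparameter grid and
  reduced by the one-standard-error rule;
* **projection** — occupiable-habitat thresholding, sea-ice isoband
  summaries (0–15 / 15–30 / 30–45 / > 45 % SIC), per-stock suitability
  time series, baseline-vs-future change maps, and percent declines;
* **synthetic_data** — gridded climate worlds with known biases and a
  known 4-D Gaussian niche, so every stage is testable without real
  archives.

## Worked example

```python
from mtenm.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(), seed=7)
s = res["summary"]
print({m: round(v["mean"], 3) for m, v in s["cv_metrics"].items()})
print(round(s["niche_recovery_spearman"], 3))
print(s["stock_suitability_decline_pct"])
```

prints (about two minutes on one core):

```
{'auc': 0.991, 'boyce': 0.819, 'sensitivity': 0.875}
0.983
{'bering': 100.0, 'canada_greenland': 98.489, 'okhotsk': 100.0,
 'svalbard_barents': 99.795}
```

The first line is the selected model's ten-fold cross-validated metrics:
held-out presences rank far above pseudo-background (AUC 0.991), the
predicted-to-expected presence ratio rises with suitability (Boyce 0.819),
and 87.5 % of held-out presences clear the occupiability threshold. The
second line is the Spearman correlation between projected and true
suitability over all ocean cells of a stable mid-Holocene bin — the model
recovers the generating niche. The last line shows that under the
SSP-like forcing in the scenario bins (sea ice collapsing below the
15–30 % optimum while the ocean warms), mean habitat suitability in all
four management stocks declines by ≥ 98 % relative to the Holocene
baseline, with the warm-edge (Okhotsk-like) stock losing all occupiable
habitat before the final bin.

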