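# Methods

This note documents the models implemented in `mtenm`, the choices made
where the methodology was genuinely open, and what the synthetic study
design does and does not demonstrate.

## Data model

Occurrences are point records with an era (`fossil`, `historical`,
`contemporary`), a stock label, and either a calendar date (historical and
contemporary records) or a calibrated-age probability distribution
(fossils). Time is discretized into half-open 35-year bins — roughly one
bowhead whale generation — anchored so the final observational bin ends at
2020 CE; scenario bins extend the same lattice forward. Space is an
abstract equal-area grid of 90 km cells indexed by (x, y); because the
grid is equal-area, no cos-latitude weighting or geodesy is needed and the
y axis behaves as a pseudo-latitude (sea ice increases toward the top).
Environmental state per bin is four layers — SIC (%), SST (°C), SSS (psu),
bathymetry (m, positive depth) — plus a land–sea mask; masked cells carry
NaN, never zero.

## Occurrence processing

1. **Summer filter.** Historical/contemporary records are kept only for
   June–October; fossils always pass (interpreted as summer sea-ice
   entrapments). A non-fossil record without a month is an error, not a
   silent drop.
2. **Ocean snapping.** Records on land move to the nearest ocean cell
   centre if it is < 170 km away (centre-to-centre Euclidean distance on
   the equal-area grid), otherwise they are dropped and logged.
3. **Fossil pseudo-replication.** Each fossil becomes one replicate per
   bin with positive calibrated-age mass, weighted by that mass, so each
   fossil contributes total weight 1. When later thinning removes a
   replicate, the survivors are *not* renormalized: renormalization would
   silently inflate sparse bins, and total-weight conservation is the
   property worth keeping interpretable. (A flag restores competition-free
   thinning of fossils if desired.)
4. **Spatial thinning.** At most one record per (cell, bin). The survivor
   is the earliest year, ties broken by lexicographic id — the literature
   leaves the survivor unspecified; determinism beats arbitrariness.
   Fossil pseudo-replicates compete with other records within their bin by
   default.
5. **Environmental annotation.** Per record, the unweighted mean of the
   3×3 neighbourhood restricted to ocean cells (coasts therefore average
   fewer than nine cells); an all-land neighbourhood is an error.
6. **Folds.** Ten cross-validation folds stratified by stock × era:
   within each stratum, ids are sorted, shuffled with a seeded RNG, and
   dealt round-robin, so per-stratum fold sizes differ by at most one and
   the assignment is independent of input order.

## Climate preparation

* **Bin averaging** takes the mean over June–October months of all years
  in a bin; a cell is missing only when it has no valid month at all.
* **Regridding** is inverse-distance weighting over the k = 4 nearest
  valid source cells (power 1); coincident nodes return the source value
  exactly, and constant fields are preserved exactly.
* **Bathymetry** snapshots at coarse (e.g. 500-year) nodes are linearly
  interpolated in time to bin midpoints; bins after the last snapshot
  reuse the contemporary snapshot unchanged.
* **Delta corrections** match a model's per-cell overlap-window
  climatology to the reference: additive for SST, multiplicative for SSS
  (cells with a zero model mean fall back to additive, logged). Delta
  methods correct the climatology, so correction *skill* is assessed on
  the per-cell time-mean field; per-bin noise is irreducible by
  construction and is not counted against the correction.
* **SIC bias model.** SIC is bounded and responds nonlinearly to its
  drivers, so the reference SIC is modelled with a beta likelihood and
  logit link as a sum of penalized smooths: cubic B-splines of source-model
  SIC (k = 8), bathymetry (k = 6), and distance-to-coast (k = 6); a cyclic
  Fourier smooth of month (2 harmonics — cyclic by construction, chosen
  over a cyclic cubic spline for parsimony); and a 4×4 tensor-product
  B-spline surface of the spatial coordinates. The response is shrunk to
  (0, 1) by the standard boundary transform y′ = (y(n − 1) + 0.5)/n before
  fitting, because the beta likelihood excludes the endpoints, and
  inverted afterwards. Smoothing uses fixed second-difference ridge
  penalties (multiplier `penalty`, default 1.0) plus a small identifiability
  ridge; the penalized likelihood is maximized by L-BFGS with analytic
  gradients. Predictions clamp covariates to the training range, so
  extrapolated output is always within [0, 100]. A `mode="anomaly"`
  variant models the percent-point change (reference − source) instead of
  the reference itself; direct prediction is the default.
* **Distance to coast** is the exact Euclidean distance transform of the
  mask, in km.

## The hypervolume niche model

Axes are standardized by the *weighted* training mean/sd. The base
bandwidth per axis is the Silverman rule on the standardized sample,
(4/(d+2))^{1/(d+4)} n_eff^{−1/(d+4)} with d = 4, times the tuned
`bandwidth_mult`. Weights are treated as frequencies — n_eff = Σw — so a
point with weight 2 is exactly two unit-weight copies and each fossil's
pseudo-replicate family counts as one record.

Kernels are truncated at `sd_count` bandwidths per axis; density is
exactly zero outside the union of truncation boxes, so the model cannot
score environments unlike anything it was trained on. The boundary
threshold is the (1 − `quantile`) quantile of the density of `n_boundary`
Monte-Carlo draws from the mixture (default 10,000; the draws at or above
the threshold are retained as the boundary sample). The reference
methodology names the projection knobs (`edges_zero_distance_factor`,
`weight_exponent`) without printing the projection formula, so this
package fixes a concrete semantics: suitability is the truncated density
normalized by its maximum over training points; inside the super-level set
the taper is 1; outside, suitability is multiplied by
max(0, 1 − d_b/(`edges_zero_distance_factor` · ‖h‖)), where d_b is the
inverse-distance-weighted mean (exponent `weight_exponent`) of the
distances to the 5 nearest boundary-sample points. This satisfies the
required behaviour — s ∈ [0, 1], s = 1 at a lone training point, zero
beyond truncation, monotone decay along rays in the single-point case, and
both knobs observably change projections.

The hypervolume's Monte-Carlo volume (bounding-box rejection sampling,
with a binomial standard error) is reported for diagnostics and grows with
the bandwidth multiplier as expected.

## Validation and model selection

* **AUC** uses the Mann–Whitney formulation (ties count ½) against
  pseudo-background drawn uniformly from the bounding box of the
  hypervolume's boundary sample and scored by the same model (10×
  the presence count per fold, seeded).
* **Continuous Boyce Index**: 101 overlapping windows of width 10 % of
  the available-suitability range; per window P = presence fraction,
  E = available fraction; the index is the Spearman correlation of P/E
  with the window midpoint over windows with E > 0. Note a property of
  this estimator under the conventional windowing: heavy window overlap
  leaves only ~10 effectively independent windows, so even when presences
  are drawn exactly from the available distribution the *magnitude* of the
  index is typically ≈ 0.25 (its sign is unbiased). Comparisons between
  models are meaningful; small absolute values should not be
  over-interpreted.
* **Sensitivity** is the (weighted) fraction of held-out presences at or
  above the 10th percentile (lower interpolation) of training-presence
  suitability.
* **Cross-validation** fits on out-of-fold records (weights respected)
  and evaluates on the held-out fold; fold RNGs derive from fold
  membership, so metrics are invariant to fold relabeling. Fold means and
  standard errors (sd/√k) are reported.
* **One-SE rule**: metric fold-means are z-scored across the tuning grid
  and summed; every configuration within one standard error of the best
  combined score (the best's SE propagated as the root-sum-square of its
  z-scaled metric SEs) is eligible, and the most parsimonious eligible
  configuration wins. Parsimony ordering — larger bandwidth, then larger
  mass quantile, then smaller truncation count — treats smoother models as
  simpler, consistent with the rule's regularization intent.

## Projection products

Occupiability thresholds at the 10th percentile (lower interpolation) of
training-presence suitability, with ≥ as the boundary convention. Sea-ice
isobands are half-open — [0,15), [15,30), [30,45), [45,100] — and empty
bands are reported as missing, not zero; extent is cell count × 8100 km².
Stock series use the sample standard deviation (0 for a single cell).
Change maps compare future occupiability against a baseline defined as
occupiable in ≥ 50 % of Holocene bins (configurable fraction). Percent
change is 100(ref − target)/ref, positive for declines; the package
reports extent-based declines and suitability-based declines separately
rather than choosing one reading.

## The synthetic study design

The generator emulates the statistical structure the pipeline assumes,
not Arctic geography: a land strip along one edge; SIC increasing with
pseudo-latitude; SST decreasing with it; SSS and bathymetry varying
across-grid; per-cell-per-bin natural variability in the truth (defaults
4 % SIC, 0.4 °C, 0.2 psu) shared by both synthetic climate "models"; and a
biased model derived from the truth by an additive SST offset (+2 °C), a
multiplicative SSS factor (×1.1), a logit-scale SIC shift (+0.5), and iid
observation noise. The natural variability is load-bearing: in a
perfectly stationary world SIC is a deterministic function of the spatial
coordinates, the bias GAM's spatial smooth absorbs the whole signal, and
the SIC spline is unidentified — as in real bias-correction practice, the
overlap window must contain climate variation.

The true niche is a product of independent Gaussian kernels on the four
axes, with its SIC optimum (22.5 %) inside the 15–30 % band where bowhead
habitat suitability peaks. Presences are sampled with probability
proportional to the true suitability of each (cell, bin); fossils get
discretized Gaussian calibrated ages (sd 120 yr, truncated to the central
95 % and renormalized); 10 % of non-fossil records get off-season months
so the summer filter is observable.

The default pipeline world is 24×24 cells with 34 observational bins
(830–2020 CE) and 6 scenario bins; 500 presences (60 fossil,
120 historical, 320 contemporary) before cleaning. The scenario forcing
(−16 % SIC and +3.5 °C per bin) is chosen so that by the final bin sea ice
sits below the niche optimum everywhere *and* every quadrant stock's
suitability falls below its Holocene mean — weaker warming lets the
ice-free north edge drift toward the niche optimum, which is a genuine
behaviour of niche models under partial forcing but not the scenario this
design targets. The default tuning grid is a deliberate subset of the full
reference grid (bandwidth_mult {1.0, 1.75, 2.5} × edge factor {1.0, 3.0},
with sd_count 3, quantile 0.95, weight exponent −2, 4,000 boundary draws),
sized so a full tuned run completes in about two minutes on one core;
every value lies on the reference grids and the grid can be widened
freely.

Passing tests on this design show that the pipeline's operations are
correct and that the estimator recovers a niche it is well-specified for.
They do not show robustness to sampling bias, spatial autocorrelation of
real occurrence archives, non-Gaussian niches, calibration-curve error in
fossil ages, or real CMIP-class model disagreement — none of which the
generator emulates.

## Numerical conventions and degenerate inputs

* Percentiles use numpy's lower interpolation; with n distinct training
  suitabilities the training sensitivity at the 10th-percentile threshold
  is (n − ⌊0.1(n − 1)⌋)/n ≈ 0.90 + O(1/n).
* Bins are half-open [start, end); a year exactly on an edge belongs to
  the later bin.
* A zero-sd axis (single training point) standardizes by 1.0.
* Zero total weight, empty age mass, all-equal GAM response, all-masked
  neighbourhoods, and a zero percent-change reference all raise named
  errors rather than returning sentinels.
* All Monte-Carlo steps take explicit seeds; the pipeline derives every
  RNG from one seed and produces bit-identical outputs across runs.

## Known limitations

* The projection formula is one concrete member of the family consistent
  with the published description of the reference workflow; absolute
  suitability values are therefore not comparable across implementations,
  though rankings are stable.
* The beta GAM selects smoothness by fixed penalties, not GCV/REML; the
  default is mildly informative and identifiable, not optimal.
* The Boyce estimator's null magnitude under overlapping windows (above)
  means its absolute value is a weak signal near zero.
* Ensemble construction and weighting of multiple climate models is out
  of scope; the "model" input is a single pre-combined field, and
  radiocarbon calibration is taken as given.
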