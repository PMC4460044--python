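# maxscale

Multi-scale presence-only habitat suitability modelling, built for the
kind of question a conservation ecologist faces with record-centre data:
given opportunistically collected occurrence records (say, bat roosts
reported by volunteers) and 100 m environmental rasters, which landscape
variables — and at which spatial scales — predict where the species
occurs, and how trustworthy is the resulting suitability map?

The package implements the full analysis chain as tested, reusable code:

1. **Multi-scale variables** — focal statistics (mean, percent cover,
   majority, class richness), woodland edge density and largest-patch
   size in circular moving windows at eight radii (500–6,000 m), plus
   Euclidean distance layers and Horn slope/aspect from a DEM.
2. **Occurrence preparation** — rule-based record filtering (season,
   identification method, coordinate precision, per-species minimum
   year, study region), thinning to one record per cell, and two
   pseudoabsence schemes: *target-group* records (which share the
   presences' sampling bias, so the bias cancels) and random building
   locations.
3. **Maximum-entropy estimation** — a Gibbs distribution over background
   cells, `raw(x) = exp(λ·f(x))/Z`, fitted by maximising the
   L1-penalised presence log-likelihood

   `L(λ) = mean_presence[λ·f(x)] − log Z(λ) − Σ_j β_j |λ_j|`

   with sample-size-dependent feature classes (linear, quadratic, hinge,
   threshold, product, categorical), per-class default penalties scaled
   by a regularisation multiplier (default 2), and the entropy-based
   logistic transform `HSI = e^H·raw / (1 + e^H·raw)`.
4. **Model selection** — univariate scale scan (best scale per variable
   by cross-validated test AUC), screening (drop test AUC ≤ 0.5 or test
   gain ≤ 0.01), collinearity pruning (|r| ≥ 0.70 drops the lower-AUC
   member, strongest pair first), and jackknife leave-one-out stepwise
   backward pruning.
5. **Validation** — 5-fold cross-validation (jackknife below 25
   records), the max-sensitivity-plus-specificity occupancy threshold,
   one-sided binomial omission tests, Moran's I correlograms of the
   residuals (1 − HSI at presences) with Monte-Carlo permutation
   p-values, and spatially aggregated (k-means) folds when residual
   spatial autocorrelation is detected.
6. **Mapping** — HSI maps over the full raster stack, thresholded
   suitable-area masks, and Schoener's D niche overlap between maps.

Because the original survey data and licensed rasters of such studies
are rarely redistributable, the package ships a synthetic-landscape
module: Gaussian-correlated landcover mosaics with exact target covers,
virtual species whose suitability is a known function of one variable at
one scale, and a building-access observation bias. Every claim the
pipeline makes can therefore be tested as parameter recovery against a
known truth. Rasters are read and written as ESRI ASCII grids.

## Worked example

```bash
python analysis/02_scale_scan.py --seed 0
```

builds ten independent 200×200-cell landscapes, gives each a virtual
species responding to deciduous cover measured in a 1,500 m window, and
scans that variable at all eight candidate scales with 5-fold
cross-validated univariate models. Output (abridged):

```
 seed  best_scale  best_auc   hit
    0      1500.0  0.735347  True
    1      1500.0  0.753135  True
    2      2000.0  0.763657 False
    ...
    9      1500.0  0.748292  True

true scale (1,500 m) recovered in 9/10 seeds
```

`best_auc` is the mean held-out AUC of the univariate model at its best
scale; `hit` marks seeds where the scan's best scale equals the true
1,500 m. The neighbouring 1,000/2,000 m windows overlap the true one
heavily, so near-misses land there — visible in seed 2.

The remaining drivers follow the same pattern: `01` writes the synthetic
study to disk, `03` shows stepwise pruning keeping the true variable
while discarding a pure-noise decoy, `04` shows target-group
pseudoabsences beating random ones under biased sampling, `05` shows
spatially constrained folds separating train from test and removing the
AUC optimism that spatial autocorrelation causes, and `06` runs the
whole pipeline into `results/pipeline_run/` (reports, correlogram, HSI
map). A `maxscale` console command wraps fixture generation, stack
building and full runs (`maxscale run-all config.yaml outdir`).

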