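# Methods

## The model

The estimator is a presence-background maximum-entropy model. Given
features `f(x)` computed from the environmental variables at every
background cell, it fits the Gibbs distribution

    raw(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_background exp(λ·f)

whose weights maximise the penalised presence log-likelihood

    L(λ) = mean_presence[λ·f(x)] − log Z(λ) − Σ_j β_j |λ_j|.

This objective is concave; it is optimised by L-BFGS-B on the smooth
split-weight reformulation (λ = a − b with a, b ≥ 0), which handles the
L1 term exactly and deterministically. Convergence is reported on the
model object rather than silently assumed. The fitted distribution's
entropy H over the background gives the logistic habitat suitability
index, `HSI = e^H·raw/(1 + e^H·raw)`, which equals 0.5 when a cell is
indistinguishable from a "typical" background cell (for a uniform model
over N cells, raw = 1/N and HSI = 0.5 exactly).

Features and penalties follow the method's conventional defaults, all
config-exposed:

- Continuous variables are min-max scaled to [0, 1] on the background
  (which always includes the presence cells). Classes: linear,
  quadratic, pairwise products, hinge and threshold with 5 interior
  knots evenly spaced on the scaled range, and one indicator per
  observed categorical code.
- The auto rule by presence count m: linear only (m<10), +quadratic
  (10≤m<15), +hinge (15≤m<80), all classes (m≥80).
- `β_j = β_mult · c_class(m) · s_j/√m`, with `c_class` interpolated from
  the per-class constant tables, `s_j` the feature's standard deviation
  over the presences (floored at 1e-3 so features constant across
  presences keep a finite weight), and `β_mult = 2` by default.
- Training gain subtracts the penalty; test gain is the unpenalised mean
  of `ln(raw·N_background)` over held-out presences.

AUC is the rank (Mann–Whitney) statistic with ties counted ½, computed
presences-versus-pseudoabsences. Permutation importance permutes one
variable at a time across the pooled presence + pseudoabsence rows,
records the drop in training AUC, floors negative drops at zero, and
normalises to 100%.

## Multi-scale variables

Thirteen scalar variables (aspect majority, mean altitude, mean slope,
six percent-cover layers, ancient-wood cover, habitat richness, largest
woodland patch, woodland edge density) are computed at eight window
radii (500–6,000 m) plus two scale-free Euclidean distance layers —
106 layers in the full stack. Conventions, each configurable:

- **Windows** are circular (cells whose centre is within the radius;
  symmetric by construction) and clipped at borders and nodata —
  statistics use the valid in-window cells only. Square windows are
  available as an option.
- **Focal sums** use exact row-run cumulative sums, not FFT
  convolution, so results equal a per-cell brute-force recomputation to
  1e-9 and layers are bitwise deterministic.
- **Terrain**: Horn's 3×3 weighted gradient; borders use odd-reflection
  padding, which reduces to one-sided differences (exact for planes).
  Aspect is the downslope compass direction in eight 45° classes;
  slopes below 1° are "flat". Majority ties resolve by fixed legend
  order (flat, N, NE, …, NW).
- **Edges** are the shared boundaries between woodland and valid
  non-woodland cells (rook adjacency); raster borders contribute no
  edge. Each segment is attributed to its woodland-side cell, and a
  window's edge length is the sum over its woodland cells; density
  divides by the valid in-window area.
- **Patches** are 8-connected components labelled over the full raster;
  a cell's value is the largest patch area with at least one cell in
  its window (a grey-dilation, so exactly the "within or intersecting"
  definition).
- **Distances** are cell-centre to cell-centre, a 100 m-resolution
  approximation of vector-based distance. Distance to woodland edge is
  0 inside woodland by default (flag to measure to the boundary cells
  instead).

Rasters are carried as ESRI ASCII grids (integer grids round-trip
bit-exactly; floats at full repr precision), lower-left origin, points
mapped to cells by `floor((p − origin)/cell_size)`.

## Occurrences and pseudoabsences

Filtering applies conjunctive predicates — month window (April–September
by default), per-species minimum year, activity and identification
method, coordinate precision ≤ 100 m, optional structure set, and
membership of a raster study mask — and logs per-predicate rejection
counts. Thinning keeps one record per cell, deterministically (first
under lexicographic (x, y, input-order)), so the whole preparation is
idempotent and reproducible. Target-group pseudoabsences are all
similarly-surveyed records filtered under relaxed rules and thinned;
building pseudoabsences take centre-points of footprints strictly larger
than 10 × 10 m, thin them, and sample n without replacement under a
seed.

## Selection ladder

Each variable is first fitted alone at every scale under the validation
scheme; the best scale maximises mean test AUC with ties to the smallest
scale (the cheapest, most local choice). Variables with best-scale test
AUC ≤ 0.5 or test gain ≤ 0.01 are removed. Pearson correlations between
the surviving best-scale layers are computed over all jointly valid
study-area cells; while any pair has |r| ≥ 0.70 the strongest pair is
resolved by dropping its lower-AUC member — a deterministic greedy order
that removes the worst redundancy first. Stepwise backward pruning then
refits with each variable left out in turn, removes the one whose
omission least harms (or most helps) mean test AUC, and repeats down to
one variable; with k variables this costs at most k(k+1)/2 − 1 refits
beyond the full model. The final set maximises mean test AUC, except for
small samples (<25 records), where the criterion is lowest omission
rate, then its p-value, with test AUC as tie-break.

## Validation

5-fold cross-validation for ≥25 presences, leave-one-out jackknife
below; the background of each fold is the pseudoabsence set plus the
training presences. The occupancy threshold maximises test sensitivity
plus specificity over the observed scores; ties between maximising
thresholds resolve to the *largest* candidate — the conservative choice,
since it yields the smallest predicted-suitable area (under jackknife,
whose single-point test folds are degenerate, the threshold comes from
the training scores instead). The omission test is the one-sided
binomial tail P(X ≥ s) with success probability equal to the
predicted-suitable fraction; fold counts are pooled for the reported
p-value.

Moran's I uses the standard symmetric double-sum over distance-band
weight matrices (1 km contiguous bands to half the maximum pairwise
distance by default) on residuals 1 − HSI at the presence points.
Significance is Monte-Carlo: 9,999 seeded permutations by default,
two-sided on |I|, Bonferroni-corrected across bands (Holm optional).
The residual-autocorrelation lag is the upper edge of the farthest band
in the initial contiguous run of corrected-significant positive I. When
a lag is detected and the sample allows, validation is repeated with
spatially aggregated folds: seeded k-means on the point coordinates
(best of 10 restarts), each cluster a fold, with mean and minimum
inter-fold distances reported.

## Synthetic studies: what they do and do not show

The generator produces Gaussian-correlated random fields (white noise
smoothed to a 500 m correlation length by default), assigned greedily to
landcover classes so realised covers hit their targets to rounding
(well inside the ±2% contract); leftover cells become seven open-habitat
classes split by elevation, giving a 13-class mosaic. Ancient woodland
is a coherent subset of deciduous cells; the DEM is an independent
smooth field scaled to 600 m relief. Virtual species multiply per-layer
response terms (logistic up/down, Gaussian) and rescale to [0, 1]; the
default truth is a logistic response (midpoint 12%, rate 4) to deciduous
cover at 1,500 m. Observation bias is an exponential decay of recorder
effort with distance from buildings (1,500 m e-folding over a 0.02
floor). Presences are distinct cells drawn with probability ∝ truth ×
effort (Efraimidis–Spirakis keys, fully seeded).

These landscapes have controlled statistical structure, not realism: no
river networks, road geometry, building morphology or detection
covariates beyond the single effort surface. Passing recovery tests
shows the machinery identifies scales, variables and bias structure it
was designed to identify under its own assumptions; it does not certify
performance on real survey data.

## Problem sizes and experiment design

The recovery experiments use sizes chosen to keep the whole suite in the
minutes range on one CPU while leaving the signal comfortably
detectable: scale recovery on 200×200-cell landscapes (10 seeds, 150
presences, 2,000 background); ladder and bias experiments on 150×150;
spatial-fold AUC comparisons on 120×120 with 100 presences; the fixture
pipeline on 150×150 with all eight scales and 999 correlogram
permutations. Pass criteria are fixed in advance of the runs: ≥8/10
seeds for the recovery experiments, strict majorities for the bias and
AUC-direction properties, ≥18/20 for the fold-distance property.

## Numerical choices and degenerate inputs

- Optimiser tolerances: ftol 1e-10, gtol 1e-9, max 1000 iterations;
  weight agreement with 1-D oracles is ~1e-8 in practice.
- Empty feature sets yield the uniform distribution (gain 0) rather than
  an error; constant features scale to zero and carry no hinge knots.
- Distance transforms are undefined without feature cells; Moran's I
  with zero-variance residuals and thresholds with a single candidate
  score raise/warn explicitly rather than returning NaN.
- Empty correlogram bands are flagged (NaN I, excluded from the
  correction count).
- All randomness flows from explicit integer seeds; pipeline runs are
  byte-identical under identical configs, and reports embed the config
  and every seed used.

## Known limitations

- GeoTIFF I/O is not provided; ESRI ASCII is the interchange format.
- Vector geoprocessing (polygon footprints beyond rectangles, CRS
  reprojection) is out of scope; study regions are raster masks.
- The correlation-based collinearity step treats categorical aspect
  codes as numeric, as raster correlation tools conventionally do.
- Niche overlap implements Schoener's D only (on logistic surfaces over
  the shared valid cells; raw-output overlap is an option).
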