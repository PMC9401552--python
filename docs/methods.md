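# Methods

## Problem and data model

Multiplexed imaging assays (MxIF, MIBI, CODEX) quantify dozens of protein
markers per segmented cell across many physical slides. Staining chemistry,
optics and acquisition batches impose *slide effects*: technical variation
shared by every cell on a slide. `slidenorm` operates on the long-format
cell table that comes out of segmentation — one row per cell with a slide
identifier, an image identifier (images nest in slides), one nonnegative
numeric intensity column per marker, and optional metadata columns. Row
order is treated as significant and preserved through every operation so
derived tables can be joined back positionally.

Validation at construction is total: missing identifiers, non-numeric or
missing marker values, negative raw intensities, and images spanning two
slides all raise specific errors. Identifiers are coerced to strings so a
numeric slide label can never be treated as a quantity. NaN marker values
are rejected rather than propagated, because every downstream statistic
assumes complete data.

## Normalization

Normalization is a two-stage map applied to the marker columns only,
`method(transform(raw))`:

**Transforms.**

- `log10`: `log10(y + 1)`. The +1 offset is a deliberate choice — raw
  intensities legitimately contain exact zeros (background cells), and the
  offset maps them to 0 while keeping the transform monotone.
- `mean_divide`: `y / mean_sm`, where `mean_sm` is the mean of marker *m* on
  the cell's own slide. Every (slide, marker) group has mean exactly 1
  afterwards, so a purely multiplicative slide effect is removed exactly and
  the transform is idempotent on its own output.
- `log10_mean_divide`: `log10(y / mean_sm + 1)` — the simplest composition
  of the two, equal to `log10` applied after `mean_divide`.

A (slide, marker) group with mean ≤ 0 makes `mean_divide` undefined and
raises an error naming the slide and marker.

**ComBat.** The model-based method is the parametric empirical-Bayes
location/scale batch model with one batch per slide and no covariates. Per
marker *m*: slide means are estimated by least squares; the grand mean
α̂_m is the size-weighted average of slide means; residuals are standardized
by the pooled within-slide variance σ̂²_m (denominator N). On the
standardized scale, the per-slide location γ̂_sm and scale δ̂²_sm estimates
are shrunk toward normal (location) and inverse-gamma (scale) priors whose
hyperparameters are fitted *per slide by method of moments across markers*
— the prior-pooling direction of the canonical ComBat algorithm, which
borrows strength across features within a batch (and is why ComBat here
requires at least two markers). Posterior effects γ*_sm, δ*²_sm come from
iterating the conditional posterior-mean and posterior-variance updates;
the iteration stops when the largest relative change falls below 1e-6 or
after 200 iterations (in practice 2–5 iterations suffice). The adjustment
is

    y* = σ̂_m / δ*_sm · (z_sm − γ*_sm) + α̂_m .

The implementation is verified against the Bioconductor reference
implementation on a frozen fixture (agreement to ~1e-15 before rounding of
the frozen values). Negative adjusted values are retained, not clipped:
clipping would distort the thresholds and variance components computed
downstream, and the normalized-table contract allows them. If the markers
behave identically within a slide (degenerate prior moments), shrinkage is
skipped and the least-squares estimates are used for that slide.

ComBat is applied *after* the chosen transform; transform and method are
independent choices recorded as provenance on the dataset. User-defined
normalizers plug into the same driver: a callable receiving
`(table, marker_cols, slide_id, image_id, **method_params)` whose output is
re-validated against the shape contract (same rows, order, ids, metadata).

## Evaluation

**Otsu threshold.** The observed range of a vector is split into 256
equal-width bins (bin count exposed as a parameter) and every internal bin
edge *t* is scored by the between-class variance ω₀ω₁(μ₀−μ₁)² of the exact
split `y ≤ t` vs `y > t`, computed from sorted cumulative sums rather than
binned approximations. The best-scoring edge is returned; ties take the
smallest edge for determinism. Constant input has no threshold and raises.
Equality with an exhaustive scan over all candidate edges is a tested
invariant, and agreement with scikit-image's histogram implementation is
within one bin width (it returns bin centers).

**Threshold discordance.** Per table and marker, a global threshold T_m is
computed on the pooled values and a slide threshold T_ms on each slide's
values; the slide's discordance is the fraction of its cells whose
positivity call `y > T` differs between the two thresholds. Strict
inequality defines positivity; off the bin edges strictness is irrelevant.
Slide-level discordances are averaged *unweighted* by default when
aggregated (cell counts are reported so a weighted average can be formed).
A `threshold_override` function replaces Otsu everywhere, supporting
user-defined thresholding.

**UMAP.** A seeded 2-D embedding (15 neighbors, min_dist 0.1, Euclidean —
the canonical defaults) of the selected marker columns, with optional
seeded downsampling without replacement. The same sampled cells are used
for every table so raw and normalized embeddings are directly comparable.
A fixed seed forces single-threaded, reproducible output; determinism is a
hard contract here.

**Variance proportions.** Per marker and table, the random-intercept model
`value ~ 1 [+ metadata fixed effects] + (1 | slide)` is fitted by REML
(statsmodels MixedLM) and the slide share σ²_slide/(σ²_slide+σ²_resid)
reported with its complement; the two proportions sum to 1 by construction.
Markers are fitted independently; no p-values or multiple-testing machinery
are involved. Only slide vs residual components are modeled — image-level
(within-slide) components are out of scope.

**Summary.** The summary report computes, per (table, marker), the k-sample
Anderson–Darling statistic comparing the marker's distribution across
slides (smaller ⇒ more homogeneous; identical samples sit below the null
mean, so the statistic can be negative), plus the mean/SD of discordance
and the slide variance share where those analyses have been run; per-table
aggregates are unweighted means over markers, and raw-minus-normalized
deltas are reported when both tables were analyzed. The AD statistic is the
package's choice of distribution-homogeneity measure: it targets
across-slide similarity directly and needs no tuning.

## Synthetic data

The generator emulates the statistical structure the framework assumes, not
any particular real dataset. Per marker, cell log-intensities follow a
two-component Gaussian mixture — negative cells at μ_m (baselines staggered
0.25 apart in log units from `base_log_mean` = 1.0), positive cells
`mixture_separation` × `noise_sd` higher — exponentiated to nonnegative,
right-skewed, bimodal intensities, the regime Otsu thresholding
presupposes. Defaults: 4 slides × 3 images × 250 cells, 3 markers, 1
binary metadata column, 30% positive cells, separation 3 SDs, log-scale
noise SD 0.5.

Slide effects u_sm ~ N(0, slide_effect_sd²) are drawn per (slide, marker)
and injected as a log-scale shift (`multiplicative`; removed exactly by
`mean_divide`), a raw-scale shift clipped at zero (`additive`), or a noise
multiplier `exp(u)` (`scale`); additive-plus-scale structure is the regime
ComBat corrects. For log-scale data the slide variance share is
slide_effect_sd² / (slide_effect_sd² + within-slide variance), giving a
known ground truth for recovery tests.

What the generator does *not* emulate: spatial structure, cell-type
composition differences between slides, image-level (within-slide) batch
effects, marker-marker correlation beyond shared positivity, and heavy
instrument artifacts. Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed model, not performance on any
real cohort.

## Numerical and design choices

- ComBat convergence: relative change < 1e-6 on successive γ*, δ*²
  updates, max 200 iterations; posterior scales are checked positive.
- Problem sizes in tests and the acceptance script: the canonical
  batch-effect fixture is 6 slides × 500 cells; ComBat homogenization uses
  3 slides × 2000 cells; variance recovery uses 40 slides × 200 cells over
  σ²_u ∈ {0, 0.25, 1, 4}. These sizes make every Monte-Carlo band
  comfortably sharp while keeping the default run fast.
- The recovery simulators condition drawn effects to their nominal moments
  (realized var(u) equals σ²_u exactly, within-slide variance exactly 1),
  so the ±0.05 recovery band measures estimator error, not the sampling
  noise of a 40-draw variance.
- Density plots use Gaussian KDE with Scott's-rule bandwidth, evaluated on
  a grid padded 4 bandwidths beyond the data range so traces integrate
  to ≈ 1.
- All figures render headlessly (Agg) and save to PNG/SVG/PDF.

## Known limitations

- ComBat needs ≥ 2 slides, ≥ 2 cells per slide, ≥ 2 markers, and positive
  pooled within-slide variance per marker; a marker constant within every
  slide is rejected as degenerate.
- Functional-data (density-registration) normalization is not implemented.
- Covariates are carried through normalization but not modeled inside
  ComBat (no design matrix beyond the slide batch).
- The Anderson–Darling statistic is sensitive to ties; intensities are
  continuous in the intended use.
- Intensity scale is not assumed bounded; if data are rescaled to [0, 1]
  upstream, all operations still apply but the log10 offset of +1
  compresses the usable range.
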