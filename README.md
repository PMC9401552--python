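# slidenorm

Normalization of cell-level multiplexed-imaging marker intensities across
slides, with a quantitative evaluation framework for how well each
normalization removes slide-to-slide technical variation while preserving
biological signal.

Multiplexed imaging assays (MxIF, MIBI, CODEX) measure dozens of protein
markers per segmented cell across many physical slides. Staining, optics
and batch handling create *slide effects* — technical variation shared by
every cell on a slide — that confound downstream single-cell analysis.
`slidenorm` is for analysts who already have segmented cell-level
quantifications (one row per cell: slide id, image id, marker intensities,
metadata) and need to (a) normalize them and (b) check, with statistics
rather than eyeballs, whether the normalization worked.

## What it computes

**Normalization** is `method(transform(raw))` on the marker columns:

- transforms: `log10(y+1)`; `mean_divide` (`y / mean_sm`, the per-slide
  per-marker mean, so every slide-marker group has mean 1 afterwards);
  `log10_mean_divide`; or none;
- methods: parametric empirical-Bayes ComBat with slide as the batch
  (location/scale effects γ*_sm, δ*²_sm shrunk toward per-slide priors and
  removed: `y* = σ̂_m/δ*_sm (z_sm − γ*_sm) + α̂_m`), or a user-supplied
  normalizer function.

**Evaluation**, run on raw and normalized tables side by side:

- *Otsu threshold discordance* D_ms = (1/n_s) Σ 1[(y > T_ms) ≠ (y > T_m)]:
  the fraction of slide *s*'s cells whose marker-positivity call flips
  between the slide-specific Otsu threshold T_ms and the global one T_m;
- *variance proportions* σ²_slide/(σ²_slide + σ²_resid) from a per-marker
  random-intercept model fitted by REML;
- a seeded 2-D *UMAP embedding* for visual assessment of slide mixing;
- a summary with the k-sample *Anderson–Darling* statistic of distribution
  homogeneity across slides.

Lower discordance, lower slide variance share, and a lower AD statistic
after normalization all indicate removed slide effects. A seeded synthetic
generator (hierarchical log-normal mixtures with multiplicative, additive
or scale slide effects) provides ground-truth data for all of this.

## Worked example

```python
import slidenorm as sn

# 6 slides x 500 cells with multiplicative slide effects (log-scale SD 0.5)
cfg = sn.SimConfig(n_slides=6, n_images_per_slide=2, n_cells_per_image=250,
                   slide_effect_type="multiplicative", slide_effect_sd=0.5, seed=1)
ds = sn.simulate_dataset(cfg)

ds = sn.normalize(ds, "mean_divide", "None")
ds = sn.run_otsu_discordance(ds, "both")
ds = sn.run_var_proportions(ds, "both")
print(sn.summarize_dataset(ds).to_text())
```

prints (excerpt):

```
Per-table aggregates (mean over markers)
----------------------------------------
     table  ad_statistic  mean_discordance  proportion_slide
       raw       92.5742            0.0546            0.0676
normalized       -0.7301            0.0156            0.0000

Raw minus normalized (positive = improvement)
---------------------------------------------
ad_statistic       93.3044
mean_discordance    0.0390
proportion_slide    0.0676
```

Read: on the raw table, slide-specific thresholds disagree with the global
threshold for 5.5% of cells on average, 6.8% of marker variance is
slide-level, and the AD statistic (92.6) flags strongly heterogeneous
per-slide distributions. After `mean_divide`, discordance drops to 1.6%,
the slide variance share to ~0, and the AD statistic to below its null
mean — the multiplicative slide effect is gone. The four diagnostic plots
(`plot_density`, `plot_discordance`, `plot_umap`, `plot_proportions`)
visualize the same comparison.

The same workflow runs from the shell:

```sh
slidenorm simulate --n-slides 6 --slide-effect-type multiplicative \
    --slide-effect-sd 0.5 --seed 1 --out cells.csv
slidenorm run --input cells.csv --marker marker1_vals --marker marker2_vals \
    --marker marker3_vals --metadata metadata1_vals --transform mean_divide \
    --seed 42 --out-dir results/run1
```

which writes `normalized.csv`, `discordance.csv`, `umap.csv`,
`var_props.csv`, `summary.csv`, `summary.txt` and the four figures.

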