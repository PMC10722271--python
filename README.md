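# divscape

Landscape-scale mapping of woody-plant diversity for conservation planning.

Tropical nature reserves rarely have wall-to-wall diversity measurements:
field crews census a few hundred 20 m × 20 m plots, while management
decisions — where to focus protection, how well an endangered animal's home
range coincides with the most diverse forest — need a continuous map.
`divscape` implements that workflow end to end:

1. **Plot diversity indices.** From a stem census, per-plot species richness
   `S` and the Shannon–Wiener index `H = −Σ pᵢ ln pᵢ` (nats), where `pᵢ` is
   the proportion of stems in species *i*.
2. **Anthropogenic disturbance surface.** Each risk element (villages,
   factories, roads, artificial and economic forests) carries an
   interference intensity `I₀` that decays with distance, linearly by
   default: `I(d) = I₀ · max(0, 1 − d/D_max)`; per-cell intensities are
   summed over all elements into one disturbance raster.
3. **Predictor selection.** Candidate rasters (climate, soil, topography,
   disturbance) are resampled bilinearly to a common 20 m grid and screened
   three ways: pairwise Pearson `|r| > 0.85` removal, iterative VIF < 10
   (`VIF_j = 1/(1−R²_j)`), and backward elimination on out-of-bag
   permutation importance (%IncMSE) with a cross-validated RMSE stopping
   rule.
4. **Random-Forest modeling.** One 1000-tree regression forest per index;
   `mtry` tuned by 10-fold cross-validated RMSE; %IncMSE importance
   (predictors above 15% flagged as crucial), univariate partial
   dependence, and variance partitioning of CV R² into unique and shared
   fractions of the four predictor groups.
5. **Bias correction.** Forest predictions regress toward the sample mean,
   so the OLS line `S_fit = a·S_obs + b` is fitted on the cross-validated
   predictions and inverted per cell: `S_bc = max((S_fit − b)/a, 0)`.
6. **Hotspots and home ranges.** Cells in the top 10% of the corrected
   surface are hotspots; they are overlaid with circular gibbon family home
   ranges of area 1.49 km² (radius √(A/π) ≈ 688 m) plus an equally wide
   buffer ring (the infrequent range, radius ≈ 1376 m).

Because real survey data of this kind are rarely released, the package
ships a fully synthetic study system (`divscape.synthetic`): spatially
autocorrelated predictor fields, disturbance sources, a two-tier survey of
114 coarse-grid + 277 fine-grid = 391 plots, and communities whose richness
and evenness respond to chosen covariates with known coefficients — so
every stage is testable and the whole pipeline is reproducible from one
seed.

## Worked example

```python
import divscape as d
from divscape import model as rf, selection as sel

cfg = d.LandscapeConfig(n_climate=4, n_soil=3, seed=11)   # 12 km x 12 km, 20 m cells
stack = d.generate_predictor_stack(cfg)
stack["disturbance"] = d.build_risk_surface(stack["clim01"], d.generate_risk_elements(cfg))
layout = d.generate_plot_layout(cfg)                       # 114 + 277 = 391 plots
community = d.simulate_communities(layout, stack, d.default_truth(), seed=11)
diversity = d.compute_diversity_table(community)

X = sel.extract_at_plots(stack, layout)
result = rf.fit_tuned_forest(X, diversity["richness"].to_numpy(),
                             rf.ModelSettings(ntree=1000, seed=11))
print(result.mtry, result.cv_metrics)
print(result.importance.head(2))
```

prints

```
8 {'r2': 0.8254376348438293, 'mae': 5.408501278772379, 'rmse': 6.982576669926845}
  predictor  inc_mse_pct  crucial
0    clim01   289.321685     True
1    soil01   169.081332     True
```

— the tuned forest explains 83% of cross-validated variance in plot
richness, and the two predictors the generator actually used as drivers
(`clim01` with a positive effect, `soil01` negative) rank first and second
in out-of-bag %IncMSE, both above the 15% "crucial" threshold.

The numbered scripts under `analysis/` run the same study as a narrative
sequence (simulate → indices → risk surface → selection → models →
prediction/hotspots → home-range overlay), writing summary tables under
`results/` and large rasters under `scratch/`. The `divscape` command-line
tool exposes each stage (`divscape run --config run.yml --seed 11` runs
everything and writes a manifest with SHA-256 checksums of every artifact).

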