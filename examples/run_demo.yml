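# Demo configuration for `divscape run --config examples/run_demo.yml --seed 1`
# A small landscape (150 x 150 cells, 40 plots) that runs in about a minute.
# Omitted keys fall back to the study-scale defaults (12 km x 12 km, 391 plots).

out_dir: scratch/demo_run
seed: 1

landscape:
  extent: [0.0, 0.0, 3000.0, 3000.0]   # xmin, ymin, xmax, ymax (m)
  cell_size: 20.0                       # m
  correlation_length: 300.0             # m; spatial smoothness of the fields
  n_climate: 3
  n_soil: 2

layout:
  n_coarse: 4                           # plots on the 1-km grid
  n_fine: 36                            # plots on the 0.5-km grid in the focal zone
  focal_zone: [200.0, 200.0, 2800.0, 2800.0]

# ground truth of the simulated communities; omit to use the package default
# (clim01 +0.45, soil01 -0.35 on log richness; clim01 +0.8 on evenness)
# truth:
#   beta_richness: {clim01: 0.45, soil01: -0.35}
#   beta_evenness: {clim01: 0.8}

model:
  ntree: 60                             # 1000 at study scale
  cv_folds: 5                           # 10 at study scale

corr_threshold: 0.85                    # |r| screen
vif_threshold: 10.0
elimination_tolerance: 0.01             # relative CV-RMSE worsening that stops elimination
hotspot_quantile: 0.90                  # top 10% of cells
home_range_area_km2: 1.49
varpart_ntree: 40

group_centers:                          # omit to use the 5 packaged synthetic centers
  - {group: A, x: 1000.0, y: 1000.0}
  - {group: B, x: 2100.0, y: 1900.0}
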