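"""Generate the synthetic study system: predictor rasters, disturbance
sources, the 391-plot two-tier survey layout, and the plot communities.

Writes the rasters/vectors/tables under scratch/analysis/ for the later
stages and a compact landscape summary under results/.
"""

import json

import divscape as d
from divscape.grids import write_stack
from divscape.risk import write_elements_geojson

from _study import SEED, ensure_dirs, results, scratch, study_config


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    stack = d.generate_predictor_stack(cfg)
    elements = d.generate_risk_elements(cfg)
    layout = d.generate_plot_layout(cfg)
    truth = d.default_truth()
    community = d.simulate_communities(layout, stack, truth, seed=SEED)

    write_stack(stack, scratch("stack"))
    write_elements_geojson(elements, scratch("elements.geojson"))
    layout.to_csv(scratch("layout.csv"), index=False)
    community.to_csv(scratch("communities.csv"), index=False)

    summary = {
        "seed": SEED,
        "extent_m": cfg.extent,
        "cell_size_m": cfg.cell_size,
        "grid_cells": cfg.nrows * cfg.ncols,
        "predictors": sorted(stack),
        "n_risk_elements": len(elements),
        "n_plots": {"coarse": 114, "fine": 277, "total": len(layout)},
        "true_drivers": {"richness": truth.beta_richness, "evenness": truth.beta_evenness},
        "n_census_rows": len(community),
    }
    with open(results("01_landscape_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"landscape: {cfg.nrows}x{cfg.ncols} cells, {len(stack)} predictor rasters")
    print(f"survey: {len(layout)} plots, census of {len(community)} species records")
    print(f"known drivers: {truth.beta_richness}")


if __name__ == "__main__":
    main()
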