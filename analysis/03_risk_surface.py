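"""Build the anthropogenic-disturbance raster: each risk element's
interference intensity decays linearly to zero at its maximum distance, and
the per-element fields are summed into one surface, which then joins the
predictor stack as the anthropogenic variable."""

import json

from divscape.grids import read_stack, write_ascii_grid
from divscape.risk import build_risk_surface, load_risk_params, read_elements_geojson

from _study import ensure_dirs, results, scratch


def main() -> None:
    ensure_dirs()
    stack = read_stack(scratch("stack"))
    template = stack["clim01"]
    elements = read_elements_geojson(scratch("elements.geojson"), load_risk_params())
    surface = build_risk_surface(template, elements)
    write_ascii_grid(surface, scratch("stack", "disturbance.asc"))

    summary = {
        "n_elements": len(elements),
        "element_types": sorted({e.element_type for e in elements}),
        "surface_min": float(surface.values.min()),
        "surface_max": float(surface.values.max()),
        "disturbed_fraction": float((surface.values > 0).mean()),
    }
    with open(results("03_risk_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"{len(elements)} risk elements -> disturbance in "
          f"[{summary['surface_min']:.2f}, {summary['surface_max']:.2f}], "
          f"{summary['disturbed_fraction']:.1%} of cells disturbed")


if __name__ == "__main__":
    main()
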