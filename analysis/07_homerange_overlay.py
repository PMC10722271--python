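"""Overlay the diversity hotspots with the circular gibbon home ranges:
five family groups, a frequent disk of 1.49 km2 (688 m radius) each plus an
equally wide buffer ring (infrequent range, radius 1376 m)."""

import pandas as pd

from divscape.grids import read_ascii_grid
from divscape.hotspots import HotspotMask, build_home_ranges, overlay_hotspots
from divscape.pipeline import default_group_centers

from _study import INDICES, ensure_dirs, results, scratch


def main() -> None:
    ensure_dirs()
    ranges = build_home_ranges(default_group_centers())
    reports = []
    for index in INDICES:
        grid = read_ascii_grid(scratch(f"hotspot_{index}.asc"))
        mask = HotspotMask(grid, threshold=float("nan"), quantile=0.90)
        reports.append(overlay_hotspots(mask, ranges, index))
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(results("07_overlay.csv"), index=False)

    wide = report.pivot_table(
        index="group", columns=["index", "tier"], values="coverage_fraction"
    ).round(3)
    print("hotspot coverage fraction of each home range:")
    print(wide)
    touched = report[report["hotspot_cells"] > 0].groupby("index")["group"].nunique()
    print(f"groups touching any hotspot: {touched.to_dict()}")


if __name__ == "__main__":
    main()
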