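"""End-to-end pipeline: simulate -> metrics -> risk -> select -> fit ->
predict -> hotspot -> overlay, for both diversity indices.

`run_all` executes every stage in order under one seed, writes each
intermediate artifact under the output directory, and returns a manifest
recording inputs, parameters, seeds and SHA-256 checksums of every file it
wrote — two runs with the same config produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import hotspots as hs
from . import metrics as dv
from . import model as rf
from . import risk as ers
from . import selection as sel
from . import synthetic as syn
from .grids import write_ascii_grid, write_stack

log = logging.getLogger("divscape")

__all__ = ["RunConfig", "run_all", "default_group_centers"]

INDICES = ("richness", "shannon")


def default_group_centers() -> pd.DataFrame:
    """Synthetic gibbon family-group centers: four clustered groups plus one
    (group E) displaced 8 km from the cluster."""
    return pd.DataFrame(
        {
            "group": ["A", "B", "C", "D", "E"],
            "x": [4000.0, 5200.0, 4400.0, 5600.0, 9656.9],
            "y": [5000.0, 4600.0, 6200.0, 5800.0, 10656.9],
        }
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    out_dir: str = "divscape_run"
    seed: int = 0
    landscape: dict = field(default_factory=dict)  # LandscapeConfig overrides
    layout: dict = field(default_factory=lambda: {"n_coarse": 114, "n_fine": 277})
    truth: dict | None = None  # GroundTruth overrides; None = default_truth()
    species_pool: int = 120
    stems_mean: float = 150.0
    risk_counts: dict | None = None
    risk_params: dict | None = None
    model: dict = field(default_factory=dict)  # ModelSettings overrides
    corr_threshold: float = 0.85
    vif_threshold: float = 10.0
    elimination_tolerance: float = 0.01
    hotspot_quantile: float = 0.90
    home_range_area_km2: float = hs.DEFAULT_HOME_RANGE_KM2
    group_centers: list[dict] | None = None  # None = packaged synthetic centers
    do_varpart: bool = True
    do_uncertainty: bool = True
    varpart_ntree: int = 300

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline for both indices; return the run manifest."""
    t0 = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    written: list[str] = []

    def _w(path: str) -> str:
        written.append(path)
        return path

    current_stage = {"name": "init"}

    def _stage(name: str):
        current_stage["name"] = name
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        # -- simulate ----------------------------------------------------
        _stage("simulate")
        lcfg = syn.LandscapeConfig(seed=config.seed, **config.landscape)
        stack = syn.generate_predictor_stack(lcfg)
        elements = syn.generate_risk_elements(
            lcfg, config.risk_counts, config.risk_params
        )
        layout = syn.generate_plot_layout(lcfg, **config.layout)
        truth = syn.GroundTruth(**config.truth) if config.truth else syn.default_truth()
        community = syn.simulate_communities(
            layout, stack, truth, config.species_pool, config.seed, config.stems_mean
        )

        # -- risk surface joins the stack as the anthropogenic predictor -
        _stage("risk")
        template = stack[next(iter(sorted(stack)))]
        stack["disturbance"] = ers.build_risk_surface(template, elements)

        write_stack(stack, _dir := os.path.join(out, "stack"))
        for name in sorted(stack):
            written.append(os.path.join(_dir, f"{name}.asc"))
        ers.write_elements_geojson(elements, _w(os.path.join(out, "elements.geojson")))
        layout.to_csv(_w(os.path.join(out, "layout.csv")), index=False)
        community.to_csv(_w(os.path.join(out, "communities.csv")), index=False)

        # -- diversity metrics -------------------------------------------
        _stage("metrics")
        diversity = dv.compute_diversity_table(community)
        diversity.to_csv(_w(os.path.join(out, "diversity.csv")), index=False)

        # -- predictors ---------------------------------------------------
        _stage("extract")
        X_full = sel.extract_at_plots(stack, layout)
        X_full.to_csv(_w(os.path.join(out, "predictors.csv")))
        centers = (
            pd.DataFrame(config.group_centers)
            if config.group_centers
            else default_group_centers()
        )
        ranges = hs.build_home_ranges(centers, config.home_range_area_km2)

        manifest: dict[str, Any] = {
            "seed": config.seed,
            "config": asdict(config),
            "n_plots": int(len(layout)),
            "indices": {},
        }

        for index in INDICES:
            _stage(f"select[{index}]")
            y = diversity[index].to_numpy(dtype=float)
            settings = rf.ModelSettings(seed=config.seed, **config.model)
            X_sel, report = sel.select_predictors(
                X_full,
                y,
                config.corr_threshold,
                config.vif_threshold,
                rf.ModelSettings(
                    ntree=config.varpart_ntree, seed=config.seed,
                    cv_folds=settings.cv_folds,
                ),
                config.elimination_tolerance,
            )
            report.to_json(_w(os.path.join(out, f"selection_{index}.json")))

            _stage(f"fit[{index}]")
            result = rf.fit_tuned_forest(X_sel, y, settings)
            result.cv_table.to_csv(_w(os.path.join(out, f"cv_{index}.csv")), index=False)
            result.importance.to_csv(
                _w(os.path.join(out, f"importance_{index}.csv")), index=False
            )

            if config.do_varpart:
                _stage(f"varpart[{index}]")
                labels = {c: sel.predictor_group(c) for c in X_sel.columns}
                vp = rf.variance_partitioning(
                    X_sel,
                    labels,
                    y,
                    rf.ModelSettings(
                        ntree=config.varpart_ntree, seed=config.seed,
                        cv_folds=settings.cv_folds,
                    ),
                )
                with open(_w(os.path.join(out, f"varpart_{index}.json")), "w") as fh:
                    json.dump(vp.to_dict(), fh, indent=2)

            _stage(f"predict[{index}]")
            surface = rf.predict_surface(result, stack)
            corrected = rf.bias_correct(result, surface)
            write_ascii_grid(surface, _w(os.path.join(out, f"predicted_{index}.asc")))
            write_ascii_grid(corrected, _w(os.path.join(out, f"corrected_{index}.asc")))

            _stage(f"hotspot[{index}]")
            mask = hs.identify_hotspots(corrected, config.hotspot_quantile)
            write_ascii_grid(mask.mask, _w(os.path.join(out, f"hotspot_{index}.asc")))

            if config.do_uncertainty:
                _stage(f"uncertainty[{index}]")
                umap = rf.uncertainty_map(result, layout, template)
                write_ascii_grid(
                    umap.classes, _w(os.path.join(out, f"uncertainty_{index}.asc"))
                )

            _stage(f"overlay[{index}]")
            overlap = hs.overlay_hotspots(mask, ranges, index)
            overlap.to_csv(_w(os.path.join(out, f"overlay_{index}.csv")), index=False)

            manifest["indices"][index] = {
                "selected": list(X_sel.columns),
                "mtry": result.mtry,
                "cv": result.cv_metrics,
                "bias": {"a": result.bias_a, "b": result.bias_b},
                "hotspot_threshold": mask.threshold,
                "hotspot_fraction": mask.flagged_fraction(),
            }
    except Exception as exc:  # name the failing stage in the error
        raise RuntimeError(
            f"pipeline failed at stage {current_stage['name']!r}: {exc}"
        ) from exc

    manifest["checksums"] = {
        os.path.relpath(p, out): _sha256(p) for p in sorted(written)
    }
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
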