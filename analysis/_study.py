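"""Shared definition of the synthetic study system used by the numbered
analysis scripts: a 12 km x 12 km landscape at 20 m resolution, 11 candidate
predictors (4 climate, 3 soil, elevation/slope/aspect, summed disturbance),
a 391-plot two-tier survey (114 coarse + 277 fine), and two known diversity
drivers (clim01 positive, soil01 negative on log richness)."""

import os

import divscape as d

SEED = 11
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

INDICES = ("richness", "shannon")


def study_config() -> d.LandscapeConfig:
    return d.LandscapeConfig(n_climate=4, n_soil=3, seed=SEED)


def ensure_dirs() -> None:
    os.makedirs(SCRATCH, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)


def scratch(*parts: str) -> str:
    return os.path.join(SCRATCH, *parts)


def results(*parts: str) -> str:
    return os.path.join(RESULTS, *parts)
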