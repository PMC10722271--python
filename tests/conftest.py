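import numpy as np
import pandas as pd
import pytest

import divscape as d
from divscape import model as rf
from divscape import selection as sel


@pytest.fixture(scope="session")
def small_cfg():
    return d.LandscapeConfig(
        extent=(0.0, 0.0, 2000.0, 2000.0),
        correlation_length=200.0,
        n_climate=3,
        n_soil=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stack(small_cfg):
    return d.generate_predictor_stack(small_cfg)


@pytest.fixture(scope="session")
def recovery():
    """The parameter-recovery study system: 391 plots (114 coarse + 277
    fine) on a 12 km x 12 km landscape, 11 predictors (4 climate, 3 soil,
    3 topography, 1 disturbance), two known drivers (clim01 +, soil01 -)
    from the generator's default ground truth, species-richness forest
    tuned over mtry by 10-fold CV.
    """
    cfg = d.LandscapeConfig(n_climate=4, n_soil=3, seed=11)
    stack = d.generate_predictor_stack(cfg)
    elements = d.generate_risk_elements(cfg)
    stack["disturbance"] = d.build_risk_surface(stack["clim01"], elements)
    layout = d.generate_plot_layout(cfg)
    truth = d.default_truth()
    community = d.simulate_communities(layout, stack, truth, seed=11)
    diversity = d.compute_diversity_table(community)
    X = sel.extract_at_plots(stack, layout)
    y = diversity["richness"].to_numpy(dtype=float)
    result = rf.fit_tuned_forest(X, y, rf.ModelSettings(ntree=500, seed=11))
    return {
        "cfg": cfg,
        "stack": stack,
        "layout": layout,
        "truth": truth,
        "community": community,
        "diversity": diversity,
        "X": X,
        "y": y,
        "result": result,
        "drivers": sorted(truth.beta_richness),
    }


@pytest.fixture
def random_plots():
    """391 random plot centers inside a 2 km extent (no grid constraint)."""
    rng = np.random.default_rng(3)
    n = 391
    return pd.DataFrame(
        {
            "plot_id": [f"P{i:03d}" for i in range(n)],
            "x": rng.uniform(50, 1950, n),
            "y": rng.uniform(50, 1950, n),
            "tier": "coarse",
            "plot_side": 20.0,
        }
    )
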