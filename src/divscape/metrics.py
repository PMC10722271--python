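"""Plot-level woody-plant diversity indices.

Two indices are computed per survey plot from the stem census:

* species richness ``S`` — the number of distinct species present;
* Shannon–Wiener index ``H = -sum(p_i * ln(p_i))`` in nats, where ``p_i`` is
  the proportion of stems belonging to species ``i``.

Note on the sign convention: the Shannon formula is implemented with the
conventional leading minus sign so that H is nonnegative and larger values
mean higher diversity; a signless entropy sum would be nonpositive and
reverse every downstream ranking.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["species_richness", "shannon_index", "compute_diversity_table"]


def _as_abundance_array(abundances, plot_id=None) -> np.ndarray:
    arr = np.asarray(
        list(abundances.values()) if isinstance(abundances, Mapping) else abundances,
        dtype=float,
    )
    label = f" in plot {plot_id}" if plot_id is not None else ""
    if arr.size == 0:
        raise ValueError(f"empty plot{label}: at least one stem is required")
    if np.any(arr < 1):
        raise ValueError(f"abundances must be >= 1 stem{label}")
    return arr


def species_richness(abundances, plot_id=None) -> int:
    """Number of species with at least one stem."""
    arr = _as_abundance_array(abundances, plot_id)
    return int(arr.size)


def shannon_index(abundances, plot_id=None) -> float:
    """Shannon–Wiener entropy of the abundance proportions, in nats."""
    arr = _as_abundance_array(abundances, plot_id)
    p = arr / arr.sum()
    return float(-np.sum(p * np.log(p)))


def compute_diversity_table(community: pd.DataFrame) -> pd.DataFrame:
    """Per-plot richness and Shannon index from a long-format census.

    Parameters
    ----------
    community
        Columns ``plot_id, species, abundance`` and per-plot coordinates
        ``x, y`` (repeated on each stem row). (plot_id, species) pairs must
        be unique.

    Returns
    -------
    DataFrame with columns ``plot_id, x, y, richness, shannon``, one row per
    plot, in order of first appearance.
    """
    required = {"plot_id", "species", "abundance", "x", "y"}
    missing = required - set(community.columns)
    if missing:
        raise ValueError(f"community table lacks columns: {sorted(missing)}")
    if community.duplicated(["plot_id", "species"]).any():
        dupes = community[community.duplicated(["plot_id", "species"])]["plot_id"].unique()
        raise ValueError(f"duplicate (plot_id, species) rows in plots: {list(dupes)[:5]}")

    records = []
    for plot_id, grp in community.groupby("plot_id", sort=False):
        abund = grp["abundance"].to_numpy()
        records.append(
            {
                "plot_id": plot_id,
                "x": float(grp["x"].iloc[0]),
                "y": float(grp["y"].iloc[0]),
                "richness": species_richness(abund, plot_id),
                "shannon": shannon_index(abund, plot_id),
            }
        )
    return pd.DataFrame.from_records(records)
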