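"""Compute per-plot species richness and Shannon-Wiener index from the
simulated stem census and summarize their distributions."""

import pandas as pd

from divscape.metrics import compute_diversity_table

from _study import ensure_dirs, results, scratch


def main() -> None:
    ensure_dirs()
    community = pd.read_csv(scratch("communities.csv"))
    diversity = compute_diversity_table(community)
    diversity.to_csv(scratch("diversity.csv"), index=False)

    summary = diversity[["richness", "shannon"]].describe().round(3)
    summary.to_csv(results("02_diversity_summary.csv"))
    print(f"{len(diversity)} plots")
    print(summary.loc[["mean", "std", "min", "max"]])


if __name__ == "__main__":
    main()
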