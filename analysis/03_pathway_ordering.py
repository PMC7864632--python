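#!/usr/bin/env python
"""Order a loading-plus-cycle ensemble by minimal cumulative RMSD.

Builds the seven-state synthetic ensemble (two loading-like outliers L1/L2
plus a tight five-state cycle C1-C5), computes the 21 pairwise whole-model
RMSDs, splits loading from cycle states by single-linkage clustering, and
finds the exact smallest-cumulative-RMSD ordering starting at L1.

Writes results/rmsd_matrix.csv and results/pathway.json.
"""

import json
from pathlib import Path

import statewalk as sw

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ens, truth = sw.synth.make_study_like_ensemble(seed=SEED)
    matrix = sw.pairwise_rmsd_matrix(ens, "whole", mode="all")
    matrix.to_csv(OUT / "rmsd_matrix.csv")
    n = len(matrix.labels)
    print(f"{n} states, {n * (n - 1) // 2} pairwise rmsds "
          f"(max asymmetry {matrix.max_asymmetry:.2e} Å)")

    g1, g2, stats = sw.loading_vs_cycle_partition(matrix)
    loading = g1 if len(g1) < len(g2) else g2
    cycle = g2 if len(g1) < len(g2) else g1
    print(f"partition: loading {sorted(loading)} vs cycle {sorted(cycle)} "
          f"(within-group max {stats['within_max']:.1f} Å, "
          f"between-group min {stats['between_min']:.1f} Å)")

    path = sw.min_cumulative_path(matrix, "L1")
    print(f"minimal-cumulative-rmsd path: {' -> '.join(path.labels)} "
          f"({path.cumulative_rmsd:.2f} Å over {path.enumeration_size} enumerated orders)")
    planted_ok = path.labels == truth["path"]
    print(f"matches the planted order: {planted_ok}")

    (OUT / "pathway.json").write_text(json.dumps({
        "order": path.labels,
        "cumulative_rmsd_A": path.cumulative_rmsd,
        "enumeration_size": path.enumeration_size,
        "loading_group": sorted(loading),
        "cycle_group": sorted(cycle),
        "partition_stats": {k: float(v) for k, v in stats.items()},
        "matches_planted_order": planted_ok,
    }, indent=2))


if __name__ == "__main__":
    main()
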