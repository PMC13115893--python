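#!/usr/bin/env python
"""Stage 3: consensus machine-learning feature selection.

SVM-RFE and random-forest importances each rank a pool; stratified CV
picks the best top-k per ranker; the per-pool intersection gives the
T-sites / G-sites, and their union the integrated U-sites.
"""

import argparse
from pathlib import Path

from oamethyl.io import read_beta_matrix
from oamethyl.pipeline import stage_seed
from oamethyl.selection import (
    consensus_sites,
    cv_subset_selection,
    rf_importance_ranking,
    svm_rfe_ranking,
    union_sites,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--grid", type=int, nargs="+", default=[60, 120, 200])
args = parser.parse_args()
out = args.dir

matrix = read_beta_matrix(out / "beta_matrix.tsv", out / "sample_sheet.tsv")
col = {c: i for i, c in enumerate(matrix.cpg_ids)}
y = matrix.labels

consensus = {}
for tag, pool_file in (("T", "t_pool.txt"), ("G", "g_pool.txt")):
    pool = (out / pool_file).read_text().split()
    X = matrix.values.T[:, [col[c] for c in pool]]
    grid = [s for s in args.grid if s <= len(pool)] or [len(pool)]
    seed = stage_seed(args.seed, f"select-{tag}")
    svm = svm_rfe_ranking(X, y, pool, elim_fraction=0.2, seed=seed)
    rf = rf_importance_ranking(X, y, pool, n_trees=200, seed=seed)
    k_svm, _ = cv_subset_selection(svm, X, y, pool, grid, seed=seed)
    k_rf, _ = cv_subset_selection(rf, X, y, pool, grid, seed=seed)
    sites = consensus_sites(svm.top(k_svm), rf.top(k_rf),
                            set_tag=f"{tag}-sites")
    consensus[tag] = sites
    print(f"{tag}: SVM-RFE k={k_svm}, RF k={k_rf}, "
          f"consensus {len(sites.cpg_ids)} probes")

u = union_sites(consensus["T"], consensus["G"])
print(f"U-sites: {len(u.cpg_ids)} probes "
      f"(overlap {u.source_sizes[2]})")

order = {c: i for i, c in enumerate(matrix.cpg_ids)}
for tag, sites in (("t", consensus["T"]), ("g", consensus["G"]), ("u", u)):
    ids = sorted(sites.cpg_ids, key=order.get)
    (out / f"{tag}_sites.txt").write_text("\n".join(ids) + "\n")
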